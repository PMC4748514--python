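"""Typed in-memory records for games, players, sites and sessions.

These are the exchange objects every other module consumes: a
:class:`GameDescription` captures one exergame's identity, metrics,
controllers, presentation hardware, exercise and goals; a
:class:`SessionRecord` captures one continuous play period of one player
on one game, carrying a :class:`MetricObservation` per game metric with
its per-iteration values.

All records are frozen dataclasses that validate their invariants at
construction time (an invalid record cannot exist), so downstream RDF
emission never has to re-check structure.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Optional, Union

import yaml

from .namespaces import (
    CONTROLLER_NS,
    METRIC_NS,
    Iri,
    normalize_iri,
)

__all__ = [
    "MetricDefinition",
    "ControllerDefinition",
    "MuscleRef",
    "ExerciseDefinition",
    "HardwareRef",
    "Goal",
    "GameDescription",
    "PlayerRecord",
    "SiteRecord",
    "MetricObservation",
    "SessionRecord",
    "define_metric",
    "load_game_description",
    "game_description_from_dict",
]

_LOCAL_NAME_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_.\-]*$")

MetricValue = Union[bool, int, float, str]


@dataclass(frozen=True)
class MetricDefinition:
    """A shared game metric (an ``exergame:GoalMetric`` instance).

    Metrics live in the common metric namespace so distinct games can
    reference the same instance; ``concept`` optionally ties the metric to
    a SKOS concept (e.g. time) and ``default_unit`` to a QUDT unit.
    """

    iri: Iri
    label: str
    concept: Optional[Iri] = None
    default_unit: Optional[Iri] = None

    def __post_init__(self) -> None:
        if not self.iri.startswith(METRIC_NS):
            raise ValueError(f"metric IRI must be in {METRIC_NS}: {self.iri}")
        if not self.label:
            raise ValueError("metric label must be non-empty")


def define_metric(
    local_name: str,
    label: str,
    concept: Optional[Iri] = None,
    unit: Optional[Iri] = None,
) -> MetricDefinition:
    """Mint a metric instance in the shared metric namespace."""
    if not local_name or not _LOCAL_NAME_RE.match(local_name):
        raise ValueError(f"invalid metric local name: {local_name!r}")
    return MetricDefinition(
        iri=Iri(METRIC_NS + local_name),
        label=label,
        concept=concept,
        default_unit=unit,
    )


@dataclass(frozen=True)
class ControllerDefinition:
    """A game controller instance, optionally owl:sameAs a DBpedia resource."""

    iri: Iri
    label: str
    same_as: Optional[Iri] = None

    def __post_init__(self) -> None:
        if not self.iri.startswith(CONTROLLER_NS):
            raise ValueError(f"controller IRI must be in {CONTROLLER_NS}: {self.iri}")


@dataclass(frozen=True)
class MuscleRef:
    """A muscle involved in an exercise.

    ``source`` is ``"ope"`` when the muscle exists in the OPE ontology and
    ``"ncit_subclass"`` when it is instead declared as a subclass of
    ``nci:Muscle``.
    """

    iri: Iri
    source: str = "ope"

    def __post_init__(self) -> None:
        if self.source not in ("ope", "ncit_subclass"):
            raise ValueError(f"muscle source must be 'ope' or 'ncit_subclass': {self.source!r}")


@dataclass(frozen=True)
class ExerciseDefinition:
    """The physical exercise a game incorporates (OPE-described)."""

    iri: Iri
    label: str
    muscles: tuple[MuscleRef, ...] = ()
    equipment: tuple[str, ...] = ()
    benefits: tuple[str, ...] = ()


@dataclass(frozen=True)
class HardwareRef:
    """Presentation hardware: the device the game is displayed on."""

    iri: Iri
    label: str


@dataclass(frozen=True)
class Goal:
    """A game or exercise goal, kept as a plain annotation."""

    kind: str  # "game_goal" | "exercise_goal"
    text: str

    def __post_init__(self) -> None:
        if self.kind not in ("game_goal", "exercise_goal"):
            raise ValueError(f"goal kind must be game_goal or exercise_goal: {self.kind!r}")


@dataclass(frozen=True)
class GameDescription:
    """One exergame, described once; all sessions refer to it by IRI."""

    iri: Iri
    label: str
    metrics: tuple[MetricDefinition, ...]
    controllers: tuple[ControllerDefinition, ...] = ()
    presentation_hardware: tuple[HardwareRef, ...] = ()
    exercise: Optional[ExerciseDefinition] = None
    goals: tuple[Goal, ...] = ()

    def __post_init__(self) -> None:
        if not self.metrics:
            raise ValueError(f"game {self.iri} must declare at least one metric")
        iris = [m.iri for m in self.metrics]
        if len(set(iris)) != len(iris):
            raise ValueError(f"duplicate metric IRIs in game {self.iri}")

    def metric(self, local_name: str) -> MetricDefinition:
        for m in self.metrics:
            if m.iri.local_name == local_name:
                return m
        raise KeyError(local_name)


@dataclass(frozen=True)
class PlayerRecord:
    """A player, identified only by an opaque IRI.

    Demographics (age in years, gender) are cohort attributes used by the
    simulator; they are never serialized as identifying literals.  The IRI
    local name must be opaque -- it may not embed an email address or
    whitespace-separated personal name.
    """

    iri: Iri
    age: Optional[float] = None
    gender: Optional[str] = None

    def __post_init__(self) -> None:
        local = self.iri.local_name
        if "@" in local or " " in local:
            raise ValueError(f"player identifier must be opaque: {local!r}")
        if self.gender is not None and self.gender not in ("male", "female", "other"):
            raise ValueError(f"unknown gender category: {self.gender!r}")


@dataclass(frozen=True)
class SiteRecord:
    """The venue of a game session; the address range is deliberately open."""

    iri: Iri
    site_type: Iri
    address: Optional[str] = None


@dataclass(frozen=True)
class MetricObservation:
    """One metric's values across the iterations of a session.

    ``values`` holds one typed value per iteration of the underlying
    physical exercise, all of one Python type (bool, int, float or str).
    """

    metric: Iri
    values: tuple[MetricValue, ...]
    unit: Optional[Iri] = None

    def __post_init__(self) -> None:
        if not self.values:
            raise ValueError(f"observation of {self.metric} has no values")
        first = type(self.values[0])
        if any(type(v) is not first for v in self.values):
            raise ValueError(
                f"observation of {self.metric} mixes value datatypes: "
                f"{sorted({type(v).__name__ for v in self.values})}"
            )

    @property
    def iterations(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class SessionRecord:
    """One play period: player x game x site x time window x observations.

    A session begins when the game starts and ends when the game ends or
    stops; start/end carry an explicit UTC offset.  Observations are
    normalized to metric-IRI order at construction (RDF imposes no
    relation order, so a canonical order makes graph round-trips exact).
    """

    session_id: Optional[str]
    game: Iri
    player: Iri
    start: datetime
    end: datetime
    observations: tuple[MetricObservation, ...]
    site: Optional[Iri] = None

    def __post_init__(self) -> None:
        for name, ts in (("start", self.start), ("end", self.end)):
            if ts.tzinfo is None:
                raise ValueError(f"session {name} time must carry a UTC offset")
        if self.start > self.end:
            raise ValueError(
                f"session start {self.start.isoformat()} is after end {self.end.isoformat()}"
            )
        if not self.observations:
            raise ValueError("session must carry at least one metric observation")
        metrics = [o.metric for o in self.observations]
        if len(set(metrics)) != len(metrics):
            raise ValueError("observation metrics must be unique within a session")
        object.__setattr__(
            self, "observations", tuple(sorted(self.observations, key=lambda o: o.metric))
        )

    def observation(self, metric: Iri) -> MetricObservation:
        for o in self.observations:
            if o.metric == metric:
                return o
        raise KeyError(metric)


# ---------------------------------------------------------------------------
# Game descriptions as YAML/JSON documents (field names mirror the dataclass)


def game_description_from_dict(doc: dict) -> GameDescription:
    """Build a :class:`GameDescription` from a plain mapping.

    The document mirrors the dataclass field names; metric entries may give
    either a full ``iri`` or a ``local_name`` to mint in the shared metric
    namespace.  See ``schemas/game_description.schema.json``.
    """
    if not isinstance(doc, dict):
        raise ValueError("game description document must be a mapping")
    for key in ("iri", "label", "metrics"):
        if key not in doc:
            raise ValueError(f"game description missing required field {key!r}")

    def opt_iri(value: Optional[str]) -> Optional[Iri]:
        return normalize_iri(value) if value else None

    metrics = []
    for m in doc["metrics"]:
        if "iri" in m:
            metrics.append(
                MetricDefinition(
                    iri=normalize_iri(m["iri"]),
                    label=m.get("label", Iri(m["iri"]).local_name),
                    concept=opt_iri(m.get("concept")),
                    default_unit=opt_iri(m.get("unit") or m.get("default_unit")),
                )
            )
        else:
            metrics.append(
                define_metric(
                    m["local_name"],
                    m.get("label", m["local_name"]),
                    concept=opt_iri(m.get("concept")),
                    unit=opt_iri(m.get("unit") or m.get("default_unit")),
                )
            )
    controllers = tuple(
        ControllerDefinition(
            iri=normalize_iri(c["iri"]),
            label=c.get("label", Iri(c["iri"]).local_name),
            same_as=opt_iri(c.get("same_as")),
        )
        for c in doc.get("controllers", ())
    )
    hardware = tuple(
        HardwareRef(iri=normalize_iri(h["iri"]), label=h.get("label", Iri(h["iri"]).local_name))
        for h in doc.get("presentation_hardware", ())
    )
    exercise = None
    if doc.get("exercise"):
        e = doc["exercise"]
        exercise = ExerciseDefinition(
            iri=normalize_iri(e["iri"]),
            label=e.get("label", Iri(e["iri"]).local_name),
            muscles=tuple(
                MuscleRef(iri=normalize_iri(m["iri"]), source=m.get("source", "ope"))
                for m in e.get("muscles", ())
            ),
            equipment=tuple(e.get("equipment", ())),
            benefits=tuple(e.get("benefits", ())),
        )
    goals = tuple(Goal(kind=g["kind"], text=g["text"]) for g in doc.get("goals", ()))
    return GameDescription(
        iri=normalize_iri(doc["iri"]),
        label=doc["label"],
        metrics=tuple(metrics),
        controllers=controllers,
        presentation_hardware=hardware,
        exercise=exercise,
        goals=goals,
    )


def load_game_description(path: Union[str, Path]) -> GameDescription:
    """Load a game description from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return game_description_from_dict(doc)
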