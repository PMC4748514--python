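"""Synthetic living-lab pilot generator.

Emulates the structure of the deployment the ontology was piloted in: a
cohort of elderly players (14 people, 3 male and 11 female, mean age 73.4
years) visiting a living-lab environment on 6 days and playing 7 different
games per visit.  Every simulated session carries one observation per game
metric, with per-iteration values drawn from per-metric distributions:

* success flags: Bernoulli;
* reaction times: log-normal (positive, right-skewed, as human response
  latencies are);
* goal/total times and scores: normal truncated at zero.

The default catalog contains the seven games the pilot platform offered:
three strength games with a predetermined number of iterations recording
success / reaction time / goal time (SideRaises -- the worked example --
BicepsCurl and LegExtension) and four activity games recording total time
and a score (Apple, Hiking, Fishing, Golf).

Everything is driven by one integer seed; the same seed reproduces the
same players, sessions and (canonicalized) graph byte for byte.  The
defaults yield 14 x 6 x 7 = 588 sessions of 2-6 minutes each, i.e. on the
order of 35 hours of play.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta, timezone
from typing import Mapping, Optional, Union

import numpy as np
from rdflib import Graph

from .namespaces import QUDT_UNIT_NS, Iri
from .records import (
    ControllerDefinition,
    ExerciseDefinition,
    GameDescription,
    HardwareRef,
    MetricObservation,
    MuscleRef,
    PlayerRecord,
    SessionRecord,
    define_metric,
)
from .graphs import game_to_graph, player_to_graph, session_to_graph, _new_graph
from .namespaces import CONTROLLER_NS, OPE_NS, default_terms
from .sideraises import RESOURCES_BASE, SECOND, TIME_CONCEPT, sideraises_game

__all__ = [
    "Bernoulli",
    "LogNormal",
    "TruncNormal",
    "SimulationConfig",
    "PilotOutput",
    "ConfigurationError",
    "default_catalog",
    "default_pilot_config",
    "simulate_session",
    "simulate_pilot",
    "config_from_dict",
]


class ConfigurationError(ValueError):
    """A simulation configuration violates its invariants."""


# ---------------------------------------------------------------------------
# Metric value models


@dataclass(frozen=True)
class Bernoulli:
    """Success/failure flag with success probability ``p``."""

    p: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ConfigurationError(f"Bernoulli p must be in [0,1]: {self.p}")

    def draw(self, rng: np.random.Generator, n: int) -> tuple:
        return tuple(bool(v) for v in rng.random(n) < self.p)


@dataclass(frozen=True)
class LogNormal:
    """Positive right-skewed values; ``mu``/``sigma`` on the log scale."""

    mu: float
    sigma: float

    def draw(self, rng: np.random.Generator, n: int) -> tuple:
        return tuple(round(float(v), 3) for v in rng.lognormal(self.mu, self.sigma, n))


@dataclass(frozen=True)
class TruncNormal:
    """Normal(mu, sigma) truncated at zero (redrawn); optionally rounded
    to integers (e.g. scores)."""

    mu: float
    sigma: float
    integer: bool = False

    def draw(self, rng: np.random.Generator, n: int) -> tuple:
        out = []
        while len(out) < n:
            v = float(rng.normal(self.mu, self.sigma))
            if v > 0:
                out.append(int(round(v)) if self.integer else round(v, 3))
        return tuple(out)


MetricModel = Union[Bernoulli, LogNormal, TruncNormal]


# ---------------------------------------------------------------------------
# Default game catalog (see module docstring)

_STRENGTH_EXERCISES = {
    "BicepsCurl": ("biceps curl", "Biceps_Brachii"),
    "LegExtension": ("leg extension", "Quadriceps_Femoris"),
}
_ACTIVITY_GAMES = ("Apple", "Hiking", "Fishing", "Golf")

UNITLESS = Iri(QUDT_UNIT_NS + "Unitless")


def _strength_game(name: str) -> GameDescription:
    label, muscle = _STRENGTH_EXERCISES[name]
    return GameDescription(
        iri=Iri(RESOURCES_BASE + name + "Game"),
        label=name,
        metrics=(
            define_metric("Success", "success"),
            define_metric("ReactionTime", "reaction time", concept=TIME_CONCEPT, unit=SECOND),
            define_metric("GoalTime", "goal time", concept=TIME_CONCEPT, unit=SECOND),
        ),
        controllers=(
            ControllerDefinition(
                iri=Iri(CONTROLLER_NS + "Kinect"),
                label="Kinect",
                same_as=Iri("http://dbpedia.org/resource/Kinect"),
            ),
        ),
        presentation_hardware=(HardwareRef(Iri(RESOURCES_BASE + "SmartTV"), "smart TV"),),
        exercise=ExerciseDefinition(
            iri=Iri(RESOURCES_BASE + name + "Exercise"),
            label=label,
            muscles=(MuscleRef(Iri(OPE_NS + muscle), source="ope"),),
        ),
    )


def _activity_game(name: str) -> GameDescription:
    return GameDescription(
        iri=Iri(RESOURCES_BASE + name + "Game"),
        label=name,
        metrics=(
            define_metric("TotalTime", "total time", concept=TIME_CONCEPT, unit=SECOND),
            define_metric("Score", "score", unit=UNITLESS),
        ),
        controllers=(
            ControllerDefinition(
                iri=Iri(CONTROLLER_NS + "Kinect"),
                label="Kinect",
                same_as=Iri("http://dbpedia.org/resource/Kinect"),
            ),
        ),
        presentation_hardware=(HardwareRef(Iri(RESOURCES_BASE + "SmartTV"), "smart TV"),),
    )


def default_catalog() -> tuple[GameDescription, ...]:
    """The seven pilot games, SideRaises first."""
    return (
        sideraises_game(),
        _strength_game("BicepsCurl"),
        _strength_game("LegExtension"),
        *(_activity_game(name) for name in _ACTIVITY_GAMES),
    )


def default_metric_models() -> dict[Iri, MetricModel]:
    from .namespaces import METRIC_NS

    return {
        Iri(METRIC_NS + "Success"): Bernoulli(0.7),
        Iri(METRIC_NS + "ReactionTime"): LogNormal(math.log(1.5), 0.4),
        Iri(METRIC_NS + "GoalTime"): TruncNormal(4.0, 1.0),
        Iri(METRIC_NS + "TotalTime"): TruncNormal(120.0, 30.0),
        Iri(METRIC_NS + "Score"): TruncNormal(10.0, 3.0, integer=True),
    }


# ---------------------------------------------------------------------------
# Configuration


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort and distribution parameters for a synthetic pilot.

    Defaults reproduce the pilot deployment's shape: 14 players (3 male),
    mean age 73.4 y (SD 5, clamped to [60, 95]), 6 visits per player,
    7 games per visit.
    """

    n_players: int = 14
    n_male: int = 3
    age_mean: float = 73.4
    age_sd: float = 5.0
    visits_per_player: int = 6
    games_per_visit: int = 7
    game_catalog: tuple[GameDescription, ...] = field(default_factory=default_catalog)
    iterations_range: tuple[int, int] = (6, 10)
    metric_models: Mapping[Iri, MetricModel] = field(default_factory=default_metric_models)
    session_gap_minutes: tuple[float, float] = (2.0, 8.0)
    session_duration_minutes: tuple[float, float] = (2.0, 6.0)
    start_date: date = date(2014, 9, 22)
    utc_offset_hours: int = 2
    site: Iri = Iri(RESOURCES_BASE + "MedicalPhysicsLaboratoryAuth")
    player_iri_base: str = RESOURCES_BASE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_players < 1:
            raise ConfigurationError("n_players must be >= 1")
        if not 0 <= self.n_male <= self.n_players:
            raise ConfigurationError("n_male must be between 0 and n_players")
        if self.visits_per_player < 1 or self.games_per_visit < 1:
            raise ConfigurationError("visits_per_player and games_per_visit must be >= 1")
        if self.games_per_visit > len(self.game_catalog):
            raise ConfigurationError(
                f"games_per_visit ({self.games_per_visit}) exceeds catalog size "
                f"({len(self.game_catalog)})"
            )
        lo, hi = self.iterations_range
        if not (1 <= lo <= hi):
            raise ConfigurationError(f"invalid iterations_range {self.iterations_range}")
        for name in ("session_gap_minutes", "session_duration_minutes"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ConfigurationError(f"invalid {name} {(lo, hi)}")
        for metric, model in self.metric_models.items():
            if not isinstance(model, (Bernoulli, LogNormal, TruncNormal)):
                raise ConfigurationError(f"unknown metric model for {metric}: {model!r}")


def default_pilot_config(seed: int = 0) -> SimulationConfig:
    """The pilot-shaped default configuration (deterministic)."""
    return SimulationConfig(seed=seed)


@dataclass(frozen=True)
class PilotOutput:
    """players + sessions + their union RDF graph."""

    players: tuple[PlayerRecord, ...]
    sessions: tuple[SessionRecord, ...]
    graph: Graph


# ---------------------------------------------------------------------------
# Simulation


def simulate_session(
    player: PlayerRecord,
    game: GameDescription,
    start: datetime,
    rng: np.random.Generator,
    *,
    iterations_range: tuple[int, int] = (6, 10),
    metric_models: Optional[Mapping[Iri, MetricModel]] = None,
    duration_minutes: tuple[float, float] = (2.0, 6.0),
    site: Optional[Iri] = None,
    session_id: Optional[str] = None,
) -> SessionRecord:
    """One session of *player* on *game* starting at *start*: one
    observation per game metric, a common iteration count, a positive
    duration."""
    models = metric_models if metric_models is not None else default_metric_models()
    n_iter = int(rng.integers(iterations_range[0], iterations_range[1] + 1))
    observations = []
    for metric in game.metrics:
        model = models.get(metric.iri)
        if model is None:
            raise ConfigurationError(f"no distribution configured for metric {metric.iri}")
        observations.append(
            MetricObservation(
                metric=metric.iri,
                values=model.draw(rng, n_iter),
                unit=metric.default_unit,
            )
        )
    duration = float(rng.uniform(*duration_minutes))
    end = start + timedelta(minutes=duration)
    return SessionRecord(
        session_id=session_id,
        game=game.iri,
        player=player.iri,
        site=site,
        start=start,
        end=end,
        observations=tuple(observations),
    )


def _simulate_players(config: SimulationConfig, rng: np.random.Generator) -> tuple[PlayerRecord, ...]:
    genders = ["male"] * config.n_male + ["female"] * (config.n_players - config.n_male)
    rng.shuffle(genders)
    players = []
    for i in range(config.n_players):
        age = float(np.clip(rng.normal(config.age_mean, config.age_sd), 60.0, 95.0))
        players.append(
            PlayerRecord(
                iri=Iri(f"{config.player_iri_base}player{i + 1:03d}"),
                age=round(age, 1),
                gender=genders[i],
            )
        )
    return tuple(players)


def simulate_pilot(config: Optional[SimulationConfig] = None) -> PilotOutput:
    """Run a full synthetic pilot; deterministic given ``config.seed``.

    Session count is ``n_players x visits_per_player x games_per_visit``;
    each player plays the same fixed slice of the catalog on every visit
    (the pilot offered the same set of games each day).  The emitted graph
    is the union of the game descriptions, the (anonymous) player nodes
    and every session, and validates cleanly under the compat profile.
    """
    config = config or default_pilot_config()
    rng = np.random.default_rng(config.seed)
    terms = default_terms()
    players = _simulate_players(config, rng)
    tz = timezone(timedelta(hours=config.utc_offset_hours))

    sessions: list[SessionRecord] = []
    for player in players:
        games = config.game_catalog[: config.games_per_visit]
        for visit in range(config.visits_per_player):
            day = config.start_date + timedelta(days=visit)
            cursor = datetime.combine(day, time(10, 0), tzinfo=tz)
            for game in games:
                sid = f"{player.iri.local_name}-d{visit + 1}-{game.iri.local_name}"
                session = simulate_session(
                    player,
                    game,
                    cursor,
                    rng,
                    iterations_range=config.iterations_range,
                    metric_models=config.metric_models,
                    duration_minutes=config.session_duration_minutes,
                    site=config.site,
                    session_id=sid,
                )
                sessions.append(session)
                gap = float(rng.uniform(*config.session_gap_minutes))
                cursor = session.end + timedelta(minutes=gap)

    graph = _new_graph(terms)
    for game in config.game_catalog:
        game_to_graph(game, terms, graph=graph)
    for player in players:
        player_to_graph(player, terms, graph=graph)
    for session in sessions:
        session_to_graph(session, terms, graph=graph)
    return PilotOutput(players=players, sessions=tuple(sessions), graph=graph)


# ---------------------------------------------------------------------------
# YAML/JSON configuration documents


def _model_from_dict(doc: Mapping) -> MetricModel:
    kind = doc.get("kind")
    if kind == "bernoulli":
        return Bernoulli(p=float(doc["p"]))
    if kind == "lognormal":
        return LogNormal(mu=float(doc["mu"]), sigma=float(doc["sigma"]))
    if kind == "normal":
        return TruncNormal(
            mu=float(doc["mu"]), sigma=float(doc["sigma"]), integer=bool(doc.get("integer", False))
        )
    raise ConfigurationError(f"unknown metric model kind {kind!r}")


def config_from_dict(doc: Mapping, *, seed: Optional[int] = None) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a plain mapping (YAML/JSON);
    *seed* overrides any seed in the document."""
    from .records import game_description_from_dict

    kwargs: dict = {}
    simple = (
        "n_players", "n_male", "age_mean", "age_sd", "visits_per_player",
        "games_per_visit", "utc_offset_hours", "seed", "player_iri_base",
    )
    for key in simple:
        if key in doc:
            kwargs[key] = doc[key]
    for key in ("iterations_range", "session_gap_minutes", "session_duration_minutes"):
        if key in doc:
            kwargs[key] = tuple(doc[key])
    if "start_date" in doc:
        value = doc["start_date"]
        kwargs["start_date"] = value if isinstance(value, date) else date.fromisoformat(value)
    if "site" in doc:
        kwargs["site"] = Iri(doc["site"])
    if "game_catalog" in doc:
        kwargs["game_catalog"] = tuple(
            game_description_from_dict(g) for g in doc["game_catalog"]
        )
    if "metric_models" in doc:
        models = dict(default_metric_models())
        for metric, spec in doc["metric_models"].items():
            from .namespaces import METRIC_NS, normalize_iri

            iri = normalize_iri(metric) if "://" in metric else Iri(METRIC_NS + metric)
            models[iri] = _model_from_dict(spec)
        kwargs["metric_models"] = models
    if seed is not None:
        kwargs["seed"] = seed
    try:
        return SimulationConfig(**kwargs)
    except TypeError as exc:
        raise ConfigurationError(str(exc)) from exc
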