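"""Conversion of tabular (CSV) game logs into session records and RDF.

Most deployed games store results in a relational database; the W3C way
to lift such data to RDF is a mapping language like R2RML.  This module
implements a deliberately small, R2RML-inspired single-table dialect: a
:class:`MappingSpec` binds the roles of the session model (session id,
player id, game IRI, timestamps, metric, iteration, value, optional site
and unit) to column names of a long-format table -- one row per metric
iteration.  Player IRIs are minted as ``base + opaque id``, preserving
the anonymity rule.

Wide-format logs and database connectivity are out of scope.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import yaml

from .namespaces import METRIC_NS, Iri, normalize_iri
from .records import MetricObservation, MetricValue, SessionRecord

__all__ = [
    "MappingSpec",
    "MappingError",
    "ConversionError",
    "load_mapping",
    "default_session_mapping",
    "rows_to_sessions",
    "read_csv_rows",
    "sessions_to_rows",
    "write_sessions_csv",
]

MANDATORY_ROLES = (
    "session_id",
    "player_id",
    "game_iri",
    "start",
    "end",
    "metric",
    "iteration",
    "value",
)
OPTIONAL_ROLES = ("site_iri", "unit")

_CASTS = {
    "boolean": lambda s: s.strip().lower() == "true",
    "integer": int,
    "decimal": float,
    "string": str,
}


class MappingError(ValueError):
    """A mapping document is missing or misbinds a role."""


class ConversionError(ValueError):
    """Rows violate the mapping's structural expectations."""


@dataclass(frozen=True)
class MappingSpec:
    """Column bindings and IRI bases for one long-format table."""

    columns: Mapping[str, str]
    iri_bases: Mapping[str, str] = field(default_factory=dict)
    datatypes: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for role in MANDATORY_ROLES:
            if role not in self.columns:
                raise MappingError(f"mapping is missing mandatory role {role!r}")
        for role in self.columns:
            if role not in MANDATORY_ROLES + OPTIONAL_ROLES:
                raise MappingError(f"unknown mapping role {role!r}")
        for metric, datatype in self.datatypes.items():
            if datatype not in _CASTS:
                raise MappingError(
                    f"unknown datatype {datatype!r} for metric {metric} "
                    f"(choose from {sorted(_CASTS)})"
                )

    def to_dict(self) -> dict:
        return {
            "columns": dict(self.columns),
            "iri_bases": dict(self.iri_bases),
            "datatypes": dict(self.datatypes),
        }


def load_mapping(source: Union[str, Path, Mapping]) -> MappingSpec:
    """Load a mapping from a YAML file, YAML text, or plain mapping."""
    if isinstance(source, Mapping):
        doc = source
    else:
        path = Path(source)
        text = path.read_text(encoding="utf-8") if path.exists() else str(source)
        doc = yaml.safe_load(text)
    if not isinstance(doc, Mapping) or "columns" not in doc:
        raise MappingError("mapping document must be a mapping with a 'columns' table")
    return MappingSpec(
        columns=dict(doc["columns"]),
        iri_bases=dict(doc.get("iri_bases", {})),
        datatypes=dict(doc.get("datatypes", {})),
    )


def default_session_mapping(player_base: str = "http://www.fitforall.gr/resources/") -> MappingSpec:
    """The mapping matching this package's own CSV session log schema."""
    return MappingSpec(
        columns={
            "session_id": "session_id",
            "player_id": "player_id",
            "game_iri": "game",
            "site_iri": "site",
            "start": "start",
            "end": "end",
            "metric": "metric",
            "unit": "unit",
            "iteration": "iteration",
            "value": "value",
        },
        iri_bases={"player": player_base},
    )


def _mint_player(value: str, mapping: MappingSpec) -> Iri:
    if "://" in value:
        return normalize_iri(value)
    base = mapping.iri_bases.get("player")
    if not base:
        raise MappingError(
            "player_id values are not IRIs and the mapping declares no 'player' iri base"
        )
    return Iri(base + value)


def _metric_iri(value: str) -> Iri:
    return normalize_iri(value) if "://" in value else Iri(METRIC_NS + value)


def _infer_value(text: str) -> MetricValue:
    if text.strip().lower() in ("true", "false"):
        return text.strip().lower() == "true"
    try:
        return int(text)
    except ValueError:
        pass
    try:
        return float(text)
    except ValueError:
        return text


def _cast_value(text: str, metric: Iri, mapping: MappingSpec) -> MetricValue:
    datatype = mapping.datatypes.get(str(metric)) or mapping.datatypes.get(metric.local_name)
    if datatype:
        return _CASTS[datatype](text)
    return _infer_value(text)


def rows_to_sessions(
    rows: Iterable[Mapping[str, str]], mapping: MappingSpec
) -> list[SessionRecord]:
    """Group long-format rows into :class:`SessionRecord` objects.

    Rows are grouped by session id in first-appearance order; per metric
    the values are ordered by the (1-based) iteration column, which must
    be contiguous and free of duplicates.
    """
    col = mapping.columns
    grouped: dict[str, dict] = {}
    for i, row in enumerate(rows, start=1):
        try:
            sid = row[col["session_id"]]
        except KeyError as exc:
            raise ConversionError(f"row {i} lacks bound column {exc}") from exc
        bucket = grouped.setdefault(
            sid, {"meta": None, "metrics": {}}
        )
        meta = (
            _mint_player(row[col["player_id"]], mapping),
            normalize_iri(row[col["game_iri"]]),
            row.get(col.get("site_iri", ""), "") or None,
            row[col["start"]],
            row[col["end"]],
        )
        if bucket["meta"] is None:
            bucket["meta"] = meta
        elif bucket["meta"] != meta:
            raise ConversionError(
                f"session {sid!r}: inconsistent player/game/site/time fields across rows"
            )
        metric = _metric_iri(row[col["metric"]])
        unit_col = col.get("unit")
        unit = row.get(unit_col, "") if unit_col else ""
        try:
            iteration = int(row[col["iteration"]])
        except ValueError as exc:
            raise ConversionError(f"session {sid!r}: non-integer iteration") from exc
        if iteration < 1:
            raise ConversionError(f"session {sid!r}: iteration must be positive")
        per_metric = bucket["metrics"].setdefault(metric, {"unit": unit or None, "values": {}})
        if iteration in per_metric["values"]:
            raise ConversionError(
                f"duplicate (session, metric, iteration) = ({sid!r}, {metric}, {iteration})"
            )
        per_metric["values"][iteration] = _cast_value(row[col["value"]], metric, mapping)

    sessions = []
    for sid, bucket in grouped.items():
        player, game, site, start_text, end_text = bucket["meta"]
        observations = []
        for metric, data in bucket["metrics"].items():
            indices = sorted(data["values"])
            if indices != list(range(1, len(indices) + 1)):
                missing = sorted(set(range(1, max(indices) + 1)) - set(indices))
                raise ConversionError(
                    f"session {sid!r}, metric {metric}: non-contiguous iterations; "
                    f"missing {missing}"
                )
            values = tuple(data["values"][i] for i in indices)
            kinds = {type(v) for v in values}
            if kinds == {int, float}:
                values = tuple(float(v) for v in values)
            observations.append(
                MetricObservation(
                    metric=metric,
                    values=values,
                    unit=normalize_iri(data["unit"]) if data["unit"] else None,
                )
            )
        try:
            start = datetime.fromisoformat(start_text)
            end = datetime.fromisoformat(end_text)
        except ValueError as exc:
            raise ConversionError(f"session {sid!r}: unparsable timestamp: {exc}") from exc
        sessions.append(
            SessionRecord(
                session_id=sid,
                game=game,
                player=player,
                site=normalize_iri(site) if site else None,
                start=start,
                end=end,
                observations=tuple(observations),
            )
        )
    return sessions


def read_csv_rows(source: Union[str, Path]) -> list[dict[str, str]]:
    """Read an RFC-4180 CSV (UTF-8, header row) into row dicts."""
    path = Path(source)
    text = path.read_text(encoding="utf-8") if path.exists() else str(source)
    return list(csv.DictReader(io.StringIO(text)))


# ---------------------------------------------------------------------------
# Inverse direction: session records -> CSV log (the simulator's output
# format; feeding it back through rows_to_sessions closes the loop)

_CSV_FIELDS = (
    "session_id", "player_id", "game", "site", "start", "end",
    "metric", "unit", "iteration", "value",
)


def _value_text(value: MetricValue) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    return repr(value) if isinstance(value, float) else str(value)


def sessions_to_rows(sessions: Sequence[SessionRecord]) -> list[dict[str, str]]:
    """Flatten sessions to long-format rows matching
    :func:`default_session_mapping`."""
    rows = []
    for session in sessions:
        if not session.session_id:
            raise ConversionError("CSV export requires every session to carry a session_id")
        for obs in session.observations:
            for i, value in enumerate(obs.values, start=1):
                rows.append(
                    {
                        "session_id": session.session_id,
                        "player_id": session.player.local_name,
                        "game": str(session.game),
                        "site": str(session.site) if session.site else "",
                        "start": session.start.isoformat(),
                        "end": session.end.isoformat(),
                        "metric": str(obs.metric),
                        "unit": str(obs.unit) if obs.unit else "",
                        "iteration": str(i),
                        "value": _value_text(value),
                    }
                )
    return rows


def write_sessions_csv(sessions: Sequence[SessionRecord], path: Union[str, Path]) -> None:
    """Write the long-format CSV session log."""
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.DictWriter(handle, fieldnames=_CSV_FIELDS)
        writer.writeheader()
        writer.writerows(sessions_to_rows(sessions))
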