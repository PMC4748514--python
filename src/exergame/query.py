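"""SPARQL evaluation over exergame graphs, plus a record-level oracle.

``run_query`` evaluates any SPARQL SELECT over an in-memory graph.
``metric_at_iteration`` ships the canned query of the published dataset
(all values of one metric at one iteration, with player and session start
date); its text is a reconstruction from the described triple structure,
stored in ``queries/metric_at_iteration.rq``.

``oracle_metric_at_iteration`` answers the same question by scanning
:class:`~exergame.records.SessionRecord` objects directly -- a deliberately
independent implementation used to cross-check the graph-side query.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from string import Template
from typing import Sequence

from rdflib import BNode, Graph, Literal

from .namespaces import RDF_NS, Iri, default_terms
from .records import SessionRecord

__all__ = [
    "ResultTable",
    "QueryError",
    "run_query",
    "metric_at_iteration",
    "oracle_metric_at_iteration",
    "canned_query_text",
]


class QueryError(ValueError):
    """A SPARQL query could not be parsed or evaluated."""


@dataclass(frozen=True)
class ResultTable:
    """A SPARQL SELECT solution sequence: ordered columns, value rows."""

    columns: tuple[str, ...]
    rows: tuple[tuple, ...]

    def __post_init__(self) -> None:
        for row in self.rows:
            if len(row) != len(self.columns):
                raise ValueError(
                    f"row arity {len(row)} does not match {len(self.columns)} columns"
                )

    def __len__(self) -> int:
        return len(self.rows)

    def to_tsv(self) -> str:
        lines = ["\t".join(self.columns)]
        for row in self.rows:
            lines.append("\t".join("" if v is None else str(v) for v in row))
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        def enc(v):
            if hasattr(v, "isoformat"):
                return v.isoformat()
            return v

        return json.dumps(
            [dict(zip(self.columns, (enc(v) for v in row))) for row in self.rows]
        )


def _term_to_python(term):
    if term is None:
        return None
    if isinstance(term, Literal):
        py = term.toPython()
        return float(py) if type(py).__name__ == "Decimal" else py
    if isinstance(term, BNode):
        return f"_:{term}"
    return str(term)


def run_query(graph: Graph, sparql_text: str) -> ResultTable:
    """Evaluate a SPARQL SELECT over *graph*.

    The default prefix table is available without declaration; results are
    converted to plain Python values (datetimes, bools, numbers, IRI
    strings).
    """
    terms = default_terms()
    try:
        result = graph.query(
            sparql_text, initNs={k: str(v) for k, v in terms.prefixes.items()}
        )
    except Exception as exc:
        raise QueryError(f"SPARQL query failed: {exc}") from exc
    if result.type != "SELECT":
        raise QueryError(f"only SELECT queries are supported, got {result.type}")
    columns = tuple(str(v) for v in result.vars)
    rows = tuple(
        tuple(_term_to_python(binding[var]) for var in result.vars) for binding in result
    )
    return ResultTable(columns=columns, rows=rows)


def canned_query_text(metric: Iri, iteration: int) -> str:
    """The canned metric-at-iteration query with placeholders filled in."""
    if iteration < 1:
        raise ValueError(f"iteration must be >= 1, got {iteration}")
    template = (
        resources.files("exergame").joinpath("queries/metric_at_iteration.rq").read_text()
    )
    direct = ""
    if iteration == 1:
        # A single iteration may be encoded as a direct literal, no Seq.
        direct = "UNION { ?relation exergame:metricValue ?value . FILTER(isLiteral(?value)) }"
    return Template(template).substitute(
        metric=str(Iri(metric)),
        member=f"{RDF_NS}_{iteration}",
        direct=direct,
    )


def metric_at_iteration(graph: Graph, metric: Iri, iteration: int) -> ResultTable:
    """All (player, startDateTime, value) rows for *metric* at the given
    1-based *iteration* across every session in *graph*."""
    table = run_query(graph, canned_query_text(metric, iteration))
    return ResultTable(
        columns=table.columns, rows=tuple(sorted(table.rows, key=_row_key))
    )


def _row_key(row):
    return tuple(str(v) for v in row)


def oracle_metric_at_iteration(
    sessions: Sequence[SessionRecord], metric: Iri, iteration: int
) -> ResultTable:
    """Record-level oracle for :func:`metric_at_iteration`: a pure scan
    over ``MetricObservation.values``."""
    if iteration < 1:
        raise ValueError(f"iteration must be >= 1, got {iteration}")
    rows = []
    for session in sessions:
        for obs in session.observations:
            if obs.metric == metric and obs.iterations >= iteration:
                rows.append((str(session.player), session.start, obs.values[iteration - 1]))
    return ResultTable(
        columns=("player", "startDateTime", "value"),
        rows=tuple(sorted(rows, key=_row_key)),
    )
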