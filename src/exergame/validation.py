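"""Structural validation of exergame RDF graphs.

Checks codify the session model's structural rules plus the deployment's
anonymity requirement (nothing identifying a patient may be stored; a
player is a plain opaque identifier).  Violations are returned as data,
never raised, and validation is pure -- the graph is not mutated.

Two profiles:

``compat``
    The rules every conformant graph must satisfy: mandatory session
    links, time ordering, well-formed metric relations and sequences,
    no personal identifiers on player nodes, no unregistered terms in
    the exergame namespace.
``strict``
    Additionally: a unit on every metric relation (the published model
    says metrics carry both value and unit, but the worked example shows
    relations without one), no single-member ``rdf:Seq``, and a warning
    when a session has no site.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from datetime import datetime
from enum import Enum
from typing import Iterable, Optional

from rdflib import RDF, Graph, Literal, URIRef

from .namespaces import (
    EXERGAME_NS,
    FOAF_NS,
    METRIC_NS,
    VCARD_NS,
    OntologyTerms,
    default_terms,
)

__all__ = ["Code", "Violation", "validate_graph", "DEFAULT_PII_PREDICATES"]

_MEMBER_RE = re.compile(r"^http://www\.w3\.org/1999/02/22-rdf-syntax-ns#_([1-9][0-9]*)$")


class Code(str, Enum):
    MISSING_LINK = "MISSING_LINK"
    TIME_ORDER = "TIME_ORDER"
    SEQ_GAP = "SEQ_GAP"
    SEQ_SINGLETON = "SEQ_SINGLETON"
    UNKNOWN_METRIC = "UNKNOWN_METRIC"
    UNIT_MISSING = "UNIT_MISSING"
    PII_PRESENT = "PII_PRESENT"
    NAMESPACE_DRIFT = "NAMESPACE_DRIFT"


@dataclass(frozen=True)
class Violation:
    """One structural violation: a closed-enum code, the offending node,
    and a human-readable detail."""

    code: Code
    node: str
    detail: str

    def to_json(self) -> str:
        return json.dumps(
            {"code": self.code.value, "node": self.node, "detail": self.detail}
        )


#: Predicates that would identify a player (FOAF / vCard personal data).
DEFAULT_PII_PREDICATES = tuple(
    URIRef(iri)
    for iri in (
        FOAF_NS + "name",
        FOAF_NS + "givenName",
        FOAF_NS + "familyName",
        FOAF_NS + "mbox",
        FOAF_NS + "phone",
        VCARD_NS + "fn",
        VCARD_NS + "hasEmail",
        VCARD_NS + "email",
        VCARD_NS + "hasTelephone",
        VCARD_NS + "tel",
    )
)


def _as_datetime(value) -> Optional[datetime]:
    if isinstance(value, Literal):
        py = value.toPython()
        if isinstance(py, datetime):
            return py
        try:
            return datetime.fromisoformat(str(value))
        except ValueError:
            return None
    return None


def validate_graph(
    graph: Graph,
    terms: Optional[OntologyTerms] = None,
    profile: str = "compat",
    *,
    pii_predicates: Iterable[URIRef] = DEFAULT_PII_PREDICATES,
) -> list[Violation]:
    """Validate *graph* against the session model; see module docstring.

    Returns an empty list iff the graph is conformant at the chosen
    profile.
    """
    if profile not in ("strict", "compat"):
        raise ValueError(f"profile must be 'strict' or 'compat': {profile!r}")
    terms = terms or default_terms()
    p = {name: URIRef(iri) for name, iri in terms.properties.items()}
    violations: list[Violation] = []
    strict = profile == "strict"

    # --- sessions -----------------------------------------------------
    session_cls = URIRef(terms.cls("GameSession"))
    mandatory = ("player", "game", "result", "startDateTime", "endDateTime")
    for sess in graph.subjects(RDF.type, session_cls):
        for name in mandatory:
            count = sum(1 for _ in graph.objects(sess, p[name]))
            if count != 1:
                violations.append(
                    Violation(
                        Code.MISSING_LINK,
                        str(sess),
                        f"expected exactly one exergame:{name}, found {count}",
                    )
                )
        if strict and next(graph.objects(sess, p["site"]), None) is None:
            violations.append(
                Violation(
                    Code.MISSING_LINK,
                    str(sess),
                    "no exergame:site (warning: site is optional)",
                )
            )
        starts = [_as_datetime(v) for v in graph.objects(sess, p["startDateTime"])]
        ends = [_as_datetime(v) for v in graph.objects(sess, p["endDateTime"])]
        if len(starts) == 1 and len(ends) == 1 and starts[0] and ends[0]:
            if starts[0] > ends[0]:
                violations.append(
                    Violation(
                        Code.TIME_ORDER,
                        str(sess),
                        f"start {starts[0].isoformat()} is after end {ends[0].isoformat()}",
                    )
                )

    # --- metric relations ---------------------------------------------
    for rel in graph.objects(None, p["metricRelation"]):
        names = list(graph.objects(rel, p["metricName"]))
        if len(names) != 1:
            violations.append(
                Violation(
                    Code.MISSING_LINK,
                    str(rel),
                    f"expected exactly one exergame:metricName, found {len(names)}",
                )
            )
        elif not (isinstance(names[0], URIRef) and str(names[0]).startswith(METRIC_NS)):
            violations.append(
                Violation(
                    Code.UNKNOWN_METRIC,
                    str(rel),
                    f"metricName {names[0]} is not an IRI in the shared metric namespace",
                )
            )
        values = list(graph.objects(rel, p["metricValue"]))
        if len(values) != 1:
            violations.append(
                Violation(
                    Code.MISSING_LINK,
                    str(rel),
                    f"expected exactly one exergame:metricValue, found {len(values)}",
                )
            )
        else:
            value = values[0]
            if not isinstance(value, Literal):
                members = {}
                for pred in graph.predicates(value, None):
                    m = _MEMBER_RE.match(str(pred))
                    if m:
                        members[int(m.group(1))] = True
                if not members:
                    violations.append(
                        Violation(
                            Code.SEQ_GAP,
                            str(value),
                            "metricValue node is neither a literal nor a populated rdf:Seq",
                        )
                    )
                else:
                    expected = set(range(1, max(members) + 1))
                    if set(members) != expected:
                        missing = sorted(expected - set(members))
                        violations.append(
                            Violation(
                                Code.SEQ_GAP,
                                str(value),
                                f"non-contiguous Seq indices; missing rdf:_{missing}",
                            )
                        )
                    if strict and len(members) == 1:
                        violations.append(
                            Violation(
                                Code.SEQ_SINGLETON,
                                str(value),
                                "rdf:Seq of length 1 (a single iteration should be a direct literal)",
                            )
                        )
        if strict and next(graph.objects(rel, p["metricUnit"]), None) is None:
            violations.append(
                Violation(Code.UNIT_MISSING, str(rel), "metric relation carries no unit")
            )

    # --- anonymity ----------------------------------------------------
    pii = tuple(pii_predicates)
    for player in set(graph.objects(None, p["player"])):
        for pred in pii:
            for obj in graph.objects(player, pred):
                violations.append(
                    Violation(
                        Code.PII_PRESENT,
                        str(player),
                        f"player node carries personal predicate {pred}",
                    )
                )

    # --- namespace drift ----------------------------------------------
    registered = set(terms.classes.values()) | set(terms.properties.values())
    used = set()
    for s, pred, o in graph:
        if str(pred).startswith(EXERGAME_NS):
            used.add(str(pred))
        if pred == RDF.type and str(o).startswith(EXERGAME_NS):
            used.add(str(o))
    for iri in sorted(used - registered):
        violations.append(
            Violation(
                Code.NAMESPACE_DRIFT,
                iri,
                "exergame-namespace term is not in the term registry",
            )
        )

    return violations
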