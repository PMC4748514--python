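"""Conversion between records and RDF graphs, plus serialization.

The emitted triple structure follows the published session model exactly:

* each game session is a node typed ``exergame:GameSession`` carrying
  ``exergame:{result, site, startDateTime, endDateTime, player, game}``;
* its result is a node typed ``exergame:Result``;
* because RDF properties are binary, each (result, metric, unit, value)
  association goes through an auxiliary ``exergame:MetricRelation`` node
  with ``exergame:metricName`` and ``exergame:metricValue``;
* a single-iteration value is attached as a literal directly; with two or
  more iterations ``exergame:metricValue`` points to an ``rdf:Seq`` whose
  membership properties ``rdf:_1`` ... ``rdf:_n`` order the values.

Sessions, results, relations and sequences are blank nodes by default, as
in the published dataset; pass ``skolem_base`` to mint resolvable IRIs
instead (useful before triplestore upload).  Graphs are plain
``rdflib.Graph`` objects throughout.
"""

from __future__ import annotations

import itertools
import re
from datetime import datetime
from decimal import Decimal
from typing import Iterable, Optional

from rdflib import RDF, RDFS, XSD, BNode, Graph, Literal, URIRef
from rdflib.compare import isomorphic as _rdflib_isomorphic

from .namespaces import (
    NCI_NS,
    OWL_NS,
    FOAF_NS,
    Iri,
    OntologyTerms,
    default_terms,
    normalize_iri,
)
from .records import (
    GameDescription,
    MetricObservation,
    MetricValue,
    PlayerRecord,
    SessionRecord,
)

__all__ = [
    "session_to_graph",
    "sessions_to_graph",
    "game_to_graph",
    "player_to_graph",
    "graph_to_sessions",
    "serialize",
    "parse",
    "canonicalize",
    "isomorphic",
    "StructuralViolationError",
    "ParseError",
    "FORMATS",
]

#: Supported serialization formats mapped to rdflib format names.
FORMATS = {"turtle": "turtle", "rdfxml": "xml", "ntriples": "nt11"}

_RDF_MEMBER_RE = re.compile(r"^http://www\.w3\.org/1999/02/22-rdf-syntax-ns#_([1-9][0-9]*)$")

_label_counter = itertools.count(1)


class StructuralViolationError(ValueError):
    """A graph lacks a mandatory link or has a malformed sequence."""

    def __init__(self, node: object, predicate: str, message: str):
        self.node = str(node)
        self.predicate = predicate
        super().__init__(f"{message} (node {node}, predicate {predicate})")


class ParseError(ValueError):
    """An RDF document could not be parsed."""


def _safe_label(text: str) -> str:
    return re.sub(r"[^A-Za-z0-9_.\-]", "_", text)


def _new_graph(terms: OntologyTerms) -> Graph:
    g = Graph()
    for prefix, ns in terms.prefixes.items():
        g.bind(prefix, ns, override=True)
    return g


def _value_literal(value: MetricValue) -> Literal:
    if isinstance(value, bool):
        return Literal(value)
    if isinstance(value, int):
        return Literal(value)
    if isinstance(value, float):
        # xsd:decimal forbids exponent notation; format positionally and
        # keep a decimal point so Turtle re-reads the value as a decimal.
        lexical = format(Decimal(repr(value)), "f")
        if "." not in lexical:
            lexical += ".0"
        return Literal(lexical, datatype=XSD.decimal)
    return Literal(value)


def _node_factory(session: SessionRecord, skolem_base: Optional[str]):
    """Return ``make(suffix)`` minting the session's subject nodes."""
    if skolem_base is not None:
        if not session.session_id:
            raise ValueError("skolemization requires a session_id")
        base = skolem_base.rstrip("/") + "/" + _safe_label(session.session_id)

        def make(suffix: str = "") -> URIRef:
            return URIRef(base + ("/" + suffix if suffix else ""))

    else:
        # "id-" prefix keeps labels valid NCNames (RDF/XML nodeID) even
        # for identifiers starting with a digit; stripped on read-back.
        stem = (
            "id-" + _safe_label(session.session_id)
            if session.session_id
            else f"genid-session{next(_label_counter)}"
        )

        def make(suffix: str = "") -> BNode:
            return BNode(stem + (("-" + suffix) if suffix else ""))

    return make


def session_to_graph(
    session: SessionRecord,
    terms: Optional[OntologyTerms] = None,
    *,
    skolem_base: Optional[str] = None,
    graph: Optional[Graph] = None,
) -> Graph:
    """Emit one session as RDF triples (see module docstring for shape)."""
    terms = terms or default_terms()
    try:
        cls = {name: URIRef(terms.cls(name)) for name in ("GameSession", "Result")}
        prop = {
            name: URIRef(terms.prop(name))
            for name in (
                "result",
                "site",
                "startDateTime",
                "endDateTime",
                "player",
                "game",
                "metricRelation",
                "metricName",
                "metricValue",
                "metricUnit",
            )
        }
    except KeyError as exc:  # pragma: no cover - registry misconfiguration
        raise KeyError(f"term registry is missing {exc}") from exc

    g = graph if graph is not None else _new_graph(terms)
    make = _node_factory(session, skolem_base)

    sess = make()
    res = make("Result")
    g.add((sess, RDF.type, cls["GameSession"]))
    g.add((sess, prop["result"], res))
    if session.site:
        g.add((sess, prop["site"], URIRef(session.site)))
    g.add((sess, prop["startDateTime"], Literal(session.start)))
    g.add((sess, prop["endDateTime"], Literal(session.end)))
    g.add((sess, prop["player"], URIRef(session.player)))
    g.add((sess, prop["game"], URIRef(session.game)))
    g.add((res, RDF.type, cls["Result"]))

    for i, obs in enumerate(session.observations, start=1):
        rel = make(f"MetricRelation{i}")
        g.add((res, prop["metricRelation"], rel))
        g.add((rel, prop["metricName"], URIRef(obs.metric)))
        if obs.unit:
            g.add((rel, prop["metricUnit"], URIRef(obs.unit)))
        if obs.iterations == 1:
            g.add((rel, prop["metricValue"], _value_literal(obs.values[0])))
        else:
            seq = make(f"Seq{i}")
            g.add((rel, prop["metricValue"], seq))
            g.add((seq, RDF.type, RDF.Seq))
            for n, value in enumerate(obs.values, start=1):
                g.add((seq, URIRef(f"{RDF}_{n}"), _value_literal(value)))
    return g


def sessions_to_graph(
    sessions: Iterable[SessionRecord],
    terms: Optional[OntologyTerms] = None,
    *,
    skolem_base: Optional[str] = None,
) -> Graph:
    """Emit many sessions into a single graph."""
    terms = terms or default_terms()
    g = _new_graph(terms)
    for s in sessions:
        session_to_graph(s, terms, skolem_base=skolem_base, graph=g)
    return g


def game_to_graph(
    game: GameDescription,
    terms: Optional[OntologyTerms] = None,
    *,
    graph: Optional[Graph] = None,
) -> Graph:
    """Emit a game description: the game instance, its GoalMetric
    instances, controllers (with ``owl:sameAs`` links when set),
    presentation hardware, exercise and goal annotations."""
    terms = terms or default_terms()
    g = graph if graph is not None else _new_graph(terms)
    p = {name: URIRef(terms.prop(name)) for name in terms.properties}
    c = {name: URIRef(terms.cls(name)) for name in terms.classes}
    same_as = URIRef(OWL_NS + "sameAs")

    game_node = URIRef(game.iri)
    g.add((game_node, RDF.type, c["Game"]))
    g.add((game_node, RDFS.label, Literal(game.label)))

    for m in game.metrics:
        node = URIRef(m.iri)
        g.add((game_node, p["gameMetric"], node))
        g.add((node, RDF.type, c["GoalMetric"]))
        g.add((node, RDFS.label, Literal(m.label)))
        if m.concept:
            g.add((node, p["concept"], URIRef(m.concept)))
        if m.default_unit:
            g.add((node, p["metricUnit"], URIRef(m.default_unit)))
            g.add((URIRef(m.default_unit), RDF.type, c["Unit"]))

    for ctrl in game.controllers:
        node = URIRef(ctrl.iri)
        g.add((game_node, p["gameController"], node))
        g.add((node, RDF.type, c["GameController"]))
        g.add((node, RDFS.label, Literal(ctrl.label)))
        if ctrl.same_as:
            g.add((node, same_as, URIRef(ctrl.same_as)))

    for hw in game.presentation_hardware:
        node = URIRef(hw.iri)
        g.add((game_node, p["presentationHardware"], node))
        g.add((node, RDF.type, c["PresentationHardware"]))
        g.add((node, RDFS.label, Literal(hw.label)))

    if game.exercise:
        ex = game.exercise
        node = URIRef(ex.iri)
        g.add((game_node, p["gameExercise"], node))
        g.add((node, RDF.type, c["Exercise"]))
        g.add((node, RDFS.label, Literal(ex.label)))
        for muscle in ex.muscles:
            g.add((node, p["involvesMuscle"], URIRef(muscle.iri)))
            if muscle.source == "ncit_subclass":
                g.add((URIRef(muscle.iri), RDFS.subClassOf, URIRef(NCI_NS + "Muscle")))
        for item in ex.equipment:
            g.add((node, p["equipment"], Literal(item)))
        for item in ex.benefits:
            g.add((node, p["benefit"], Literal(item)))

    for goal in game.goals:
        pred = p["gameGoal"] if goal.kind == "game_goal" else p["exerciseGoal"]
        g.add((game_node, pred, Literal(goal.text)))
    return g


def player_to_graph(
    player: PlayerRecord,
    terms: Optional[OntologyTerms] = None,
    *,
    graph: Optional[Graph] = None,
) -> Graph:
    """Emit a player node: typed ``exergame:Player`` and ``foaf:Person``,
    never with identifying literals (demographics stay in memory)."""
    terms = terms or default_terms()
    g = graph if graph is not None else _new_graph(terms)
    node = URIRef(player.iri)
    g.add((node, RDF.type, URIRef(terms.cls("Player"))))
    g.add((node, RDF.type, URIRef(FOAF_NS + "Person")))
    return g


# ---------------------------------------------------------------------------
# Graph -> records


def _one(g: Graph, node, pred: URIRef, what: str):
    values = list(g.objects(node, pred))
    if len(values) != 1:
        raise StructuralViolationError(
            node, str(pred), f"expected exactly one {what}, found {len(values)}"
        )
    return values[0]


def _literal_to_python(lit) -> MetricValue:
    if not isinstance(lit, Literal):
        raise StructuralViolationError(lit, "metricValue", "metric value is not a literal")
    if lit.datatype == XSD.boolean:
        return bool(lit.toPython())
    if lit.datatype in (XSD.integer, XSD.int, XSD.long, XSD.short):
        return int(lit.toPython())
    if lit.datatype in (XSD.decimal, XSD.double, XSD.float):
        return float(lit)
    text = str(lit)
    # Compat: published excerpts print plain TRUE/FALSE for booleans.
    if text.lower() in ("true", "false"):
        return text.lower() == "true"
    try:
        return int(text)
    except ValueError:
        pass
    try:
        return float(text)
    except ValueError:
        return text


def _seq_values(g: Graph, seq_node) -> tuple[MetricValue, ...]:
    members: dict[int, MetricValue] = {}
    for pred, obj in g.predicate_objects(seq_node):
        m = _RDF_MEMBER_RE.match(str(pred))
        if m:
            members[int(m.group(1))] = _literal_to_python(obj)
    if not members:
        raise StructuralViolationError(seq_node, "rdf:_n", "rdf:Seq node has no members")
    expected = set(range(1, max(members) + 1))
    if set(members) != expected:
        missing = sorted(expected - set(members))
        raise StructuralViolationError(
            seq_node, "rdf:_n", f"non-contiguous Seq indices; missing rdf:_{missing}"
        )
    return tuple(members[i] for i in range(1, max(members) + 1))


def _coerce_datetime(value, node, predicate: str) -> datetime:
    if isinstance(value, Literal):
        py = value.toPython()
        if isinstance(py, datetime):
            return py
        try:
            return datetime.fromisoformat(str(value).replace(" 02:00", "+02:00"))
        except ValueError:
            pass
    raise StructuralViolationError(node, predicate, f"unparsable dateTime {value!r}")


def _session_id_from_node(node) -> Optional[str]:
    if isinstance(node, URIRef):
        return Iri(str(node)).local_name
    label = str(node)
    if label.startswith("id-"):
        return label[3:]
    if label.startswith("genid-session") or re.fullmatch(r"[NnCc][0-9a-fA-F]{8,}", label):
        return None  # auto-generated label, not an identifier
    return label


def graph_to_sessions(
    graph: Graph, terms: Optional[OntologyTerms] = None
) -> list[SessionRecord]:
    """Read every ``exergame:GameSession`` node back into a
    :class:`SessionRecord`; inverse of :func:`session_to_graph`.

    Seq members are restored in ``rdf:_n`` index order; non-contiguous
    indices and missing mandatory links raise
    :class:`StructuralViolationError` naming the node and predicate.
    """
    terms = terms or default_terms()
    p = {name: URIRef(terms.prop(name)) for name in terms.properties}
    sessions = []
    for sess in sorted(graph.subjects(RDF.type, URIRef(terms.cls("GameSession"))), key=str):
        player = _one(graph, sess, p["player"], "exergame:player")
        game = _one(graph, sess, p["game"], "exergame:game")
        result = _one(graph, sess, p["result"], "exergame:result")
        start = _coerce_datetime(
            _one(graph, sess, p["startDateTime"], "exergame:startDateTime"),
            sess, "exergame:startDateTime",
        )
        end = _coerce_datetime(
            _one(graph, sess, p["endDateTime"], "exergame:endDateTime"),
            sess, "exergame:endDateTime",
        )
        sites = list(graph.objects(sess, p["site"]))
        site = normalize_iri(str(sites[0])) if sites else None

        observations = []
        for rel in graph.objects(result, p["metricRelation"]):
            metric = _one(graph, rel, p["metricName"], "exergame:metricName")
            value_node = _one(graph, rel, p["metricValue"], "exergame:metricValue")
            units = list(graph.objects(rel, p["metricUnit"]))
            unit = normalize_iri(str(units[0])) if units else None
            if isinstance(value_node, Literal):
                values: tuple[MetricValue, ...] = (_literal_to_python(value_node),)
            else:
                values = _seq_values(graph, value_node)
            # Mixed int/float members collapse to float (one datatype per
            # observation).
            kinds = {type(v) for v in values}
            if kinds == {int, float}:
                values = tuple(float(v) for v in values)
            observations.append(
                MetricObservation(metric=normalize_iri(str(metric)), values=values, unit=unit)
            )
        if not observations:
            raise StructuralViolationError(
                result, str(p["metricRelation"]), "result node carries no metric relations"
            )
        sessions.append(
            SessionRecord(
                session_id=_session_id_from_node(sess),
                game=normalize_iri(str(game)),
                player=normalize_iri(str(player)),
                site=site,
                start=start,
                end=end,
                observations=tuple(observations),
            )
        )
    return sessions


# ---------------------------------------------------------------------------
# Serialization


def serialize(graph: Graph, format: str = "turtle") -> str:
    """Serialize to Turtle, RDF/XML or N-Triples."""
    if format not in FORMATS:
        raise ValueError(f"unsupported format {format!r}; choose from {sorted(FORMATS)}")
    if format == "turtle" and len(graph) == 0:
        # keep the prefix block even when there are no statements
        return "".join(
            f"@prefix {prefix}: <{ns}> .\n" for prefix, ns in sorted(graph.namespaces())
        )
    return graph.serialize(format=FORMATS[format])


def parse(
    text: str, format: str = "turtle", terms: Optional[OntologyTerms] = None
) -> Graph:
    """Parse an RDF document; exergame IRIs under the ``purl.com`` host
    alias are normalized to ``purl.org``."""
    if format not in FORMATS:
        raise ValueError(f"unsupported format {format!r}; choose from {sorted(FORMATS)}")
    raw = Graph()
    try:
        raw.parse(data=text, format=FORMATS[format])
    except Exception as exc:
        raise ParseError(f"cannot parse {format} document: {exc}") from exc
    terms = terms or default_terms()
    g = _new_graph(terms)

    def norm(term):
        if isinstance(term, URIRef) and str(term).startswith("http://purl.com/net/exergame/"):
            return URIRef(normalize_iri(str(term)))
        return term

    for s, pred, o in raw:
        g.add((norm(s), norm(pred), norm(o)))
    return g


def _bnode_adjacency(graph: Graph):
    """Per blank node: ground signature lines and bnode-neighbor edges."""
    ground: dict = {}
    edges: dict = {}
    for s, pred, o in graph:
        s_b, o_b = isinstance(s, BNode), isinstance(o, BNode)
        if s_b:
            ground.setdefault(s, []).append(
                "O|" + pred.n3() + "|" + ("_" if o_b else o.n3())
            )
            edges.setdefault(s, [])
            if o_b:
                edges[s].append(("O", pred.n3(), o))
        if o_b:
            ground.setdefault(o, []).append(
                "S|" + pred.n3() + "|" + ("_" if s_b else s.n3())
            )
            edges.setdefault(o, [])
            if s_b:
                edges[o].append(("S", pred.n3(), s))
    return ground, edges


def _hash(text: str) -> str:
    import hashlib

    return hashlib.sha256(text.encode("utf-8")).hexdigest()


def _refine(colors: dict, edges: dict) -> dict:
    """Iterated neighbourhood hashing until the colour partition is stable."""
    distinct = len(set(colors.values()))
    while True:
        new = {}
        for node, color in colors.items():
            parts = sorted(f"{tag}|{pred}|{colors[n]}" for tag, pred, n in edges[node])
            new[node] = _hash(color + "#" + "#".join(parts))
        new_distinct = len(set(new.values()))
        if new_distinct == distinct:
            return new
        colors, distinct = new, new_distinct


def _render(graph: Graph, colors: dict) -> str:
    order = sorted(colors, key=lambda b: colors[b])
    relabel = {b: BNode(f"c14n{i}") for i, b in enumerate(order)}
    out = Graph()
    for s, pred, o in graph:
        out.add((relabel.get(s, s), pred, relabel.get(o, o)))
    lines = sorted(line for line in out.serialize(format="nt11").splitlines() if line.strip())
    return "\n".join(lines) + "\n"


def _canonical_text(graph: Graph, colors: dict, edges: dict, depth: int = 0) -> str:
    classes: dict = {}
    for node, color in colors.items():
        classes.setdefault(color, []).append(node)
    tied = sorted(c for c, nodes in classes.items() if len(nodes) > 1)
    if not tied or depth > 16:
        return _render(graph, colors)
    # Individualize each member of the first tied class in turn and keep
    # the lexicographically least canonical text (label-independent).
    best = None
    for node in classes[tied[0]]:
        trial = dict(colors)
        trial[node] = _hash(colors[node] + "!")
        text = _canonical_text(graph, _refine(trial, edges), edges, depth + 1)
        if best is None or text < best:
            best = text
    return best


def canonicalize(graph: Graph) -> str:
    """Sorted N-Triples text with deterministic blank-node labels.

    Output is identical for any two graphs differing only in blank-node
    labels, enabling bit-exact comparison of independently built graphs.
    Labels are assigned by iterated neighbourhood hashing (colour
    refinement) over the blank nodes, grounded in the IRIs and literals
    around them; residual symmetric nodes are resolved by individualizing
    each candidate and keeping the least resulting text.
    """
    ground, edges = _bnode_adjacency(graph)
    if not ground:
        return _render(graph, {})
    colors = {b: _hash("\n".join(sorted(lines))) for b, lines in ground.items()}
    return _canonical_text(graph, _refine(colors, edges), edges)


def isomorphic(a: Graph, b: Graph) -> bool:
    """Graph isomorphism up to blank-node relabeling."""
    return _rdflib_isomorphic(a, b)
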