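from datetime import datetime, timedelta, timezone
from itertools import combinations

import pytest
from hypothesis import HealthCheck, given, settings
from rdflib import RDF, BNode, Graph, Literal, URIRef

from exergame import (
    Iri,
    MetricObservation,
    SessionRecord,
    StructuralViolationError,
    canonicalize,
    game_to_graph,
    graph_to_sessions,
    isomorphic,
    parse,
    serialize,
    session_to_graph,
)
from exergame.namespaces import EXERGAME_NS, METRIC_NS, RDF_NS
from exergame.records import GameDescription, define_metric

from .strategies import sessions

EX = EXERGAME_NS
SUCCESS = Iri(METRIC_NS + "Success")
TZ = timezone(timedelta(hours=2))


def _shuffle_bnode_labels(graph: Graph) -> Graph:
    relabel: dict = {}
    out = Graph()
    for s, p, o in graph:
        def r(t):
            if isinstance(t, BNode):
                return relabel.setdefault(t, BNode())
            return t
        out.add((r(s), p, r(o)))
    return out


class TestSessionEmission:
    def test_result_node_has_three_metric_relations(self, fixture_graph):
        (result,) = fixture_graph.objects(None, URIRef(EX + "result"))
        relations = list(fixture_graph.objects(result, URIRef(EX + "metricRelation")))
        assert len(relations) == 3

    def test_success_values_form_rdf_seq(self, fixture_graph):
        rel = next(
            s
            for s in fixture_graph.subjects(URIRef(EX + "metricName"), URIRef(SUCCESS))
        )
        (seq,) = fixture_graph.objects(rel, URIRef(EX + "metricValue"))
        assert (seq, RDF.type, RDF.Seq) in fixture_graph
        members = [
            bool(fixture_graph.value(seq, URIRef(f"{RDF_NS}_{i}")).toPython())
            for i in range(1, 7)
        ]
        assert members == [True, True, False, True, False, True]
        assert fixture_graph.value(seq, URIRef(f"{RDF_NS}_7")) is None

    def test_exactly_one_session_and_result_node(self, fixture_graph):
        assert len(list(fixture_graph.subjects(RDF.type, URIRef(EX + "GameSession")))) == 1
        assert len(list(fixture_graph.subjects(RDF.type, URIRef(EX + "Result")))) == 1

    def test_single_iteration_emits_direct_literal(self):
        session = SessionRecord(
            session_id="one",
            game=Iri("http://example.org/g"),
            player=Iri("http://example.org/p1"),
            start=datetime(2014, 9, 22, 10, 0, tzinfo=TZ),
            end=datetime(2014, 9, 22, 10, 5, tzinfo=TZ),
            observations=(MetricObservation(metric=SUCCESS, values=(42,)),),
        )
        g = session_to_graph(session)
        (rel,) = g.subjects(URIRef(EX + "metricName"), URIRef(SUCCESS))
        (value,) = g.objects(rel, URIRef(EX + "metricValue"))
        assert isinstance(value, Literal) and value.toPython() == 42
        assert (None, RDF.type, RDF.Seq) not in g

    def test_zero_observation_sessions_cannot_exist(self):
        with pytest.raises(ValueError):
            SessionRecord(
                session_id="none",
                game=Iri("http://example.org/g"),
                player=Iri("http://example.org/p1"),
                start=datetime(2014, 9, 22, 10, 0, tzinfo=TZ),
                end=datetime(2014, 9, 22, 10, 5, tzinfo=TZ),
                observations=(),
            )


class TestGameEmission:
    def test_kinect_same_as_dbpedia(self, fixture_game, terms):
        g = game_to_graph(fixture_game, terms)
        assert (
            URIRef("http://purl.org/net/exergame/controller#Kinect"),
            URIRef("http://www.w3.org/2002/07/owl#sameAs"),
            URIRef("http://dbpedia.org/resource/Kinect"),
        ) in g

    def test_three_goal_metric_instances(self, fixture_game, terms):
        g = game_to_graph(fixture_game, terms)
        metrics = list(g.subjects(RDF.type, URIRef(EX + "GoalMetric")))
        assert len(metrics) == 3

    def test_ncit_muscles_are_muscle_subclasses(self, fixture_game, terms):
        g = game_to_graph(fixture_game, terms)
        nci_muscle = URIRef(
            "http://ncicb.nci.nih.gov/xml/owl/EVS/Thesaurus.owl#Muscle"
        )
        subclasses = {
            str(s).rsplit("#")[-1]
            for s in g.subjects(
                URIRef("http://www.w3.org/2000/01/rdf-schema#subClassOf"), nci_muscle
            )
        }
        assert subclasses == {"Infraspinatus", "Teres_Minor", "Teres_Major"}

    def test_game_without_exercise_emits_no_exercise_triples(self, terms):
        game = GameDescription(
            iri=Iri("http://example.org/g/Plain"),
            label="Plain",
            metrics=(define_metric("Score", "score"),),
        )
        g = game_to_graph(game, terms)
        assert (None, URIRef(EX + "gameExercise"), None) not in g
        assert (None, RDF.type, URIRef(EX + "Exercise")) not in g


class TestGraphToSessions:
    def test_round_trip_fixture(self, fixture_session, fixture_graph, terms):
        assert graph_to_sessions(fixture_graph, terms) == [fixture_session]

    def test_hand_typed_worked_example(self, terms):
        # The published triple listing typed by hand: plain TRUE/FALSE
        # literals, metric IRI under the purl.com host alias.
        turtle = """
        @prefix exergame: <http://purl.org/net/exergame/ns#> .
        @prefix rdf: <http://www.w3.org/1999/02/22-rdf-syntax-ns#> .
        @prefix xsd: <http://www.w3.org/2001/XMLSchema#> .
        _:SideRaisesGameSession rdf:type exergame:GameSession ;
            exergame:result _:SideRaisesGameResult ;
            exergame:site <http://www.fitforall.gr/resources/MedicalPhysicsLaboratoryAuth> ;
            exergame:startDateTime "2014-09-22T18:09:39+02:00"^^xsd:dateTime ;
            exergame:endDateTime "2014-09-22T18:09:39+02:00"^^xsd:dateTime ;
            exergame:player <http://www.fitforall.gr/resources/player162> ;
            exergame:game <http://www.fitforall.gr/resources/SideRaisesGame> .
        _:SideRaisesGameResult rdf:type exergame:Result ;
            exergame:metricRelation _:MetricRelation1 .
        _:MetricRelation1
            exergame:metricName <http://purl.com/net/exergame/metric#Success> ;
            exergame:metricValue _:node197jv5qonx686 .
        _:node197jv5qonx686 rdf:type rdf:Seq ;
            rdf:_1 "TRUE" ; rdf:_2 "TRUE" ; rdf:_3 "FALSE" ;
            rdf:_4 "TRUE" ; rdf:_5 "FALSE" ; rdf:_6 "TRUE" .
        """
        (session,) = graph_to_sessions(parse(turtle, "turtle"), terms)
        success = session.observation(SUCCESS)
        assert success.values == (True, True, False, True, False, True)
        assert session.player == "http://www.fitforall.gr/resources/player162"
        assert session.start.isoformat() == "2014-09-22T18:09:39+02:00"

    def test_missing_mandatory_link_names_node_and_predicate(self, fixture_graph, terms):
        fixture_graph.remove((None, URIRef(EX + "player"), None))
        with pytest.raises(StructuralViolationError, match="player"):
            graph_to_sessions(fixture_graph, terms)

    @pytest.mark.parametrize(
        "present",
        # all strict subsets of {1..4} containing 1..k gaps, length <= 4:
        [c for n in (2, 3, 4) for k in range(1, n) for c in combinations(range(1, n + 1), k)
         if c != tuple(range(1, k + 1))],
    )
    def test_seq_gap_detection(self, present, terms):
        g = Graph()
        sess, res, rel, seq = BNode(), BNode(), BNode(), BNode()
        t = datetime(2014, 9, 22, 10, 0, tzinfo=TZ)
        g.add((sess, RDF.type, URIRef(EX + "GameSession")))
        g.add((sess, URIRef(EX + "player"), URIRef("http://example.org/p1")))
        g.add((sess, URIRef(EX + "game"), URIRef("http://example.org/g1")))
        g.add((sess, URIRef(EX + "startDateTime"), Literal(t)))
        g.add((sess, URIRef(EX + "endDateTime"), Literal(t)))
        g.add((sess, URIRef(EX + "result"), res))
        g.add((res, URIRef(EX + "metricRelation"), rel))
        g.add((rel, URIRef(EX + "metricName"), URIRef(SUCCESS)))
        g.add((rel, URIRef(EX + "metricValue"), seq))
        g.add((seq, RDF.type, RDF.Seq))
        for i in present:
            g.add((seq, URIRef(f"{RDF_NS}_{i}"), Literal(True)))
        with pytest.raises(StructuralViolationError, match="non-contiguous"):
            graph_to_sessions(g, terms)

    @given(session=sessions())
    @settings(max_examples=60, deadline=None, derandomize=True,
              suppress_health_check=[HealthCheck.function_scoped_fixture])
    def test_round_trip_identity_property(self, session, terms):
        assert graph_to_sessions(session_to_graph(session, terms), terms) == [session]

    def test_skolemized_round_trip(self, fixture_session, terms):
        g = session_to_graph(fixture_session, terms, skolem_base="http://example.org/id")
        assert not any(isinstance(s, BNode) for s, _, _ in g)
        assert graph_to_sessions(g, terms) == [fixture_session]


class TestSerialization:
    def test_empty_graph_serialization_only_prefixes(self, terms):
        from exergame.graphs import _new_graph

        text = serialize(_new_graph(terms), "turtle")
        lines = [l for l in text.splitlines() if l.strip()]
        assert lines and all(l.startswith("@prefix") for l in lines)

    @pytest.mark.parametrize("fmt", ["turtle", "rdfxml", "ntriples"])
    def test_round_trip_isomorphic(self, fixture_graph, fmt):
        reparsed = parse(serialize(fixture_graph, fmt), fmt)
        assert isomorphic(fixture_graph, reparsed)

    def test_cross_format_pairwise_isomorphism(self, fixture_graph):
        texts = {
            fmt: canonicalize(parse(serialize(fixture_graph, fmt), fmt))
            for fmt in ("turtle", "rdfxml", "ntriples")
        }
        assert len(set(texts.values())) == 1

    def test_parse_error_reported(self):
        with pytest.raises(ValueError, match="cannot parse"):
            parse("this is not turtle @@@", "turtle")

    def test_unsupported_format_rejected(self, fixture_graph):
        with pytest.raises(ValueError, match="unsupported"):
            serialize(fixture_graph, "jsonld")


class TestCanonicalize:
    def test_label_independence(self, fixture_graph):
        shuffled = _shuffle_bnode_labels(fixture_graph)
        assert canonicalize(fixture_graph) == canonicalize(shuffled)

    def test_sensitive_to_added_triple(self, fixture_graph):
        before = canonicalize(fixture_graph)
        fixture_graph.add(
            (URIRef("http://example.org/x"), URIRef("http://example.org/p"), Literal(1))
        )
        assert canonicalize(fixture_graph) != before

    def test_symmetric_duplicate_sessions(self, fixture_session, terms):
        from dataclasses import replace

        from exergame import sessions_to_graph

        twin = replace(fixture_session, session_id="twin")
        g = sessions_to_graph([fixture_session, twin], terms)
        assert canonicalize(g) == canonicalize(_shuffle_bnode_labels(g))

    def test_matches_golden_file(self, fixture_graph, golden_canonical):
        assert canonicalize(fixture_graph) == golden_canonical

    def test_agrees_with_independent_isomorphism_check(self, fixture_graph):
        shuffled = _shuffle_bnode_labels(fixture_graph)
        # dual route: our canonical text equality vs rdflib's isomorphism
        assert isomorphic(fixture_graph, shuffled)
        assert canonicalize(fixture_graph) == canonicalize(shuffled)
        shuffled.add((BNode(), URIRef(EX + "player"), URIRef("http://example.org/p9")))
        assert not isomorphic(fixture_graph, shuffled)
        assert canonicalize(fixture_graph) != canonicalize(shuffled)
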