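"""The validator must flag every structural rule exactly, and nothing on
conformant graphs (soundness against the emitter)."""

from datetime import datetime, timedelta, timezone

import pytest
from hypothesis import HealthCheck, given, settings
from rdflib import RDF, BNode, Literal, URIRef

from exergame import Code, canonicalize, session_to_graph, validate_graph
from exergame.namespaces import EXERGAME_NS, FOAF_NS, RDF_NS

from .strategies import sessions

EX = EXERGAME_NS
TZ = timezone(timedelta(hours=2))


def codes(violations):
    return [v.code for v in violations]


class TestFixtureValidity:
    def test_fixture_graph_is_clean(self, fixture_graph, terms):
        assert validate_graph(fixture_graph, terms) == []

    def test_strict_flags_only_the_unitless_success_relation(self, fixture_graph, terms):
        violations = validate_graph(fixture_graph, terms, profile="strict")
        assert codes(violations) == [Code.UNIT_MISSING]

    def test_validation_is_pure(self, fixture_graph, terms):
        before = canonicalize(fixture_graph)
        validate_graph(fixture_graph, terms, profile="strict")
        assert canonicalize(fixture_graph) == before


MANDATORY_SESSION_LINKS = ["player", "game", "result", "startDateTime", "endDateTime"]


class TestSingleDeletionSweep:
    """Deleting each mandatory structural element yields exactly one
    violation whose code identifies the rule (exhaustive over the
    worked-example graph)."""

    @pytest.mark.parametrize("link", MANDATORY_SESSION_LINKS)
    def test_session_link_deletion(self, fixture_graph, terms, link):
        fixture_graph.remove((None, URIRef(EX + link), None))
        violations = validate_graph(fixture_graph, terms)
        if link == "result":
            # the result (and its relations) become unreachable; the
            # missing link itself is still reported on the session node
            assert Code.MISSING_LINK in codes(violations)
            session_violations = [v for v in violations if v.code == Code.MISSING_LINK]
            assert any(link in v.detail for v in session_violations)
        else:
            assert codes(violations) == [Code.MISSING_LINK]
            assert link in violations[0].detail

    @pytest.mark.parametrize("link", ["metricName", "metricValue"])
    def test_relation_link_deletion(self, fixture_graph, terms, link):
        # delete the link from a single relation
        rel = next(fixture_graph.objects(None, URIRef(EX + "metricRelation")))
        fixture_graph.remove((rel, URIRef(EX + link), None))
        violations = validate_graph(fixture_graph, terms)
        assert codes(violations) == [Code.MISSING_LINK]
        assert link in violations[0].detail

    def test_seq_member_deletion_is_a_gap(self, fixture_graph, terms):
        seq = next(fixture_graph.subjects(RDF.type, RDF.Seq))
        fixture_graph.remove((seq, URIRef(f"{RDF_NS}_2"), None))
        violations = validate_graph(fixture_graph, terms)
        assert codes(violations) == [Code.SEQ_GAP]
        assert "_[2]" in violations[0].detail


class TestIndividualRules:
    def test_pii_on_player_node(self, fixture_graph, terms):
        fixture_graph.add(
            (
                URIRef("http://www.fitforall.gr/resources/player162"),
                URIRef(FOAF_NS + "name"),
                Literal("Jane Doe"),
            )
        )
        assert codes(validate_graph(fixture_graph, terms)) == [Code.PII_PRESENT]

    def test_time_order(self, fixture_graph, terms):
        sess = next(fixture_graph.subjects(RDF.type, URIRef(EX + "GameSession")))
        fixture_graph.remove((sess, URIRef(EX + "endDateTime"), None))
        fixture_graph.add(
            (
                sess,
                URIRef(EX + "endDateTime"),
                Literal(datetime(2014, 9, 22, 17, 0, tzinfo=TZ)),
            )
        )
        assert codes(validate_graph(fixture_graph, terms)) == [Code.TIME_ORDER]

    def test_seq_singleton_strict_only(self, fixture_graph, terms):
        rel = next(fixture_graph.objects(None, URIRef(EX + "metricRelation")))
        fixture_graph.remove((rel, URIRef(EX + "metricValue"), None))
        seq = BNode()
        fixture_graph.add((rel, URIRef(EX + "metricValue"), seq))
        fixture_graph.add((seq, RDF.type, RDF.Seq))
        fixture_graph.add((seq, URIRef(f"{RDF_NS}_1"), Literal(True)))
        assert Code.SEQ_SINGLETON not in codes(validate_graph(fixture_graph, terms))
        assert Code.SEQ_SINGLETON in codes(
            validate_graph(fixture_graph, terms, profile="strict")
        )

    def test_unknown_metric_namespace(self, fixture_graph, terms):
        rel = next(fixture_graph.objects(None, URIRef(EX + "metricRelation")))
        fixture_graph.remove((rel, URIRef(EX + "metricName"), None))
        fixture_graph.add(
            (rel, URIRef(EX + "metricName"), URIRef("http://elsewhere.org/Success"))
        )
        assert Code.UNKNOWN_METRIC in codes(validate_graph(fixture_graph, terms))

    def test_namespace_drift(self, fixture_graph, terms):
        fixture_graph.add(
            (
                BNode(),
                URIRef(EX + "notARealProperty"),
                Literal("x"),
            )
        )
        violations = validate_graph(fixture_graph, terms)
        assert codes(violations) == [Code.NAMESPACE_DRIFT]
        assert "notARealProperty" in violations[0].node

    def test_missing_site_warned_in_strict_only(self, fixture_graph, terms):
        fixture_graph.remove((None, URIRef(EX + "site"), None))
        assert validate_graph(fixture_graph, terms) == []
        strict = validate_graph(fixture_graph, terms, profile="strict")
        assert any(
            v.code == Code.MISSING_LINK and "site" in v.detail for v in strict
        )

    def test_violations_export_as_json_lines(self, fixture_graph, terms):
        import json

        fixture_graph.remove((None, URIRef(EX + "player"), None))
        (violation,) = validate_graph(fixture_graph, terms)
        doc = json.loads(violation.to_json())
        assert doc["code"] == "MISSING_LINK"

    def test_unknown_profile_rejected(self, fixture_graph, terms):
        with pytest.raises(ValueError, match="profile"):
            validate_graph(fixture_graph, terms, profile="lenient")


class TestSoundness:
    @given(session=sessions())
    @settings(max_examples=50, deadline=None, derandomize=True,
              suppress_health_check=[HealthCheck.function_scoped_fixture])
    def test_emitted_graphs_validate_cleanly(self, session, terms):
        graph = session_to_graph(session, terms)
        assert validate_graph(graph, terms) == []
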