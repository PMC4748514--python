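# exergame

Tools for publishing exergame telemetry as linked open data.

Exergames — serious games that combine gameplay with physical exercise —
are increasingly used to monitor the physical and cognitive status of
elderly players through their in-game metrics (success per exercise
iteration, reaction time, goal time, scores). The exergame ontology
(`http://purl.org/net/exergame/ns#`) gives that telemetry a standard RDF
structure so game sessions from different platforms can be pooled,
queried and compared. This package is an executable implementation of
that data model for researchers and platform developers: it builds,
validates, serializes, queries and *simulates* ontology-conformant
session data, with no live endpoint required.

## The data model

A game is described once (an `exergame:Game` instance with its
`exergame:GoalMetric` metrics, `exergame:GameController`s — linked
`owl:sameAs` to DBpedia — presentation hardware and OPE-described
exercise) and every session refers to it by IRI. One play period is an
`exergame:GameSession` node carrying

```
session --exergame:player-->  <player IRI (opaque, anonymous)>
        --exergame:game---->  <game IRI>
        --exergame:site---->  <site IRI>
        --exergame:startDateTime / endDateTime--> xsd:dateTime
        --exergame:result-->  result
```

RDF properties are binary, so each (result × metric × unit × value)
association goes through an auxiliary n-ary node:

```
result --exergame:metricRelation--> relation
relation --exergame:metricName--> exergame-metric:Success
relation --exergame:metricValue--> rdf:Seq with rdf:_1 ... rdf:_n
```

A single-iteration value attaches as a literal directly; two or more
iterations are ordered with `rdf:Seq` membership properties. Players are
plain opaque identifiers — the validator rejects FOAF/vCard personal
predicates on player nodes.

## Worked example

The bundled fixture is the SideRaises game (side raises with hand
weights; metrics success, reaction time, goal time; Kinect controller,
smart TV) and one recorded session of player162:

```python
>>> import exergame as xg
>>> game, session = xg.sideraises_fixture()
>>> graph = xg.session_to_graph(session)
>>> len(graph)
40
>>> table = xg.metric_at_iteration(graph, xg.define_metric("Success", "s").iri, 3)
>>> table.columns
('player', 'startDateTime', 'value')
>>> table.rows
(('http://www.fitforall.gr/resources/player162',
  datetime.datetime(2014, 9, 22, 18, 9, 39,
                    tzinfo=datetime.timezone(datetime.timedelta(seconds=7200))),
  False),)
```

The 40 triples are the session node, its result, three metric-relation
nodes and three six-member `rdf:Seq` value sequences. The query result
says: in that session, the third side-raise iteration was not performed
successfully (`False`), by player162, on 2014-09-22 at 18:09:39 (+02:00).

From the shell, the same pipeline end to end:

```bash
exergame simulate --seed 1 --out-prefix pilot      # pilot.ttl + pilot.csv
exergame validate pilot.ttl                        # exit 0, no violations
exergame query pilot.ttl --canned metric-at-iteration \
    --metric Success --iteration 3
exergame convert pilot.csv --out again.ttl         # CSV -> RDF loop
exergame canonicalize again.ttl                    # deterministic N-Triples
```

The simulator reproduces the shape of the ontology's living-lab pilot:
14 elderly players (3 male, mean age 73.4), 6 visits each, 7 games per
visit — 588 sessions, ~23k triples. See `docs/methods.md` for the
distribution choices and their rationale.

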