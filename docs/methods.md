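# Methods

## The session model

The package implements the exergame ontology's session model as an
executable data layer. Its core construct is the n-ary metric
association: because an RDF property can only link two things, the
association between a session's result, a metric, a unit of measurement
and a value is reified as an auxiliary `exergame:MetricRelation` node.
Per-iteration values (one per repetition of the underlying physical
exercise) are ordered with `rdf:Seq` membership properties
`rdf:_1 … rdf:_n`; when a metric was observed for a single iteration the
value is attached to the relation as a literal directly, with no `rdf:Seq`
node. Sessions, results, relations and sequences are blank nodes by
default, matching the published dataset; an optional skolemization switch
mints resolvable IRIs under a caller-supplied base for triplestore
upload, where blank nodes would not remain addressable.

Modeling points that the published material leaves open, and how this
package resolves them:

* **Linkage properties.** The properties attaching a game's metrics,
  controllers, hardware and exercise to the game instance, and a unit to
  a metric relation, are never named in the published description. This
  package mints `gameMetric`, `gameController`, `presentationHardware`,
  `gameExercise` and `metricUnit` in the exergame namespace, plus
  `involvesMuscle`, `equipment`, `benefit`, `gameGoal` and `exerciseGoal`
  for the exercise and goal annotations. All are registered in
  `OntologyTerms` and remappable, so a corrected official term list can
  be dropped in without code changes.
* **Host alias.** Exergame namespaces are canonically under `purl.org`;
  documents using the `purl.com` host variant are accepted on parse and
  normalized.
* **Players and FOAF.** Player instances are emitted with both
  `exergame:Player` and `foaf:Person` types (Player is treated as a
  subclass of `foaf:Person`; an assumption, since the published text uses
  both without stating the relation).
* **Goals.** Game and exercise goals are kept as plain string
  annotations (`gameGoal` / `exerciseGoal`), not typed individuals — no
  class IRIs for them are published.
* **Units.** Whether every metric relation must carry a unit is
  ambiguous: the model text says metrics have both value and unit, but
  the published worked example shows a Success relation with neither.
  `UNIT_MISSING` is therefore a strict-profile violation only, and the
  bundled Success observation is unitless.
* **Timestamps.** Start/end times are `xsd:dateTime` with a mandatory
  UTC offset; `start == end` is legal (the worked example prints
  identical start and end). The worked example's offset separator is
  mangled in some renderings (`… 02:00`); it is read as `+02:00`.

## Value datatypes

Metric values are booleans, integers, decimals or strings; all values of
one observation share one datatype. Floats are emitted as `xsd:decimal`
in positional notation (exponent-free, always with a decimal point, from
the shortest round-trip representation), which survives Turtle/RDF-XML/
N-Triples round trips exactly. On parse, plain literals are interpreted
leniently: `TRUE`/`FALSE` in any case become booleans (the published
listing prints uppercase booleans), then integer, then decimal, then
string. A consequence is that a *string* metric value whose lexical form
looks like a number or boolean is reinterpreted on read-back; declare an
explicit datatype in the tabular mapping when that matters.

## Canonicalization

`canonicalize()` produces sorted N-Triples with deterministic blank-node
labels, so two independently built graphs can be compared byte for byte.
Labels are assigned by colour refinement: each blank node starts from a
hash of its ground neighbourhood (predicates plus adjacent IRIs and
literals), colours are iteratively re-hashed with neighbouring colours
until the partition stabilises, and nodes are labelled `c14n0…` in colour
order. If symmetric nodes remain (e.g. two byte-identical sessions), each
candidate is individualized in turn and the lexicographically least
resulting text is kept — label-independent by construction. This runs in
roughly linear time on session graphs (about 2 s for a full default
pilot of ~23k triples); the tie-breaking branch is exponential only on
adversarial symmetric graphs, which the session model does not produce.
Equality of canonical texts is cross-checked against an independent
graph-isomorphism test in the suite.

## Validation

`validate_graph` returns violations as data (code, node, detail), never
raising, and does not mutate the graph. The `compat` profile checks what
every conformant graph must satisfy: exactly one player / game / result /
start / end per session, start ≤ end, one metricName and metricValue per
relation with metric IRIs in the shared metric namespace, contiguous
`rdf:Seq` indices from 1, no FOAF/vCard personal predicates on player
nodes (the anonymity rule: a player is a plain unique identifier), and no
unregistered exergame-namespace terms. The `strict` profile adds units on
every relation, no single-member sequences, and a warning for sessions
without a site (site cardinality is deliberately unconstrained). The PII
predicate blocklist (`foaf:name/givenName/familyName/mbox/phone`,
`vcard:fn/email/hasEmail/tel/hasTelephone`) is configurable because the
anonymity requirement is a principle, not a fixed predicate list.

## The synthetic pilot

The simulator emulates the living-lab deployment the ontology was piloted
in, so the whole toolchain is testable without downloading anything. The
default configuration *is* the pilot's shape: 14 players, 3 male and 11
female, ages drawn from Normal(73.4, 5) years clamped to [60, 95]; 6
visits per player on consecutive days; 7 different games per visit (the
same seven each day); all sessions at one living-lab site. The default
catalog holds seven games modeled on the pilot platform: three strength
games with per-iteration metrics (SideRaises — the worked example —
BicepsCurl, LegExtension: success, reaction time, goal time) and four
activity games (Apple, Hiking, Fishing, Golf: total time and score).

No per-metric distributions were published, so these are package
choices, all overridable in the configuration:

| metric       | model                         | default            |
|--------------|-------------------------------|--------------------|
| Success      | Bernoulli                     | p = 0.7            |
| ReactionTime | log-normal (s)                | μ = ln 1.5, σ = 0.4 |
| GoalTime     | Normal truncated at 0 (s)     | μ = 4, σ = 1       |
| TotalTime    | Normal truncated at 0 (s)     | μ = 120, σ = 30    |
| Score        | trunc. Normal, integer-rounded | μ = 10, σ = 3      |

Reaction latencies are log-normal because human response times are
positive and right-skewed. Iteration counts per session are uniform on
[6, 10] (the worked example has 6 iterations); session durations uniform
on [2, 6] minutes with [2, 8]-minute gaps, which puts the default pilot's
588 sessions on the order of 35 hours of play — the deployment's reported
magnitude, emulated rather than enforced. Everything is driven by one
`numpy` generator seeded from the config, so a seed reproduces players,
sessions and canonical graph bytes exactly.

What the simulator does **not** emulate: learning and fatigue effects,
day-to-day drift, dropout, missing telemetry, or any correlation between
demographics and performance. Tests passing on simulated data therefore
demonstrate structural and pipeline correctness (emission, validation,
query, conversion), not behavioural realism of real elderly cohorts.

## Queries and the oracle

`metric_at_iteration` ships the dataset's canned request — all values of
one metric at one iteration with player and session start date. The
published query text was not preserved, so the shipped `.rq` is a
reconstruction from the described structure (session → result →
metricRelation → metricName/metricValue → `rdf:_n`); at iteration 1 it
also covers the direct-literal encoding with a UNION branch. Column
naming (`player`, `startDateTime`, `value`) is a package convention.
Every graph-side answer is cross-checked in the suite against
`oracle_metric_at_iteration`, an independent pure scan over
`SessionRecord.values`, and generic SPARQL evaluation is spot-checked
against a brute-force nested triple-scan pattern matcher.

## Tabular conversion

The CSV converter implements a minimal, R2RML-inspired single-table
dialect (full R2RML is out of scope: the mapping language is cited as an
option for lifting relational game stores, not a requirement). The
canonical input is long format — one row per metric iteration — with a
YAML mapping binding roles to columns. Duplicate or non-contiguous
iterations and inconsistent per-session metadata are hard errors. The
simulator writes the same schema, closing the loop: simulator CSV →
converter → RDF is canonically byte-identical to the simulator's own RDF.

## Problem sizes

The test suite runs the property checks at fixed sizes chosen to keep a
full run around 15 s on one core: 200 randomized sessions for round-trip
and cross-format isomorphism, 100 seeded miniature pilots for
query-vs-oracle equivalence, and fixture-scale graphs for the deletion
sweep and golden-file comparison. The acceptance script simulates one
full default pilot (588 sessions) per run.

## Known limitations

* No OWL reasoning, SHACL, or SKOS vocabulary serving; validation is the
  structural rule set above.
* JSON-LD and named graphs are unsupported; formats are Turtle, RDF/XML
  and N-Triples.
* The worked-example session's ReactionTime and GoalTime values are
  synthetic stand-ins (the published listing elides those rows); only its
  Success values, identifiers and timestamps are as published.
* `graph_to_sessions` recovers session identifiers from blank-node
  labels / skolem IRIs; graphs that lost labels in transit yield
  sessions with `session_id=None`.
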