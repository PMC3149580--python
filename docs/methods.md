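# Methods

## Scope of the knowledge model

The package models the slice of the BioAssay Ontology that the endpoint
axioms and the three worked activity queries exercise: bioassay,
perturbagen, measure group, meta target, mode of action (inhibition,
activation ≡ stimulation ≡ agonist), the endpoint hierarchy
(perturbagen-concentration vs response endpoints, with IC50/EC50/AC50/CC50
and the percent-response classes beneath them), and the object/datatype
properties wiring them together.  Accessions that appear in the worked
queries are pinned to their published values (IC50 = BAO_0000190,
AC50 = BAO_0000186, ...); supporting terms the queries never print
(measure group, CC50, agonist, the 50%-response nominal individuals, the
spec classes) are minted in the same style and flagged `invented` in
`schema.REGISTRY_TABLE`.  No claim is made that the invented accessions
coincide with the full ontology's, and the full 730-class vocabulary,
external imports (GO/CLO/UO/taxonomy) and the web application are out of
scope.  The endpoint standardizer ships the explicitly documented
endpoint names plus a synonym dictionary; it maps unknown names to an
`unmapped` sentinel rather than guessing.

Assays link to endpoints through a measure-group node so that multiplexed
and multi-parametric assays fit the same schema; the loader creates one
measure group per (assay, measure-group index) and the worked examples
never need more than one.

## Reasoning semantics

The reasoner is a desk-scale forward chainer, not a tableau algorithm.
It implements exactly the fragment the axioms use:

* **Classification** builds the reflexive-transitive subsumption closure
  over named classes.  Asserted subclass edges keep provenance
  `asserted`; equivalence-induced mutual edges, transitive compositions
  and structurally derived subsumptions are `inferred`.  Structural
  subsumption between defined classes holds when every conjunct of the
  superclass definition is entailed by some conjunct of the subclass
  definition: restrictions must share a property and have subsumed
  fillers (union fillers entailed disjunct-wise; a `hasValue` conjunct
  entails an existential over any enumerated class containing the
  value).  The closure feeds the filler checks, so the loop runs to
  fixpoint.  This derives IC50 ⊑ AC50 and EC50 ⊑ AC50 and nothing
  spurious (no AC50 ⊑ IC50, no EC50 ⊑ IC50).
* **Materialization** applies five rule families to a fixpoint: subclass
  propagation, equivalence propagation, inverse-property completion (in
  both directions, giving a bijection between `hasPerturbagen` and
  `isPerturbagenOf` assertions), domain/range typing, and realization of
  individuals against the defined classes.  Rule families can be
  disabled individually (`materialize(..., rules=...)`) to demonstrate
  which answers depend on which inference; the result is independent of
  rule-application order, and re-materializing a fixpoint adds nothing.
* **Closed-property reading of universal restrictions.**  "Only"
  restrictions are evaluated over the asserted fillers: all known
  fillers must qualify and at least one must exist.  This deviates from
  open-world OWL semantics deliberately — the paired existential
  restriction in each definition plays the role of closing the property,
  which is what makes forward-chaining realization sound here.
  Existential heads never invent individuals, so termination is
  structural.
* **Consistency** checking is limited to explicit disjointness
  violations (e.g. an individual typed both perturbagen and endpoint
  raises, naming the individual and the clashing classes).  No general
  satisfiability checking is attempted.

The subsumption closure is also emitted as `rdfs:subClassOf` triples
(including the reflexive pairs) so that queries of the shape
`?endpoint rdf:type ?type . ?type rdfs:subClassOf <root>` see the
inferred taxonomy, including `?type` bound to the root itself — the
worked results contain such rows.

## Triple store and serialization choices

Graphs are sets of ground triples with canonical (subject, predicate,
object) ordering, so two stores built in different insertion orders
serialize byte-identically.  Float literals are stored and serialized by
lexical form and only compared numerically inside query filters: a value
curated as `6.3096` stays the string `6.3096` through any number of
round-trips, which is what makes result tuples reproducible to the
character.  Blank nodes are unsupported; anonymous class-expression
nodes in the schema graph get deterministic minted IRIs, and instance
individuals follow the `individual_<classAccession>_<sourceID>` scheme
(endpoints additionally carry a family index — 2 for concentration-type,
1 for response-type — and a running counter; the original assignment of
those counters is not documented anywhere, so fixtures pin them
explicitly and the loader otherwise numbers rows in input order).  The
supported Turtle subset is prefix declarations, `a`, object and
predicate lists, and typed literals.

## Query engine

Queries are ASTs (basic graph patterns, UNION, numeric FILTER, SELECT
DISTINCT, GROUP BY with a count-distinct HAVING threshold), evaluated by
an index-backed join with greedy most-constrained-first ordering.  Rows
are canonically sorted over the projection.  Two engine-independent
oracles back the tests: an unordered full-scan backtracker and a true
exhaustive-assignment enumerator.  A filter applied to a non-numeric or
unbound binding drops the row with a logged warning rather than raising,
matching how a SPARQL engine treats type errors in filters.

The promiscuity query joins the perturbagen to both the assay and the
endpoint (`?pert isPerturbagenOf ?assay` and `... ?endpoint`).  The
assay-only variant would credit a compound with every co-resident
compound's activity in multi-compound assays; the joined form expresses
"compounds that *have* a response ≥ 50 % in ≥ 3 assays" and is the
variant under test, including ground-truth recovery on generated data.

## Annotation loading

Concentrations are normalized to micromolar (nM × 10⁻³, mM × 10³; μM
values keep their input spelling verbatim).  Concentration-type endpoint
rows point `hasPercentResponse` at a shared 50 %-response nominal
individual selected by mode of action (inhibition → the
fifty-percent-inhibition individual, activation/stimulation → the
fifty-percent-activation one), which is exactly what lets realization
match the `hasValue` conjunct of the IC50/EC50 definitions.  CC50 rows
use a separate fifty-percent-viability nominal so a cytotoxicity record
does not cross-realize as IC50.  Only the forward `hasPerturbagen`
direction is asserted (at both endpoint and assay level); the inverse
edges exist only after materialization, which keeps the promiscuity
query an honest test of inference.  Rows with unmapped endpoints,
unknown units or modes of action, or non-positive/non-numeric
concentrations are rejected with machine-readable reasons, and
accepted + rejected always partition the input.

The QC cross-check compares the curated endpoint name, concentration
value and unit against a source table keyed by (assay, compound) and
flags `mismatch`, `missing` (blank cells or unkeyed rows) and
`non-atomic` (a source cell packing several delimiter-separated values).

## Synthetic data

The fixture tables encode the worked-example result tuples — same
assay/compound identifiers, same literal spellings — plus distractors
that violate each filter (excess concentration, sub-threshold response,
wrong mode of action) and rows sitting exactly on the inclusive
boundaries (10 μM, 50 %), pinning the `<=`/`>=` semantics of the printed
filters.

The random generator emulates a curated PubChem-style set at the study's
shape: 194 assays with 20 endpoint records each by default, a mix of the
six standardized endpoint types the study exercised, log-uniform
screening concentrations on 0.01–100 μM, response values drawn from
N(0, 15) % for inactives and N(80, 15) % for actives (10 % actives), and
five planted promiscuous compounds responding ≥ 50 % in four distinct
assays each.  Background compounds appear in at most two assays, so with
the usual HAVING threshold of three the planted set is exactly
recoverable — that is the designed ground truth, not an empirical
finding.  Randomness is Python's Mersenne Twister seeded from the
config; identical configs are byte-identical.  The generator does not
emulate real activity distributions, chemical structures, inter-assay
correlations, or curation noise, so passing tests demonstrate the
engine's logic, not robustness to real PubChem data.  The original
store's triple and result counts (45,075 triples; 2,741 Example-1 rows)
depend on unpublished curated data and are deliberately not reproduced.

Most tests run the pipeline at reduced sizes (6–20 assays, 4–6 endpoints
per assay, 20 seeds for the equivalence and recovery properties); one
scale check runs the full default configuration end to end.

## Known limitations

* No general OWL reasoning: no negation, no role hierarchies beyond a
  single inverse pair, no datatype range reasoning, no justification
  generation; nominals only as `hasValue` targets and small enumerated
  classes.
* The query engine has no OPTIONAL, property paths, subqueries, text
  parser, or aggregation beyond count-distinct HAVING.
* Universal restrictions use the closed asserted-filler reading
  described above; conclusions can be retracted under pure open-world
  semantics if new fillers appear (materialization itself is monotone
  for the rule set as defined).
* Endpoint standardization is a dictionary plus token rules over the
  documented name variants; it is not a general PubChem name parser.
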