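# minibao

A self-contained engine for the BioAssay Ontology's knowledge model of
high-throughput screening (HTS) results: an RDF-style triple store, the
description-logic axioms that define standardized assay endpoints
(IC50, EC50, AC50, percent inhibition/activation, ...), a forward-chaining
reasoner that materializes inferred class memberships and inverse
relations, and a SPARQL-subset query engine for semantic activity queries
over curated assay annotations.

## Why

Public HTS repositories accumulate thousands of differently named but
equivalent endpoint labels ("Mean IC50", "Best-Fit Value IC50 (uM)",
"IC50_Mean", ...), and relational queries cannot see that an AC50 record
is also, logically, an IC50 record.  Encoding endpoints as defined
description-logic classes fixes both problems: standardization collapses
the name variants, and subsumption/realization reasoning surfaces results
a literal query would miss.  This package implements that pipeline at
desk scale — curated annotation table in, materialized knowledge graph
and query answers out — for anyone who wants to study, test, or teach the
mechanism without a triple-store server and a tableau reasoner.

## The model

Endpoints are classes under `endpoint` (BAO_0000179), split into
perturbagen-concentration endpoints (BAO_0000180) and response endpoints
(BAO_0000181).  The concentration endpoints are *defined* classes:

```
IC50 ≡ (∃ hasModeOfAction.inhibition) ⊓ (∀ hasModeOfAction.inhibition)
       ⊓ (hasPercentResponse value fifty_percent_inhibition)
EC50 ≡ … analogous with activation …
AC50 ≡ (∃ hasModeOfAction.(inhibition ⊔ activation))
       ⊓ (∀ hasModeOfAction.(inhibition ⊔ activation))
       ⊓ (∃ hasPercentResponse.{fifty_percent_inhibition, fifty_percent_activation})
```

The structural classifier derives IC50 ⊑ AC50 and EC50 ⊑ AC50 (and no
converse edges); `activation ≡ stimulation ≡ agonist`; and
`hasPerturbagen` has inverse `isPerturbagenOf`.  The materializer runs
subclass/equivalence propagation, inverse-property completion,
domain/range typing, and realization of individuals against the
definitions to a fixpoint, tagging every triple asserted or inferred.

## Worked example

Find promiscuous compounds (response ≥ 50 % in ≥ 3 assays), which is only
answerable after inference because the data assert `hasPerturbagen`
edges, not their inverses:

```python
import minibao as mb
from minibao.synth import fixture_example3

onto, _ = mb.build_mini_bao()
rows, _ = fixture_example3()
graph = mb.load_annotations(rows, onto).graph
inferred = mb.materialize(graph, onto)

perts = mb.example3_promiscuous(inferred, onto, min_assays=3)
print([p.value for p in perts])
for row in mb.example3_profile(inferred, onto, perts[0]):
    print({k.name: v for k, v in row.items()})
```

prints

```
['http://www.bioassayontology.org/bao#individual_BAO_0000021_646704']
{'assay': <http://www.bioassayontology.org/bao#individual_BAO_0000015_1262>, 'percentResponseValue': "116.84"^^xsd:float}
{'assay': <http://www.bioassayontology.org/bao#individual_BAO_0000015_1306>, 'percentResponseValue': "106.48"^^xsd:float}
{'assay': <http://www.bioassayontology.org/bao#individual_BAO_0000015_1316>, 'percentResponseValue': "99.42"^^xsd:float}
```

i.e. compound 646704 is the one perturbagen active in three distinct
assays, with per-assay percent responses 116.84, 106.48 and 99.42.  Run
the same workflow from a shell with the `minibao` command
(`fixtures` → `load` → `reason` → `query example3`).

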