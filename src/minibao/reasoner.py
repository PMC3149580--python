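"""Forward-chaining materialization and structural classification.

The implemented fragment is exactly what the endpoint axioms exercise:
named subsumption, class equivalence, inverse object properties,
domain/range typing, and realization of individuals against defined
classes built from some/only/hasValue/cardinality restrictions over named,
union and small enumerated (nominal) fillers.

Universal ("only") restrictions are evaluated under an asserted-filler
closure: all known fillers must qualify and at least one filler must
exist.  This deviates from pure open-world OWL semantics; the paired
existential restrictions in the endpoint definitions play the role of
closing each property, which is what makes desk-scale forward chaining
sound here.  Existential heads never invent individuals, so the fixpoint
terminates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .rdf_model import Graph, Iri, Literal, RDF_TYPE, RDFS_SUBCLASSOF, Triple
from .schema import (
    AllValuesFrom,
    ClassExpression,
    DataExact,
    ExactCardinality,
    HasValue,
    Named,
    OneOf,
    Ontology,
    SomeValuesFrom,
    Union_,
    conjuncts,
)

__all__ = [
    "ALL_RULES",
    "ConsistencyError",
    "SubsumptionClosure",
    "InferredGraph",
    "classify",
    "materialize",
    "realize",
]

#: rule families applied by :func:`materialize`
ALL_RULES = frozenset(
    {"subclass", "equivalence", "inverse", "domain_range", "realization"}
)


class ConsistencyError(Exception):
    """A disjointness clash: the offending class/individual is in args."""


@dataclass
class SubsumptionClosure:
    """Reflexive-transitive subsumption over named classes with provenance."""

    pairs: dict = field(default_factory=dict)  # (sub, sup) -> "asserted"|"inferred"

    def add(self, sub: Iri, sup: Iri, provenance: str) -> bool:
        if (sub, sup) in self.pairs:
            return False
        self.pairs[(sub, sup)] = provenance
        return True

    def __contains__(self, pair: tuple) -> bool:
        return pair in self.pairs

    def provenance(self, sub: Iri, sup: Iri) -> Optional[str]:
        return self.pairs.get((sub, sup))

    def superclasses(self, sub: Iri) -> set:
        return {sup for (s, sup) in self.pairs if s == sub}

    def rows(self) -> list[tuple[str, str, str]]:
        """(sub, sup, provenance) rows in canonical order, for TSV export."""
        return sorted(
            (sub.value, sup.value, prov) for (sub, sup), prov in self.pairs.items()
        )


# ----------------------------------------------------------------------
# TBox classification
# ----------------------------------------------------------------------


def _resolve_nominal(expr: ClassExpression, onto: Ontology) -> ClassExpression:
    if isinstance(expr, Named):
        members = onto.nominal_members(expr.iri)
        if members:
            return OneOf(members)
    return expr


def _individual_in_filler(i: Iri, filler: ClassExpression, onto: Ontology) -> bool:
    filler = _resolve_nominal(filler, onto)
    if isinstance(filler, OneOf):
        return i in filler.individuals
    if isinstance(filler, Union_):
        return any(_individual_in_filler(i, m, onto) for m in filler.members)
    return False


def _filler_subsumed(
    sub: ClassExpression, sup: ClassExpression, closure: SubsumptionClosure,
    onto: Ontology,
) -> bool:
    if sub == sup:
        return True
    if isinstance(sub, Union_):
        return all(_filler_subsumed(m, sup, closure, onto) for m in sub.members)
    if isinstance(sup, Union_):
        return any(_filler_subsumed(sub, m, closure, onto) for m in sup.members)
    sub_r, sup_r = _resolve_nominal(sub, onto), _resolve_nominal(sup, onto)
    if isinstance(sub_r, OneOf) and isinstance(sup_r, OneOf):
        return sub_r.individuals <= sup_r.individuals
    if isinstance(sub, Named) and isinstance(sup, Named):
        return (sub.iri, sup.iri) in closure
    return False


def _conjunct_entails(
    c: ClassExpression, d: ClassExpression, closure: SubsumptionClosure,
    onto: Ontology,
) -> bool:
    """Does conjunct ``c`` (of the sub class) entail conjunct ``d``?"""
    if c == d:
        return True
    if isinstance(d, Named):
        return isinstance(c, Named) and (c.iri, d.iri) in closure
    if isinstance(d, SomeValuesFrom):
        if isinstance(c, SomeValuesFrom) and c.property == d.property:
            return _filler_subsumed(c.filler, d.filler, closure, onto)
        # a hasValue closes the existential over any class containing the value
        if isinstance(c, HasValue) and c.property == d.property:
            return _individual_in_filler(c.individual, d.filler, onto)
        return False
    if isinstance(d, AllValuesFrom):
        return (
            isinstance(c, AllValuesFrom)
            and c.property == d.property
            and _filler_subsumed(c.filler, d.filler, closure, onto)
        )
    if isinstance(d, ExactCardinality):
        return (
            isinstance(c, ExactCardinality)
            and c.property == d.property
            and c.n == d.n
            and (
                (c.filler is None and d.filler is None)
                or (
                    c.filler is not None
                    and d.filler is not None
                    and _filler_subsumed(c.filler, d.filler, closure, onto)
                )
            )
        )
    if isinstance(d, Union_):
        return any(_conjunct_entails(c, m, closure, onto) for m in d.members)
    return False


def _def_subsumes(
    sub_def: tuple, sup_def: tuple, closure: SubsumptionClosure, onto: Ontology
) -> bool:
    return all(
        any(_conjunct_entails(c, d, closure, onto) for c in sub_def)
        for d in sup_def
    )


def classify(onto: Ontology, *, use_equivalence: bool = True) -> SubsumptionClosure:
    """Compute the reflexive-transitive subsumption closure.

    Asserted named subclass edges keep provenance ``asserted`` (as do the
    reflexive pairs); everything else -- equivalence-induced mutual edges,
    transitive compositions, structurally derived subsumptions between
    defined classes -- is ``inferred``.  Raises :class:`ConsistencyError`
    if a class ends up below two disjoint classes.
    """
    closure = SubsumptionClosure()
    names: set[Iri] = set(onto.named_classes())
    for sub, sup in onto.asserted_subclass_pairs():
        names.update((sub, sup))
    for c in names:
        closure.add(c, c, "asserted")
    for sub, sup in onto.asserted_subclass_pairs():
        closure.add(sub, sup, "asserted")
    if use_equivalence:
        for x, y in onto.named_equivalence_pairs():
            closure.add(x, y, "inferred")

    # definitions may also imply named superclasses via Named conjuncts
    defs = {
        c: conjuncts(e)
        for c, e in onto.definitions.items()
        if not isinstance(e, OneOf)
    }
    changed = True
    while changed:
        changed = False
        # transitive closure
        for (a, b) in list(closure.pairs):
            for c in list(closure.superclasses(b)):
                if closure.add(a, c, "inferred"):
                    changed = True
        # structural subsumption between defined classes (feeds on closure)
        for c_iri, c_def in defs.items():
            for n in (m.iri for m in c_def if isinstance(m, Named)):
                if closure.add(c_iri, n, "inferred"):
                    changed = True
            for d_iri, d_def in defs.items():
                if c_iri == d_iri or (c_iri, d_iri) in closure:
                    continue
                if _def_subsumes(c_def, d_def, closure, onto):
                    closure.add(c_iri, d_iri, "inferred")
                    changed = True

    for group in onto.disjoint_groups():
        for c in names:
            sups = closure.superclasses(c)
            hit = [d for d in group if d in sups]
            if len(hit) > 1:
                raise ConsistencyError(
                    f"class {c.value} is subsumed by disjoint classes", c, tuple(hit)
                )
    return closure


# ----------------------------------------------------------------------
# ABox materialization
# ----------------------------------------------------------------------


@dataclass
class InferredGraph:
    """Asserted graph plus the disjoint set of materialized triples."""

    base: Graph
    inferred: Graph
    closure: SubsumptionClosure

    def union(self) -> Graph:
        g = self.base.copy()
        g.add_all(iter(self.inferred))
        return g


def _filler_holds(y, filler: ClassExpression, types: dict, onto: Ontology) -> bool:
    """Is the (asserted-closure) filler ``y`` an instance of ``filler``?"""
    filler = _resolve_nominal(filler, onto)
    if isinstance(filler, OneOf):
        return y in filler.individuals
    if isinstance(filler, Union_):
        return any(_filler_holds(y, m, types, onto) for m in filler.members)
    if isinstance(filler, Named):
        return filler.iri in types.get(y, set())
    return False


def materialize(
    graph: Graph,
    onto: Ontology,
    *,
    rules: Iterable[str] = ALL_RULES,
    closure: Optional[SubsumptionClosure] = None,
) -> InferredGraph:
    """Compute the fixpoint of the inference rules over ``graph``.

    ``rules`` selects rule families (see :data:`ALL_RULES`); restricting
    them is useful to demonstrate which inferences a query answer depends
    on.  The subsumption closure is always computed (without equivalence
    edges if the ``equivalence`` rule is off) and emitted as
    ``rdfs:subClassOf`` triples so that queries over types can follow the
    class hierarchy.
    """
    rules = frozenset(rules)
    unknown = rules - ALL_RULES
    if unknown:
        raise ValueError(f"unknown rule families: {sorted(unknown)}")
    if closure is None:
        closure = classify(onto, use_equivalence="equivalence" in rules)

    work = graph.copy()
    inferred = Graph(graph.prefix_map)

    def add(t: Triple) -> bool:
        if t in work:
            return False
        work.add(t)
        inferred.add(t)
        return True

    if "subclass" in rules:
        for (sub, sup) in closure.pairs:
            add(Triple(sub, RDFS_SUBCLASSOF, sup))

    inverse_pairs = onto.inverse_pairs() if "inverse" in rules else []
    domains = onto.property_domains() if "domain_range" in rules else []
    ranges = onto.property_ranges() if "domain_range" in rules else []
    defs = {c: conjuncts(e) for c, e in onto.definitions.items()}
    sup_map: dict = {}
    for (a, b) in closure.pairs:
        sup_map.setdefault(a, set()).add(b)
    # realization only ever fires on nodes carrying a definition property
    def_props = {
        conj.property
        for c_def in defs.values()
        for conj in c_def
        if not isinstance(conj, (Named, OneOf, Union_))
    }

    changed = True
    while changed:
        changed = False

        if "inverse" in rules:
            for p, q in inverse_pairs:
                for direction_p, direction_q in ((p, q), (q, p)):
                    for t in work.match(None, direction_p, None):
                        if isinstance(t.object, Literal):
                            continue
                        if add(Triple(t.object, direction_q, t.subject)):
                            changed = True

        if "domain_range" in rules:
            for p, cls in domains:
                for t in work.match(None, p, None):
                    if add(Triple(t.subject, RDF_TYPE, cls)):
                        changed = True
            for p, cls in ranges:
                for t in work.match(None, p, None):
                    if not isinstance(t.object, Literal):
                        if add(Triple(t.object, RDF_TYPE, cls)):
                            changed = True

        # current type map (shared by propagation and realization)
        types: dict = {}
        for t in work.match(None, RDF_TYPE, None):
            types.setdefault(t.subject, set()).add(t.object)

        if "subclass" in rules or "equivalence" in rules:
            for x, tset in types.items():
                for c in list(tset):
                    for d in sup_map.get(c, ()):
                        if add(Triple(x, RDF_TYPE, d)):
                            changed = True

        if "realization" in rules:
            individuals = {
                t.subject
                for p in def_props
                for t in work.match(None, p, None)
                if isinstance(t.subject, Iri)
            }
            # refresh after propagation
            types = {}
            for t in work.match(None, RDF_TYPE, None):
                types.setdefault(t.subject, set()).add(t.object)
            for c_iri, c_def in defs.items():
                if len(c_def) == 1 and isinstance(c_def[0], OneOf):
                    for i in c_def[0].individuals:
                        if add(Triple(i, RDF_TYPE, c_iri)):
                            changed = True
                    continue
                for x in individuals:
                    if c_iri in types.get(x, set()):
                        continue
                    if _realizes(x, c_def, work, types, onto):
                        if add(Triple(x, RDF_TYPE, c_iri)):
                            changed = True

    _check_abox_consistency(work, onto, closure)
    # keep base and inferred disjoint
    out_inferred = Graph(graph.prefix_map)
    for t in inferred:
        if t not in graph:
            out_inferred.add(t)
    return InferredGraph(base=graph.copy(), inferred=out_inferred, closure=closure)


def _realizes(x: Iri, c_def: tuple, work: Graph, types: dict, onto: Ontology) -> bool:
    for conj in c_def:
        if isinstance(conj, Named):
            if conj.iri not in types.get(x, set()):
                return False
        elif isinstance(conj, SomeValuesFrom):
            fillers = work.objects(x, conj.property)
            if not any(_filler_holds(y, conj.filler, types, onto) for y in fillers):
                return False
        elif isinstance(conj, AllValuesFrom):
            fillers = work.objects(x, conj.property)
            if not fillers:
                return False
            if not all(_filler_holds(y, conj.filler, types, onto) for y in fillers):
                return False
        elif isinstance(conj, HasValue):
            if Triple(x, conj.property, conj.individual) not in work:
                return False
        elif isinstance(conj, ExactCardinality):
            fillers = set(work.objects(x, conj.property))
            if conj.filler is not None:
                fillers = {
                    y for y in fillers if _filler_holds(y, conj.filler, types, onto)
                }
            if len(fillers) != conj.n:
                return False
        elif isinstance(conj, DataExact):
            fillers = {
                y for y in work.objects(x, conj.property) if isinstance(y, Literal)
            }
            if len(fillers) != conj.n:
                return False
        else:  # Union_/OneOf at top level: treat as a one-disjunct check
            if isinstance(conj, Union_):
                if not any(
                    _realizes(x, (m,), work, types, onto) for m in conj.members
                ):
                    return False
            elif isinstance(conj, OneOf):
                if x not in conj.individuals:
                    return False
            else:  # pragma: no cover
                raise TypeError(f"unsupported conjunct {conj!r}")
    return True


def _check_abox_consistency(work: Graph, onto: Ontology, closure: SubsumptionClosure):
    groups = onto.disjoint_groups()
    if not groups:
        return
    schema_nodes = {Iri(onto.registry.base + lid) for lid, _l, _r in
                    onto.registry.entries()}
    for t in work.match(None, RDF_TYPE, None):
        x = t.subject
        if x in schema_nodes:
            continue
        xtypes = set(work.objects(x, RDF_TYPE))
        for group in groups:
            hit = [c for c in group if c in xtypes]
            if len(hit) > 1:
                raise ConsistencyError(
                    f"individual {x.value} typed into disjoint classes "
                    f"{[c.value for c in hit]}", x, tuple(hit)
                )


def realize(individual: Iri, inferred: InferredGraph) -> set:
    """All named classes the individual is typed into (superclass-closed).

    Unknown individuals yield the empty set.
    """
    out = set()
    for g in (inferred.base, inferred.inferred):
        for t in g.match(individual, RDF_TYPE, None):
            if isinstance(t.object, Iri):
                out.add(t.object)
    return out
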