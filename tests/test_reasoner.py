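"""Classification and materialization semantics."""

import random

import pytest

import minibao as mb
from minibao.rdf_model import Graph, Iri, Literal, RDF_TYPE, Triple
from minibao.schema import (
    BAO,
    DisjointClasses,
    EquivalentClasses,
    IdRegistry,
    InverseProperties,
    Named,
    Ontology,
    PropertyDomain,
    PropertyRange,
    SubClassOf,
)
from minibao.reasoner import ConsistencyError, classify, materialize, realize


def _toy_ontology(n_classes, edges, equivalences=(), disjoints=()):
    reg = IdRegistry()
    iris = [reg.register(f"c{i}", f"X_{i:04d}", "class") for i in range(n_classes)]
    onto = Ontology(registry=reg)
    for i, j in edges:
        onto.axioms.append(SubClassOf(Named(iris[i]), Named(iris[j])))
    for group in equivalences:
        onto.axioms.append(EquivalentClasses(tuple(Named(iris[i]) for i in group)))
    for group in disjoints:
        onto.axioms.append(DisjointClasses(tuple(Named(iris[i]) for i in group)))
    return onto, iris


class TestClassify:
    def test_inferred_endpoint_taxonomy(self, onto):
        cl = classify(onto)
        ic50, ec50, ac50 = (onto.registry.iri(x) for x in ("IC50", "EC50", "AC50"))
        assert cl.provenance(ic50, ac50) == "inferred"
        assert cl.provenance(ec50, ac50) == "inferred"
        assert (ac50, ic50) not in cl
        assert (ec50, ic50) not in cl
        assert (ac50, ec50) not in cl

    def test_reflexive(self, onto):
        cl = classify(onto)
        for c in onto.named_classes():
            assert (c, c) in cl

    def test_endpoint_subhierarchy_has_no_spurious_edges(self, onto):
        cl = classify(onto)
        r = onto.registry.iri
        endpoint_classes = ["IC50", "EC50", "AC50", "CC50", "percent inhibition",
                            "percent activation", "endpoint",
                            "perturbagen concentration endpoint",
                            "response endpoint"]
        expected = {
            (a, a) for a in endpoint_classes
        } | {
            ("IC50", "AC50"), ("EC50", "AC50"),
            ("IC50", "perturbagen concentration endpoint"), ("IC50", "endpoint"),
            ("EC50", "perturbagen concentration endpoint"), ("EC50", "endpoint"),
            ("AC50", "perturbagen concentration endpoint"), ("AC50", "endpoint"),
            ("CC50", "perturbagen concentration endpoint"), ("CC50", "endpoint"),
            ("percent inhibition", "response endpoint"),
            ("percent inhibition", "endpoint"),
            ("percent activation", "response endpoint"),
            ("percent activation", "endpoint"),
            ("perturbagen concentration endpoint", "endpoint"),
            ("response endpoint", "endpoint"),
        }
        got = {
            (a, b)
            for a in endpoint_classes
            for b in endpoint_classes
            if (r(a), r(b)) in cl
        }
        assert got == expected

    def test_random_hierarchies_match_path_existence_oracle(self):
        nx = pytest.importorskip("networkx")
        rng = random.Random(7)
        for _ in range(30):
            n = rng.randint(2, 15)
            edges = [
                (i, j)
                for i in range(n)
                for j in range(i + 1, n)
                if rng.random() < 0.25
            ]
            onto, iris = _toy_ontology(n, edges)
            cl = classify(onto)
            dag = nx.DiGraph(edges)
            dag.add_nodes_from(range(n))
            for i in range(n):
                for j in range(n):
                    expected = i == j or nx.has_path(dag, i, j)
                    assert ((iris[i], iris[j]) in cl) == expected

    def test_unsatisfiable_class_raises_consistency_error(self):
        onto, iris = _toy_ontology(
            3, edges=[(0, 1), (0, 2)], disjoints=[(1, 2)])
        with pytest.raises(ConsistencyError):
            classify(onto)


def _single_row_graph(onto, std, moa="inhibition"):
    row = mb.AssayAnnotation(
        assay_id="1", measure_group_index=1, compound_id="7",
        endpoint_raw=std, endpoint_std=std, mode_of_action=moa,
        concentration_value="4.0", concentration_unit="uM",
        response_value="50", endpoint_uid="2_1")
    res = mb.load_annotations([row], onto)
    assert not res.rejected
    return res.graph


class TestMaterialize:
    def test_single_ic50_row_realizes_full_type_set(self, onto):
        g = materialize(_single_row_graph(onto, "IC50"), onto)
        r = onto.registry.iri
        endpoint = Iri(f"{BAO}individual_BAO_0000190_2_1")
        types = realize(endpoint, g)
        for label in ("IC50", "AC50", "perturbagen concentration endpoint",
                      "endpoint"):
            assert r(label) in types
        assert r("response endpoint") not in types
        assert r("percent inhibition") not in types

    def test_inverse_edge_inferred(self, onto):
        g = materialize(_single_row_graph(onto, "IC50"), onto)
        endpoint = Iri(f"{BAO}individual_BAO_0000190_2_1")
        compound = Iri(f"{BAO}individual_BAO_0000021_7")
        assert Triple(compound, onto.registry.iri("is perturbagen of"),
                      endpoint) in g.inferred

    def test_inverse_assertions_in_bijection(self, onto):
        g = materialize(_single_row_graph(onto, "IC50"), onto)
        union = g.union()
        fwd = {(t.subject, t.object)
               for t in union.match(None, onto.registry.iri("has perturbagen"), None)}
        inv = {(t.object, t.subject)
               for t in union.match(None, onto.registry.iri("is perturbagen of"), None)}
        assert fwd == inv

    def test_stimulation_and_activation_realize_identically(self, onto):
        r = onto.registry.iri
        g = Graph()
        a, b = Iri(BAO + "ind_a"), Iri(BAO + "ind_b")
        g.add(Triple(a, RDF_TYPE, r("stimulation")))
        g.add(Triple(b, RDF_TYPE, r("activation")))
        out = materialize(g, onto)
        assert realize(a, out) == realize(b, out)

    def test_empty_graph_yields_no_instance_inferences(self, onto):
        out = materialize(Graph(), onto)
        # only schema-level output appears: the subclass closure and the
        # typing of the enumerated 50%-response nominals
        schema_nodes = {Iri(BAO + lid) for lid, _l, _r in
                        onto.registry.entries()}
        instance_facts = [
            t for t in out.inferred
            if t.predicate != mb.Iri(
                "http://www.w3.org/2000/01/rdf-schema#subClassOf")
            and t.subject not in schema_nodes
        ]
        assert instance_facts == []

    def test_monotone_and_idempotent(self, onto):
        g = _single_row_graph(onto, "EC50", moa="activation")
        out1 = materialize(g, onto)
        # adding a fact never removes inferences
        g2 = g.copy()
        g2.add(Triple(Iri(BAO + "ind_x"), RDF_TYPE,
                      onto.registry.iri("inhibition")))
        out2 = materialize(g2, onto)
        assert set(out1.inferred) - set(iter(g2)) <= set(out2.inferred)
        # re-materializing the fixpoint adds nothing
        again = materialize(out1.union(), onto)
        assert len(again.inferred) == 0

    def test_base_and_inferred_disjoint(self, onto, ex1):
        g, _ = ex1
        assert all(t not in g.base for t in g.inferred)

    def test_disjointness_violation_reports_individual(self, onto):
        r = onto.registry.iri
        g = Graph()
        x = Iri(BAO + "ind_bad")
        g.add(Triple(x, RDF_TYPE, r("perturbagen")))
        g.add(Triple(x, RDF_TYPE, r("endpoint")))
        with pytest.raises(ConsistencyError, match="ind_bad"):
            materialize(g, onto)

    def test_unknown_individual_realizes_to_empty_set(self, onto):
        out = materialize(Graph(), onto)
        assert realize(Iri(BAO + "ghost"), out) == set()


class TestNaiveOracle:
    """materialize agrees with a naive, unoptimized rule applier on random
    small instance graphs over a toy ontology (subclass + equivalence +
    inverse + domain/range only)."""

    def _naive(self, graph, onto):
        triples = set(graph)
        subs = {}
        for a in onto.axioms:
            if isinstance(a, SubClassOf):
                subs.setdefault(a.sub.iri, set()).add(a.sup.iri)
            elif isinstance(a, EquivalentClasses):
                names = [m.iri for m in a.members]
                for x in names:
                    for y in names:
                        if x != y:
                            subs.setdefault(x, set()).add(y)
        inv = [(a.p, a.q) for a in onto.axioms if isinstance(a, InverseProperties)]
        doms = [(a.property, a.domain) for a in onto.axioms
                if isinstance(a, PropertyDomain)]
        rngs = [(a.property, a.range) for a in onto.axioms
                if isinstance(a, PropertyRange)]
        changed = True
        while changed:
            changed = False
            new = set()
            for t in triples:
                if t.predicate == RDF_TYPE:
                    for sup in subs.get(t.object, ()):
                        new.add(Triple(t.subject, RDF_TYPE, sup))
                for p, q in inv:
                    if t.predicate == p and not isinstance(t.object, Literal):
                        new.add(Triple(t.object, q, t.subject))
                    if t.predicate == q and not isinstance(t.object, Literal):
                        new.add(Triple(t.object, p, t.subject))
                for p, cls in doms:
                    if t.predicate == p:
                        new.add(Triple(t.subject, RDF_TYPE, cls))
                for p, cls in rngs:
                    if t.predicate == p and not isinstance(t.object, Literal):
                        new.add(Triple(t.object, RDF_TYPE, cls))
            if not new <= triples:
                triples |= new
                changed = True
        return triples

    def test_agreement_on_random_aboxes(self):
        rng = random.Random(11)
        reg = IdRegistry()
        classes = [reg.register(f"c{i}", f"C_{i}", "class") for i in range(5)]
        props = [reg.register(f"p{i}", f"P_{i}", "object property")
                 for i in range(3)]
        onto = Ontology(registry=reg)
        onto.axioms += [
            SubClassOf(Named(classes[0]), Named(classes[1])),
            SubClassOf(Named(classes[1]), Named(classes[2])),
            EquivalentClasses((Named(classes[3]), Named(classes[4]))),
            InverseProperties(props[0], props[1]),
            PropertyDomain(props[2], classes[0]),
            PropertyRange(props[2], classes[3]),
        ]
        inds = [Iri(BAO + f"i{k}") for k in range(6)]
        for trial in range(25):
            g = Graph()
            for _ in range(rng.randint(1, 12)):
                if rng.random() < 0.4:
                    g.add(Triple(rng.choice(inds), RDF_TYPE, rng.choice(classes)))
                else:
                    g.add(Triple(rng.choice(inds), rng.choice(props),
                                 rng.choice(inds)))
            ours = {t for t in materialize(g, onto).union()
                    if t.predicate != mb.Iri(
                        "http://www.w3.org/2000/01/rdf-schema#subClassOf")}
            naive = self._naive(g, onto)
            assert ours == naive
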