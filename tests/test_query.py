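"""Query evaluation semantics, against scan/enumeration oracles and the
worked-example fixtures."""

import itertools
import logging
import random

import pytest

import minibao as mb
from minibao.rdf_model import Graph, Iri, Literal, RDF_TYPE, Triple, Variable
from minibao.query import (
    BGP,
    And,
    Comparison,
    Filter,
    Query,
    TriplePattern,
    UnionPattern,
    evaluate,
    sparql_text,
    _plain,
)
from conftest import plain_rows

B = "http://example.org/"
V = Variable


def iri(x):
    return Iri(B + x)


# ----------------------------------------------------------------------
# independent oracles
# ----------------------------------------------------------------------


def _oracle_bgp_scan(patterns, g, binding):
    """Unoptimized backtracking: scan every triple for every pattern, in
    the given pattern order (no indexes, no reordering)."""
    if not patterns:
        return [binding]
    p, rest = patterns[0], patterns[1:]
    out = []
    for t in g.match(None, None, None):
        new = dict(binding)
        ok = True
        for term, val in ((p.subject, t.subject), (p.predicate, t.predicate),
                          (p.object, t.object)):
            if isinstance(term, Variable):
                if term in new and new[term] != val:
                    ok = False
                    break
                new[term] = val
            elif term != val:
                ok = False
                break
        if ok:
            out.extend(_oracle_bgp_scan(rest, g, new))
    return out


def _oracle_rows(pattern, g):
    if isinstance(pattern, BGP):
        return _oracle_bgp_scan(list(pattern.patterns), g, {})
    if isinstance(pattern, UnionPattern):
        return _oracle_rows(pattern.left, g) + _oracle_rows(pattern.right, g)
    if isinstance(pattern, Filter):
        out = []
        for row in _oracle_rows(pattern.pattern, g):
            keep = _oracle_expr(pattern.expr, row)
            if keep:
                out.append(row)
        return out
    raise TypeError(pattern)


def _oracle_expr(expr, row):
    if isinstance(expr, And):
        return all(_oracle_expr(p, row) for p in expr.parts)
    t = row.get(expr.var)
    if not isinstance(t, Literal):
        return False
    try:
        x = float(t.lexical)
    except ValueError:
        return False
    import operator

    ops = {"<=": operator.le, ">=": operator.ge, "<": operator.lt,
           ">": operator.gt, "=": operator.eq, "!=": operator.ne}
    return ops[expr.op](x, expr.value)


def _oracle_evaluate(query, g):
    """Scan-based oracle mirroring SELECT DISTINCT projection + sorting,
    sharing no code with the engine's join machinery."""
    from minibao.rdf_model import term_key

    rows = _oracle_rows(query.body, mb.query._as_graph(g))
    rows = [r for r in rows if all(v in r for v in query.select_vars)]
    if query.group_by is not None:
        hv, k = query.having_count_distinct
        groups = {}
        for r in rows:
            groups.setdefault(r[query.group_by], set()).add(r[hv])
        rows = [{query.group_by: key} for key, assays in groups.items()
                if len(assays) >= k]
    proj = {tuple((v.name, term_key(r[v])) for v in query.select_vars): r
            for r in rows}
    out = [{v: r[v] for v in query.select_vars} for r in proj.values()]
    out.sort(key=lambda r: tuple(term_key(r[v]) for v in query.select_vars))
    return out


def _oracle_enumerate(query, g):
    """True exhaustive-assignment oracle: try every assignment of query
    variables to terms occurring in the graph."""
    graph = mb.query._as_graph(g)
    terms = set()
    for t in graph:
        terms.update([t.subject, t.predicate, t.object])
    assert isinstance(query.body, (BGP, Filter))
    body = query.body
    expr = None
    if isinstance(body, Filter):
        body, expr = body.pattern, body.expr
    vs = sorted(body.variables(), key=lambda v: v.name)
    rows = []
    for combo in itertools.product(terms, repeat=len(vs)):
        binding = dict(zip(vs, combo))
        ok = True
        for p in body.patterns:
            def subst(term):
                return binding[term] if isinstance(term, Variable) else term
            try:
                t = Triple(subst(p.subject), subst(p.predicate), subst(p.object))
            except ValueError:
                ok = False
                break
            if t not in graph:
                ok = False
                break
        if ok and (expr is None or _oracle_expr(expr, binding)):
            rows.append(binding)
    from minibao.rdf_model import term_key

    seen = {}
    for r in rows:
        key = tuple(term_key(r[v]) for v in query.select_vars)
        seen[key] = {v: r[v] for v in query.select_vars}
    return [seen[k] for k in sorted(seen)]


# ----------------------------------------------------------------------


def _random_graph(rng, n):
    g = Graph()
    subjects = [iri(f"s{i}") for i in range(5)]
    preds = [iri(f"p{i}") for i in range(3)]
    objects = subjects + [Literal(str(v), "float") for v in (10, 50, 80)]
    for _ in range(n):
        g.add(Triple(rng.choice(subjects), rng.choice(preds),
                     rng.choice(objects)))
    return g


class TestEvaluate:
    def test_single_pattern_matches_scan(self, ex3, onto):
        g, _ = ex3
        q = Query((V("x"),),
                  BGP((TriplePattern(V("x"), RDF_TYPE,
                                     onto.registry.iri("perturbagen")),)))
        got = evaluate(q, g)
        oracle = _oracle_evaluate(q, g)
        assert got == oracle
        assert len(got) == 3  # the three fixture compounds

    def test_unsatisfiable_filter_returns_empty(self, ex1, onto):
        g, _ = ex1
        assert mb.example1_active_inhibitors(g, onto, conc_max=-1) == []

    def test_small_random_graphs_match_enumeration_oracle(self):
        rng = random.Random(3)
        q = Query(
            (V("x"), V("y")),
            Filter(
                BGP((
                    TriplePattern(V("x"), iri("p0"), V("y")),
                    TriplePattern(V("x"), iri("p1"), V("v")),
                )),
                Comparison(V("v"), ">=", 50),
            ),
        )
        for _ in range(20):
            g = _random_graph(rng, rng.randint(3, 25))
            assert evaluate(q, g) == _oracle_enumerate(q, g)

    def test_fixture_queries_match_scan_oracle(self, ex1, ex2, onto):
        from minibao.query import build_example_query

        g1, _ = ex1
        q1 = build_example_query(onto, onto.registry.iri("inhibition"))
        assert evaluate(q1, g1) == _oracle_evaluate(q1, g1)
        g2, _ = ex2
        q2 = build_example_query(onto, onto.registry.iri("activation"),
                                 with_moa_type=True)
        assert evaluate(q2, g2) == _oracle_evaluate(q2, g2)

    def test_non_numeric_filter_binding_drops_row_with_warning(self, caplog):
        g = Graph()
        g.add(Triple(iri("s"), iri("p"), Literal("not-a-number")))
        g.add(Triple(iri("s"), iri("p"), Literal("60", "float")))
        q = Query((V("v"),),
                  Filter(BGP((TriplePattern(iri("s"), iri("p"), V("v")),)),
                         Comparison(V("v"), ">=", 50)))
        with caplog.at_level(logging.WARNING, logger="minibao.query"):
            rows = evaluate(q, g)
        assert [r[V("v")].lexical for r in rows] == ["60"]
        assert any("non-numeric" in m for m in caplog.messages)

    def test_select_var_must_occur_in_body(self):
        with pytest.raises(ValueError, match="does not occur"):
            Query((V("ghost"),),
                  BGP((TriplePattern(V("x"), iri("p"), V("y")),)))

    def test_filter_must_reference_bound_vars(self):
        with pytest.raises(ValueError, match="unbound"):
            Query((V("x"),),
                  Filter(BGP((TriplePattern(V("x"), iri("p"), V("y")),)),
                         Comparison(V("z"), ">=", 1)))


class TestWorkedExamples:
    def test_example1_fixture_rows_exact(self, ex1, onto):
        g, expected = ex1
        got = plain_rows(mb.example1_active_inhibitors(g, onto))
        assert sorted(got, key=str) == sorted(expected, key=str)

    def test_example1_printed_tuples_present(self, ex1, onto):
        g, _ = ex1
        got = plain_rows(mb.example1_active_inhibitors(g, onto))
        bao = mb.BAO
        printed = [
            {"compound": f"{bao}individual_BAO_0000021_2858522",
             "endpoint": f"{bao}individual_BAO_0000190_2_2357",
             "type": f"{bao}BAO_0000190", "responseValue": "50",
             "screeningConc": "4.0",
             "assay": f"{bao}individual_BAO_0000015_1293"},
            {"compound": f"{bao}individual_BAO_0000021_133407",
             "endpoint": f"{bao}individual_BAO_0000190_2_2533",
             "type": f"{bao}BAO_0000190", "responseValue": "50",
             "screeningConc": "8.59",
             "assay": f"{bao}individual_BAO_0000015_2409"},
            {"compound": f"{bao}individual_BAO_0000021_11057",
             "endpoint": f"{bao}individual_BAO_0000190_2_4122",
             "type": f"{bao}BAO_0000186", "responseValue": "50",
             "screeningConc": "6.3096",
             "assay": f"{bao}individual_BAO_0000015_948"},
            {"compound": f"{bao}individual_BAO_0000021_657680",
             "endpoint": f"{bao}individual_BAO_0000201_1_1670",
             "type": f"{bao}BAO_0000201", "responseValue": "63.48",
             "screeningConc": "4.0",
             "assay": f"{bao}individual_BAO_0000015_834"},
        ]
        for row in printed:
            assert row in got

    def test_example1_ac50_endpoint_also_surfaces_as_ic50(self, ex1, onto):
        g, _ = ex1
        got = plain_rows(mb.example1_active_inhibitors(g, onto))
        for_11057 = {r["type"] for r in got
                     if r["compound"].endswith("_11057")}
        assert f"{mb.BAO}BAO_0000186" in for_11057
        assert f"{mb.BAO}BAO_0000190" in for_11057

    def test_example1_distractors_absent(self, ex1, onto):
        g, _ = ex1
        got = plain_rows(mb.example1_active_inhibitors(g, onto))
        compounds = {r["compound"].rsplit("_", 1)[1] for r in got}
        assert {"900001", "900002", "900003"}.isdisjoint(compounds)
        # inclusive boundaries pass
        assert {"900004", "900005"} <= compounds

    def test_example2_fixture_rows_exact(self, ex2, onto):
        g, expected = ex2
        got = plain_rows(mb.example2_activators(g, onto))
        assert sorted(got, key=str) == sorted(expected, key=str)

    def test_example2_stimulation_only_row_found_via_equivalence(self, ex2, onto):
        g, _ = ex2
        got = plain_rows(mb.example2_activators(g, onto))
        rows_645132 = [r for r in got if r["compound"].endswith("_645132")]
        assert rows_645132, "stimulation-asserted endpoint must be retrieved"
        assert {r["responseValue"] for r in rows_645132} == {"132.52"}
        assert {r["screeningConc"] for r in rows_645132} == {"5.7"}
        moa_types = {r["moaType"] for r in rows_645132}
        assert f"{mb.BAO}BAO_0000087" in moa_types  # activation
        assert f"{mb.BAO}BAO_0000093" in moa_types  # stimulation

    def test_example2_activation_and_stimulation_queries_agree(self, ex2, onto):
        g, _ = ex2
        act = plain_rows(mb.example2_activators(g, onto, moa_label="activation"))
        stim = plain_rows(mb.example2_activators(g, onto, moa_label="stimulation"))
        assert act == stim

    def test_example3_promiscuous_and_profile(self, ex3, onto):
        g, expected = ex3
        perts = mb.example3_promiscuous(g, onto)
        assert [p.value for p in perts] == expected["promiscuous"]
        prof = plain_rows(mb.example3_profile(g, onto, perts[0]))
        assert sorted(prof, key=str) == sorted(expected["profile"], key=str)

    def test_example3_two_assay_compound_excluded(self, ex3, onto):
        g, _ = ex3
        perts = {p.value for p in mb.example3_promiscuous(g, onto)}
        assert not any(p.endswith("_700001") for p in perts)
        assert not any(p.endswith("_700002") for p in perts)

    def test_example3_requires_inferred_inverse_edges(self, ex3, onto):
        g, _ = ex3
        assert mb.example3_promiscuous(g.base, onto) == []

    def test_profile_of_unknown_perturbagen_is_empty(self, ex3, onto):
        g, _ = ex3
        assert mb.example3_profile(g, onto, Iri(mb.BAO + "ghost")) == []

    def test_sparql_text_mentions_filter_and_union(self, onto):
        from minibao.query import build_example_query

        text = sparql_text(build_example_query(onto))
        assert "SELECT DISTINCT" in text
        assert "UNION" in text
        assert "FILTER" in text and "<= 10" in text and ">= 50" in text
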