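"""SPARQL-subset query AST and evaluator.

Supports basic graph patterns (BGP) with variable joins, UNION, numeric
FILTERs over float literals, SELECT DISTINCT projection, and GROUP BY with
a count-distinct HAVING threshold -- the fragment needed for the three
worked assay queries (active inhibitors, activators, promiscuous
perturbagens).  Queries are built as ASTs, not parsed from text; a
serializer prints them in SPARQL-like syntax for inspection.

Result rows are canonically sorted over the projected bindings so output
is reproducible; the workflow's numeric result indices are presentation
order only and are not modeled.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Union as TUnion

from .rdf_model import (
    Graph,
    Iri,
    Literal,
    RDF_TYPE,
    RDFS_SUBCLASSOF,
    Term,
    Variable,
    term_key,
)
from .reasoner import InferredGraph
from .schema import Ontology

logger = logging.getLogger(__name__)

__all__ = [
    "TriplePattern",
    "BGP",
    "UnionPattern",
    "Comparison",
    "And",
    "Or",
    "Filter",
    "Query",
    "BindingRow",
    "evaluate",
    "sparql_text",
    "rows_to_tsv",
    "rows_to_jsonl",
    "example1_active_inhibitors",
    "example2_activators",
    "example3_promiscuous",
    "example3_profile",
    "build_example_query",
]


@dataclass(frozen=True)
class TriplePattern:
    subject: Term
    predicate: Term
    object: Term

    def variables(self) -> set:
        return {t for t in (self.subject, self.predicate, self.object)
                if isinstance(t, Variable)}


@dataclass(frozen=True)
class BGP:
    patterns: tuple

    def variables(self) -> set:
        out: set = set()
        for p in self.patterns:
            out |= p.variables()
        return out


@dataclass(frozen=True)
class UnionPattern:
    left: "Pattern"
    right: "Pattern"

    def variables(self) -> set:
        return self.left.variables() | self.right.variables()


@dataclass(frozen=True)
class Comparison:
    var: Variable
    op: str  # <=, >=, <, >, =, !=
    value: float

    def variables(self) -> set:
        return {self.var}


@dataclass(frozen=True)
class And:
    parts: tuple

    def variables(self) -> set:
        return set().union(*(p.variables() for p in self.parts))


@dataclass(frozen=True)
class Or:
    parts: tuple

    def variables(self) -> set:
        return set().union(*(p.variables() for p in self.parts))


BoolExpr = TUnion[Comparison, And, Or]


@dataclass(frozen=True)
class Filter:
    pattern: "Pattern"
    expr: BoolExpr

    def variables(self) -> set:
        return self.pattern.variables()


Pattern = TUnion[BGP, UnionPattern, Filter]

#: a solution row: variable -> ground term
BindingRow = dict


@dataclass(frozen=True)
class Query:
    select_vars: tuple
    body: Pattern
    distinct: bool = True
    group_by: Optional[Variable] = None
    having_count_distinct: Optional[tuple] = None  # (Variable, int threshold)

    def __post_init__(self):
        body_vars = self.body.variables()
        for v in self.select_vars:
            if v not in body_vars:
                raise ValueError(f"select variable {v} does not occur in body")
        if self.group_by is not None and self.group_by not in body_vars:
            raise ValueError(f"group variable {self.group_by} does not occur in body")
        if self.having_count_distinct is not None:
            hv, k = self.having_count_distinct
            if hv not in body_vars:
                raise ValueError(f"having variable {hv} does not occur in body")
        _check_filter_vars(self.body)


def _check_filter_vars(pattern: Pattern) -> None:
    if isinstance(pattern, Filter):
        unbound = pattern.expr.variables() - pattern.pattern.variables()
        if unbound:
            raise ValueError(f"filter references unbound variables {unbound}")
        _check_filter_vars(pattern.pattern)
    elif isinstance(pattern, UnionPattern):
        _check_filter_vars(pattern.left)
        _check_filter_vars(pattern.right)


# ----------------------------------------------------------------------
# Evaluation
# ----------------------------------------------------------------------


def _substitute(t: Term, binding: BindingRow) -> Optional[Term]:
    if isinstance(t, Variable):
        return binding.get(t)
    return t


def _eval_bgp(bgp: BGP, g: Graph) -> list[BindingRow]:
    # greedy join order: most-constrained pattern first given bound vars
    remaining = list(bgp.patterns)
    ordered: list[TriplePattern] = []
    bound: set = set()

    def score(p: TriplePattern) -> tuple:
        terms = (p.subject, p.predicate, p.object)
        n_const = sum(1 for t in terms if not isinstance(t, Variable))
        n_bound = sum(1 for t in terms if isinstance(t, Variable) and t in bound)
        return (-(n_const + n_bound), -n_const)

    while remaining:
        if ordered:
            connected = [p for p in remaining if p.variables() & bound] or remaining
        else:
            connected = remaining
        nxt = min(connected, key=score)
        remaining.remove(nxt)
        ordered.append(nxt)
        bound |= nxt.variables()

    solutions: list[BindingRow] = [{}]
    for p in ordered:
        next_solutions: list[BindingRow] = []
        for binding in solutions:
            s = _substitute(p.subject, binding)
            pr = _substitute(p.predicate, binding)
            o = _substitute(p.object, binding)
            for t in g.match(s, pr, o):
                new = dict(binding)
                ok = True
                for term, val in ((p.subject, t.subject), (p.predicate, t.predicate),
                                  (p.object, t.object)):
                    if isinstance(term, Variable):
                        if term in new and new[term] != val:
                            ok = False
                            break
                        new[term] = val
                if ok:
                    next_solutions.append(new)
        solutions = next_solutions
        if not solutions:
            break
    return solutions


def _eval_expr(expr: BoolExpr, row: BindingRow) -> Optional[bool]:
    """None signals a non-numeric or unbound operand (row is dropped)."""
    if isinstance(expr, And):
        vals = [_eval_expr(p, row) for p in expr.parts]
        return None if any(v is None for v in vals) else all(vals)
    if isinstance(expr, Or):
        vals = [_eval_expr(p, row) for p in expr.parts]
        return None if any(v is None for v in vals) else any(vals)
    term = row.get(expr.var)
    if not isinstance(term, Literal) or not term.is_numeric():
        return None
    x = term.as_float()
    return {
        "<=": x <= expr.value,
        ">=": x >= expr.value,
        "<": x < expr.value,
        ">": x > expr.value,
        "=": x == expr.value,
        "!=": x != expr.value,
    }[expr.op]


def _eval_pattern(pattern: Pattern, g: Graph) -> list[BindingRow]:
    if isinstance(pattern, BGP):
        return _eval_bgp(pattern, g)
    if isinstance(pattern, UnionPattern):
        return _eval_pattern(pattern.left, g) + _eval_pattern(pattern.right, g)
    if isinstance(pattern, Filter):
        out = []
        for row in _eval_pattern(pattern.pattern, g):
            verdict = _eval_expr(pattern.expr, row)
            if verdict is None:
                logger.warning("filter over non-numeric binding; row dropped: %s", row)
            elif verdict:
                out.append(row)
        return out
    raise TypeError(f"unknown pattern {pattern!r}")


def _as_graph(g) -> Graph:
    if isinstance(g, InferredGraph):
        if not hasattr(g, "_union_cache"):
            g._union_cache = g.union()
        return g._union_cache
    return g


def _row_key(row: BindingRow, select_vars: Sequence[Variable]) -> tuple:
    return tuple(term_key(row[v]) for v in select_vars)


def evaluate(query: Query, g) -> list[BindingRow]:
    """Evaluate a query over a Graph or an InferredGraph (asserted+inferred).

    Returns projected rows, canonically sorted; duplicate-free when the
    query is DISTINCT.
    """
    graph = _as_graph(g)
    rows = _eval_pattern(query.body, graph)
    # drop rows not total over select vars (possible under UNION branches)
    rows = [r for r in rows if all(v in r for v in query.select_vars)]

    if query.group_by is not None:
        hv, k = query.having_count_distinct or (None, 0)
        groups: dict = {}
        for r in rows:
            groups.setdefault(r[query.group_by], []).append(r)
        kept = []
        for key_term, members in groups.items():
            if hv is not None:
                if len({m[hv] for m in members if hv in m}) < k:
                    continue
            kept.append({query.group_by: key_term})
        rows = kept

    projected = [{v: r[v] for v in query.select_vars} for r in rows]
    if query.distinct:
        seen, out = set(), []
        for r in projected:
            k = _row_key(r, query.select_vars)
            if k not in seen:
                seen.add(k)
                out.append(r)
        projected = out
    projected.sort(key=lambda r: _row_key(r, query.select_vars))
    return projected


# ----------------------------------------------------------------------
# SPARQL-like serializer (documentation/CLI aid)
# ----------------------------------------------------------------------


def _fmt_term(t: Term) -> str:
    return repr(t)


def _fmt_expr(expr: BoolExpr) -> str:
    if isinstance(expr, And):
        return " && ".join(_fmt_expr(p) for p in expr.parts)
    if isinstance(expr, Or):
        return " || ".join(_fmt_expr(p) for p in expr.parts)
    return f"?{expr.var.name} {expr.op} {expr.value:g}"


def _fmt_pattern(pattern: Pattern, indent: str = "  ") -> str:
    if isinstance(pattern, BGP):
        return "\n".join(
            f"{indent}{_fmt_term(p.subject)} {_fmt_term(p.predicate)} "
            f"{_fmt_term(p.object)} ."
            for p in pattern.patterns
        )
    if isinstance(pattern, UnionPattern):
        return (
            f"{indent}{{\n{_fmt_pattern(pattern.left, indent + '  ')}\n{indent}}}\n"
            f"{indent}UNION\n"
            f"{indent}{{\n{_fmt_pattern(pattern.right, indent + '  ')}\n{indent}}}"
        )
    if isinstance(pattern, Filter):
        return (
            f"{_fmt_pattern(pattern.pattern, indent)}\n"
            f"{indent}FILTER({_fmt_expr(pattern.expr)})"
        )
    raise TypeError(f"unknown pattern {pattern!r}")


def sparql_text(query: Query) -> str:
    head = "SELECT " + ("DISTINCT " if query.distinct else "")
    head += " ".join(f"?{v.name}" for v in query.select_vars)
    out = f"{head}\nWHERE {{\n{_fmt_pattern(query.body)}\n}}"
    if query.group_by is not None:
        out += f"\nGROUP BY ?{query.group_by.name}"
    if query.having_count_distinct is not None:
        hv, k = query.having_count_distinct
        out += f"\nHAVING (count(distinct ?{hv.name}) >= {k})"
    return out


def rows_to_tsv(rows: list[BindingRow], select_vars: Sequence[Variable]) -> str:
    lines = ["\t".join(v.name for v in select_vars)]
    for r in rows:
        lines.append("\t".join(_plain(r[v]) for v in select_vars))
    return "\n".join(lines) + "\n"


def rows_to_jsonl(rows: list[BindingRow], select_vars: Sequence[Variable]) -> str:
    out = []
    for r in rows:
        out.append(json.dumps({v.name: _plain(r[v]) for v in select_vars}))
    return "\n".join(out) + ("\n" if out else "")


def _plain(t: Term) -> str:
    if isinstance(t, Iri):
        return t.value
    if isinstance(t, Literal):
        return t.lexical
    return repr(t)


# ----------------------------------------------------------------------
# The three worked queries
# ----------------------------------------------------------------------

V = Variable


def _shared_tail(onto: Ontology) -> list[TriplePattern]:
    c = onto.registry.iri
    return [
        TriplePattern(V("endpoint"), c("has perturbagen"), V("compound")),
        TriplePattern(V("assay"), c("has measure group"), V("measureGroup")),
        TriplePattern(V("measureGroup"), c("has endpoint"), V("endpoint")),
    ]


def build_example_query(
    onto: Ontology,
    moa_class: Optional[Iri] = None,
    *,
    with_moa_type: bool = False,
    conc_max: float = 10.0,
    resp_min: float = 50.0,
) -> Query:
    """The endpoint-activity query skeleton shared by the first two examples.

    ``moa_class`` restricts the mode-of-action node (inhibition for the
    inhibitor query, activation for the activator query);
    ``with_moa_type`` additionally binds ?moaType over the realized
    mode-of-action classes.
    """
    c = onto.registry.iri
    if moa_class is None:
        moa_class = c("inhibition")
    moa_patterns = [
        TriplePattern(V("endpoint"), c("has mode of action"), V("moa")),
        TriplePattern(V("moa"), RDF_TYPE, moa_class),
    ]
    if with_moa_type:
        moa_patterns += [
            TriplePattern(V("moa"), RDF_TYPE, V("moaType")),
            TriplePattern(V("moaType"), RDFS_SUBCLASSOF, c("mode of action")),
        ]
    conc_branch = BGP(tuple(
        [
            TriplePattern(V("endpoint"), RDF_TYPE, c("endpoint")),
            *moa_patterns,
            TriplePattern(V("endpoint"), c("has screening concentration value"),
                          V("screeningConc")),
            TriplePattern(V("endpoint"), c("has concentration unit"),
                          c("micromolar")),
            TriplePattern(V("endpoint"), c("has percent response"),
                          V("percentResponse")),
            TriplePattern(V("percentResponse"), c("has response value"),
                          V("responseValue")),
            TriplePattern(V("endpoint"), RDF_TYPE, V("type")),
            TriplePattern(V("type"), RDFS_SUBCLASSOF,
                          c("perturbagen concentration endpoint")),
        ]
        + _shared_tail(onto)
    ))
    resp_branch = BGP(tuple(
        [
            TriplePattern(V("endpoint"), RDF_TYPE, c("endpoint")),
            *moa_patterns,
            TriplePattern(V("endpoint"), c("has screening concentration spec"),
                          V("concSpec")),
            TriplePattern(V("concSpec"), c("has concentration unit"),
                          c("micromolar")),
            TriplePattern(V("concSpec"), c("has screening concentration value"),
                          V("screeningConc")),
            TriplePattern(V("endpoint"), c("has response value"),
                          V("responseValue")),
            TriplePattern(V("endpoint"), RDF_TYPE, V("type")),
            TriplePattern(V("type"), RDFS_SUBCLASSOF, c("response endpoint")),
        ]
        + _shared_tail(onto)
    ))
    body = Filter(
        UnionPattern(conc_branch, resp_branch),
        And((
            Comparison(V("screeningConc"), "<=", conc_max),
            Comparison(V("responseValue"), ">=", resp_min),
        )),
    )
    select = [V("compound"), V("endpoint"), V("type")]
    if with_moa_type:
        select.append(V("moaType"))
    select += [V("responseValue"), V("screeningConc"), V("assay")]
    return Query(tuple(select), body)


def example1_active_inhibitors(
    g, onto: Ontology, conc_max: float = 10.0, resp_min: float = 50.0
) -> list[BindingRow]:
    """Compounds from inhibitory assays with response >= ``resp_min`` %
    at <= ``conc_max`` uM, across concentration- and response-type
    endpoints (subsumption makes AC50-typed rows surface as IC50 hits and
    vice versa)."""
    q = build_example_query(onto, onto.registry.iri("inhibition"),
                            conc_max=conc_max, resp_min=resp_min)
    return evaluate(q, g)


def example2_activators(
    g,
    onto: Ontology,
    conc_max: float = 10.0,
    resp_min: float = 50.0,
    moa_label: str = "activation",
) -> list[BindingRow]:
    """Activator query; ?moaType ranges over the realized mode-of-action
    classes, so activation/stimulation equivalence is visible in the rows.
    ``moa_label`` may be any registered mode-of-action class; equivalent
    labels return identical result sets."""
    q = build_example_query(onto, onto.registry.iri(moa_label),
                            with_moa_type=True, conc_max=conc_max,
                            resp_min=resp_min)
    return evaluate(q, g)


def _profile_branches(onto: Ontology, pert_term: Term) -> UnionPattern:
    c = onto.registry.iri
    head = [
        TriplePattern(pert_term, c("is perturbagen of"), V("assay")),
        TriplePattern(V("assay"), c("has measure group"), V("measureGroup")),
        TriplePattern(V("measureGroup"), c("has endpoint"), V("endpoint")),
        TriplePattern(pert_term, c("is perturbagen of"), V("endpoint")),
    ]
    direct = BGP(tuple(head + [
        TriplePattern(V("endpoint"), c("has response value"),
                      V("percentResponseValue")),
    ]))
    via_nominal = BGP(tuple(head + [
        TriplePattern(V("endpoint"), c("has percent response"),
                      V("percentResponse")),
        TriplePattern(V("percentResponse"), c("has response value"),
                      V("percentResponseValue")),
    ]))
    return UnionPattern(direct, via_nominal)


def example3_promiscuous(
    g, onto: Ontology, min_assays: int = 3, resp_min: float = 50.0
) -> list[Iri]:
    """Perturbagens with response >= ``resp_min`` % in at least
    ``min_assays`` distinct assays.

    Load-bearing inference: the instance data asserts only the forward
    has-perturbagen direction, so the ?pert -> assay/endpoint edges exist
    only after inverse-property materialization.
    """
    c = onto.registry.iri
    pert = V("pert")
    body = Filter(
        _prepend_type(_profile_branches(onto, pert), pert, c("perturbagen")),
        Comparison(V("percentResponseValue"), ">=", resp_min),
    )
    q = Query((pert,), body, group_by=pert,
              having_count_distinct=(V("assay"), min_assays))
    return [row[pert] for row in evaluate(q, g)]


def _prepend_type(union: UnionPattern, var: Variable, cls: Iri) -> UnionPattern:
    tp = TriplePattern(var, RDF_TYPE, cls)
    return UnionPattern(
        BGP((tp,) + union.left.patterns), BGP((tp,) + union.right.patterns)
    )


def example3_profile(g, onto: Ontology, perturbagen: Iri,
                     resp_min: float = 50.0) -> list[BindingRow]:
    """(assay, percent response) profile of one perturbagen; empty for an
    unknown perturbagen."""
    body = Filter(
        _profile_branches(onto, perturbagen),
        Comparison(V("percentResponseValue"), ">=", resp_min),
    )
    q = Query((V("assay"), V("percentResponseValue")), body)
    return evaluate(q, g)
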