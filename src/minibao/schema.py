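"""Mini BioAssay Ontology: identifier registry, class expressions, axioms.

The registry pins the BAO accession numbers that appear in the worked
queries (IC50 = BAO_0000190, AC50 = BAO_0000186, ...).  Supporting terms
that the public accession list does not fix (measure group, CC50, the
50%-response nominal individuals, ...) are minted in the same style; they
are flagged ``invented`` in the registry table below.

The description-logic fragment covers named classes, intersections,
unions, existential/universal restrictions, hasValue, exact cardinality,
and small enumerated (nominal) classes -- exactly the constructs the
endpoint definitions use.  The headline definitions:

    IC50 = (some hasModeOfAction . inhibition)
           and (only hasModeOfAction . inhibition)
           and (hasPercentResponse value fifty_percent_inhibition)

    EC50 analogous with activation / fifty_percent_activation.

    AC50 = (some hasModeOfAction . (inhibition or activation))
           and (only hasModeOfAction . (inhibition or activation))
           and (some hasPercentResponse . fifty_percent_response)

where fifty_percent_response = {fifty_percent_inhibition,
fifty_percent_activation}.  This is what makes IC50 and EC50 classify
under AC50 (and not conversely).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

from .rdf_model import (
    Graph,
    Iri,
    Literal,
    OWL_NS,
    RDF_NS,
    RDFS_NS,
    RDF_TYPE,
    RDFS_SUBCLASSOF,
    Triple,
)

__all__ = [
    "BAO",
    "Named",
    "Intersection",
    "Union_",
    "SomeValuesFrom",
    "AllValuesFrom",
    "HasValue",
    "ExactCardinality",
    "OneOf",
    "DataExact",
    "ClassExpression",
    "SubClassOf",
    "EquivalentClasses",
    "DisjointClasses",
    "InverseProperties",
    "PropertyDomain",
    "PropertyRange",
    "ClassAssertion",
    "PropertyAssertion",
    "Axiom",
    "IdRegistry",
    "Ontology",
    "normalize",
    "build_mini_bao",
    "ontology_from_graph",
]

BAO = "http://www.bioassayontology.org/bao#"

OWL_CLASS = Iri(OWL_NS + "Class")
OWL_RESTRICTION = Iri(OWL_NS + "Restriction")
OWL_OBJECT_PROPERTY = Iri(OWL_NS + "ObjectProperty")
OWL_DATATYPE_PROPERTY = Iri(OWL_NS + "DatatypeProperty")
OWL_NAMED_INDIVIDUAL = Iri(OWL_NS + "NamedIndividual")
OWL_EQUIVALENT_CLASS = Iri(OWL_NS + "equivalentClass")
OWL_DISJOINT_WITH = Iri(OWL_NS + "disjointWith")
OWL_INVERSE_OF = Iri(OWL_NS + "inverseOf")
OWL_ON_PROPERTY = Iri(OWL_NS + "onProperty")
OWL_SOME_VALUES_FROM = Iri(OWL_NS + "someValuesFrom")
OWL_ALL_VALUES_FROM = Iri(OWL_NS + "allValuesFrom")
OWL_HAS_VALUE = Iri(OWL_NS + "hasValue")
OWL_CARDINALITY = Iri(OWL_NS + "cardinality")
OWL_QUALIFIED_CARDINALITY = Iri(OWL_NS + "qualifiedCardinality")
OWL_ON_CLASS = Iri(OWL_NS + "onClass")
OWL_INTERSECTION_OF = Iri(OWL_NS + "intersectionOf")
OWL_UNION_OF = Iri(OWL_NS + "unionOf")
OWL_ONE_OF = Iri(OWL_NS + "oneOf")
RDFS_LABEL = Iri(RDFS_NS + "label")
RDFS_DOMAIN = Iri(RDFS_NS + "domain")
RDFS_RANGE = Iri(RDFS_NS + "range")
RDF_FIRST = Iri(RDF_NS + "first")
RDF_REST = Iri(RDF_NS + "rest")
RDF_NIL = Iri(RDF_NS + "nil")


# ----------------------------------------------------------------------
# Class expressions
# ----------------------------------------------------------------------


@dataclass(frozen=True)
class Named:
    iri: Iri


@dataclass(frozen=True)
class Intersection:
    members: tuple

    def __post_init__(self):
        if len(self.members) < 2:
            raise ValueError("intersection needs at least 2 members")


@dataclass(frozen=True)
class Union_:
    members: tuple

    def __post_init__(self):
        if len(self.members) < 2:
            raise ValueError("union needs at least 2 members")


@dataclass(frozen=True)
class SomeValuesFrom:
    property: Iri
    filler: "ClassExpression"


@dataclass(frozen=True)
class AllValuesFrom:
    property: Iri
    filler: "ClassExpression"


@dataclass(frozen=True)
class HasValue:
    property: Iri
    individual: Iri


@dataclass(frozen=True)
class ExactCardinality:
    property: Iri
    n: int
    filler: Optional["ClassExpression"] = None

    def __post_init__(self):
        if self.n < 0:
            raise ValueError("cardinality must be non-negative")


@dataclass(frozen=True)
class OneOf:
    """Nominal class: enumeration of named individuals."""

    individuals: frozenset


@dataclass(frozen=True)
class DataExact:
    """Exact cardinality over a datatype property (``= n p.xsd:float``)."""

    property: Iri
    n: int


ClassExpression = Union[
    Named, Intersection, Union_, SomeValuesFrom, AllValuesFrom, HasValue,
    ExactCardinality, OneOf, DataExact,
]


def _expr_key(e: ClassExpression) -> tuple:
    if isinstance(e, Named):
        return (0, e.iri.value)
    if isinstance(e, SomeValuesFrom):
        return (1, e.property.value, _expr_key(e.filler))
    if isinstance(e, AllValuesFrom):
        return (2, e.property.value, _expr_key(e.filler))
    if isinstance(e, HasValue):
        return (3, e.property.value, e.individual.value)
    if isinstance(e, ExactCardinality):
        return (4, e.property.value, e.n, _expr_key(e.filler) if e.filler else ())
    if isinstance(e, DataExact):
        return (5, e.property.value, e.n)
    if isinstance(e, OneOf):
        return (6, tuple(sorted(i.value for i in e.individuals)))
    if isinstance(e, Intersection):
        return (7, tuple(_expr_key(m) for m in e.members))
    return (8, tuple(_expr_key(m) for m in e.members))


def normalize(expr: ClassExpression) -> ClassExpression:
    """Canonical form: flatten nested and/or, sort and dedupe members.

    Idempotent; single-member and/or collapse to the member itself.
    """
    if isinstance(expr, Intersection) or isinstance(expr, Union_):
        cls = type(expr)
        flat: list[ClassExpression] = []
        for m in expr.members:
            m = normalize(m)
            if isinstance(m, cls):
                flat.extend(m.members)
            else:
                flat.append(m)
        seen, out = set(), []
        for m in sorted(flat, key=_expr_key):
            k = _expr_key(m)
            if k not in seen:
                seen.add(k)
                out.append(m)
        if len(out) == 1:
            return out[0]
        return cls(tuple(out))
    if isinstance(expr, SomeValuesFrom):
        return SomeValuesFrom(expr.property, normalize(expr.filler))
    if isinstance(expr, AllValuesFrom):
        return AllValuesFrom(expr.property, normalize(expr.filler))
    if isinstance(expr, ExactCardinality) and expr.filler is not None:
        return ExactCardinality(expr.property, expr.n, normalize(expr.filler))
    return expr


def conjuncts(expr: ClassExpression) -> tuple:
    """Top-level conjuncts of a normalized expression."""
    expr = normalize(expr)
    if isinstance(expr, Intersection):
        return expr.members
    return (expr,)


# ----------------------------------------------------------------------
# Axioms
# ----------------------------------------------------------------------


@dataclass(frozen=True)
class SubClassOf:
    sub: ClassExpression
    sup: ClassExpression


@dataclass(frozen=True)
class EquivalentClasses:
    members: tuple


@dataclass(frozen=True)
class DisjointClasses:
    members: tuple


@dataclass(frozen=True)
class InverseProperties:
    p: Iri
    q: Iri


@dataclass(frozen=True)
class PropertyDomain:
    property: Iri
    domain: Iri


@dataclass(frozen=True)
class PropertyRange:
    property: Iri
    range: Iri


@dataclass(frozen=True)
class ClassAssertion:
    class_expr: ClassExpression
    individual: Iri


@dataclass(frozen=True)
class PropertyAssertion:
    property: Iri
    subject: Iri
    object: object  # Iri or Literal


Axiom = Union[
    SubClassOf, EquivalentClasses, DisjointClasses, InverseProperties,
    PropertyDomain, PropertyRange, ClassAssertion, PropertyAssertion,
]


# ----------------------------------------------------------------------
# Identifier registry
# ----------------------------------------------------------------------


class IdRegistry:
    """Bidirectional label <-> BAO accession map with a role tag per entry."""

    ROLES = ("class", "object property", "datatype property", "individual")

    def __init__(self, base: str = BAO):
        self.base = base
        self._by_label: dict[str, str] = {}
        self._by_id: dict[str, str] = {}
        self._role: dict[str, str] = {}

    def register(self, label: str, local_id: str, role: str) -> Iri:
        if role not in self.ROLES:
            raise ValueError(f"unknown role {role!r}")
        if label in self._by_label and self._by_label[label] != local_id:
            raise ValueError(f"label {label!r} already bound")
        if local_id in self._by_id and self._by_id[local_id] != label:
            raise ValueError(f"id {local_id!r} already bound")
        self._by_label[label] = local_id
        self._by_id[local_id] = label
        self._role[local_id] = role
        return Iri(self.base + local_id)

    def iri(self, label: str) -> Iri:
        return Iri(self.base + self._by_label[label])

    def local_id(self, label: str) -> str:
        return self._by_label[label]

    def label(self, local_id: str) -> str:
        return self._by_id[local_id]

    def label_of_iri(self, iri: Iri) -> str:
        return self._by_id[iri.value.removeprefix(self.base)]

    def role(self, local_id: str) -> str:
        return self._role[local_id]

    def __contains__(self, label: str) -> bool:
        return label in self._by_label

    def entries(self) -> list[tuple[str, str, str]]:
        return sorted(
            (lid, self._by_id[lid], self._role[lid]) for lid in self._by_id
        )


@dataclass
class Ontology:
    registry: IdRegistry
    axioms: list = field(default_factory=list)
    #: defined (necessary-and-sufficient) classes -> normalized expression
    definitions: dict = field(default_factory=dict)

    def define(self, class_iri: Iri, expr: ClassExpression) -> None:
        if class_iri in self.definitions:
            raise ValueError(f"{class_iri} already has a definition")
        expr = normalize(expr)
        self.definitions[class_iri] = expr
        self.axioms.append(EquivalentClasses((Named(class_iri), expr)))

    # convenience accessors used by the reasoner ----------------------

    def asserted_subclass_pairs(self) -> list[tuple[Iri, Iri]]:
        return [
            (a.sub.iri, a.sup.iri)
            for a in self.axioms
            if isinstance(a, SubClassOf)
            and isinstance(a.sub, Named)
            and isinstance(a.sup, Named)
        ]

    def named_equivalence_pairs(self) -> list[tuple[Iri, Iri]]:
        # merge overlapping equivalence groups (pairwise-encoded chains
        # must behave like one group)
        parent: dict[Iri, Iri] = {}

        def find(x: Iri) -> Iri:
            while parent.setdefault(x, x) != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a in self.axioms:
            if isinstance(a, EquivalentClasses):
                named = [m.iri for m in a.members if isinstance(m, Named)]
                for x in named[1:]:
                    parent[find(x)] = find(named[0])
        groups: dict[Iri, list[Iri]] = {}
        for x in parent:
            groups.setdefault(find(x), []).append(x)
        pairs = []
        for members in groups.values():
            for x in members:
                for y in members:
                    if x != y:
                        pairs.append((x, y))
        return pairs

    def disjoint_groups(self) -> list[tuple]:
        return [
            tuple(m.iri for m in a.members if isinstance(m, Named))
            for a in self.axioms
            if isinstance(a, DisjointClasses)
        ]

    def inverse_pairs(self) -> list[tuple[Iri, Iri]]:
        return [(a.p, a.q) for a in self.axioms if isinstance(a, InverseProperties)]

    def property_domains(self) -> list[tuple[Iri, Iri]]:
        return [(a.property, a.domain) for a in self.axioms if isinstance(a, PropertyDomain)]

    def property_ranges(self) -> list[tuple[Iri, Iri]]:
        return [(a.property, a.range) for a in self.axioms if isinstance(a, PropertyRange)]

    def nominal_members(self, class_iri: Iri) -> frozenset:
        """Members of a OneOf-defined (enumerated) class; empty if not one."""
        d = self.definitions.get(class_iri)
        if isinstance(d, OneOf):
            return d.individuals
        return frozenset()

    def named_classes(self) -> list[Iri]:
        return [
            Iri(self.registry.base + lid)
            for lid, _label, role in self.registry.entries()
            if role == "class"
        ]


# ----------------------------------------------------------------------
# The mini-BAO
# ----------------------------------------------------------------------

#: (label, accession, role, invented?) -- accessions marked invented are
#: minted here because the worked queries never print them.
REGISTRY_TABLE = [
    ("bioassay", "BAO_0000015", "class", False),
    ("perturbagen", "BAO_0000021", "class", False),
    ("meta target", "BAO_0000035", "class", True),
    ("measure group", "BAO_0000040", "class", True),
    ("concentration unit", "BAO_0000077", "class", True),
    ("mode of action", "BAO_0000084", "class", False),
    ("activation", "BAO_0000087", "class", False),
    ("inhibition", "BAO_0000091", "class", False),
    ("stimulation", "BAO_0000093", "class", False),
    ("agonist", "BAO_0000094", "class", True),
    ("nanomolar", "BAO_0000106", "individual", True),
    ("micromolar", "BAO_0000107", "individual", False),
    ("millimolar", "BAO_0000108", "individual", True),
    ("fifty percent inhibition", "BAO_0000148", "individual", True),
    ("fifty percent activation", "BAO_0000149", "individual", True),
    ("fifty percent response", "BAO_0000150", "class", True),
    ("fifty percent viability", "BAO_0000151", "individual", True),
    ("endpoint", "BAO_0000179", "class", False),
    ("perturbagen concentration endpoint", "BAO_0000180", "class", False),
    ("response endpoint", "BAO_0000181", "class", False),
    ("has concentration unit", "BAO_0000183", "object property", False),
    ("has perturbagen", "BAO_0000185", "object property", False),
    ("AC50", "BAO_0000186", "class", False),
    ("CC50", "BAO_0000187", "class", True),
    ("EC50", "BAO_0000188", "class", False),
    ("IC50", "BAO_0000190", "class", False),
    ("has response value", "BAO_0000195", "datatype property", False),
    ("has mode of action", "BAO_0000196", "object property", False),
    ("percent activation", "BAO_0000200", "class", False),
    ("percent inhibition", "BAO_0000201", "class", False),
    ("percent stimulation", "BAO_0000202", "class", True),
    ("percent viability", "BAO_0000203", "class", True),
    ("fold activation", "BAO_0000204", "class", True),
    ("has endpoint", "BAO_0000208", "object property", False),
    ("has measure group", "BAO_0000209", "object property", False),
    ("curvefit spec", "BAO_0000220", "class", True),
    ("has curvefit spec", "BAO_0000221", "object property", True),
    ("endpoint spec", "BAO_0000222", "class", True),
    ("has specification", "BAO_0000223", "object property", True),
    ("has screening concentration value", "BAO_0000336", "datatype property", False),
    ("has percent response", "BAO_0000337", "object property", False),
    ("has screening concentration spec", "BAO_0000338", "object property", False),
    ("is perturbagen of", "BAO_0000361", "object property", False),
]

#: standardized endpoint label -> family ("concentration" | "response")
ENDPOINT_FAMILIES = {
    "IC50": "concentration",
    "EC50": "concentration",
    "AC50": "concentration",
    "CC50": "concentration",
    "percent inhibition": "response",
    "percent activation": "response",
    "percent stimulation": "response",
    "percent viability": "response",
    "fold activation": "response",
}


def build_mini_bao(base: str = BAO) -> tuple[Ontology, Graph]:
    """Construct the mini-BAO ontology and its OWL-vocabulary triple graph.

    Returns the ontology (registry + axioms + defined-class expressions)
    and a graph holding the same axioms in RDF, plus the handful of
    schema-level individuals (concentration units, the 50%-response
    nominals with their literal values).
    """
    reg = IdRegistry(base)
    for label, local_id, role, _invented in REGISTRY_TABLE:
        reg.register(label, local_id, role)
    onto = Ontology(registry=reg)

    def c(label: str) -> Iri:
        return reg.iri(label)

    ax = onto.axioms.append

    # class hierarchy (asserted edges)
    hierarchy = [
        ("perturbagen concentration endpoint", "endpoint"),
        ("response endpoint", "endpoint"),
        ("IC50", "perturbagen concentration endpoint"),
        ("EC50", "perturbagen concentration endpoint"),
        ("AC50", "perturbagen concentration endpoint"),
        ("CC50", "perturbagen concentration endpoint"),
        ("percent inhibition", "response endpoint"),
        ("percent activation", "response endpoint"),
        ("percent stimulation", "response endpoint"),
        ("percent viability", "response endpoint"),
        ("fold activation", "response endpoint"),
        ("inhibition", "mode of action"),
        ("activation", "mode of action"),
        ("stimulation", "mode of action"),
        ("agonist", "mode of action"),
    ]
    for sub, sup in hierarchy:
        ax(SubClassOf(Named(c(sub)), Named(c(sup))))

    # activation == stimulation == agonist
    ax(EquivalentClasses((Named(c("activation")), Named(c("stimulation")),
                          Named(c("agonist")))))

    # disjointness among the root concepts
    ax(DisjointClasses((Named(c("perturbagen")), Named(c("endpoint")),
                        Named(c("meta target")))))

    # object property wiring (Fig-1-style indirection through measure group)
    has_mg = c("has measure group")
    has_ep = c("has endpoint")
    has_pert = c("has perturbagen")
    ax(PropertyDomain(has_mg, c("bioassay")))
    ax(PropertyRange(has_mg, c("measure group")))
    ax(PropertyDomain(has_ep, c("measure group")))
    ax(PropertyRange(has_ep, c("endpoint")))
    ax(PropertyRange(has_pert, c("perturbagen")))
    ax(InverseProperties(has_pert, c("is perturbagen of")))

    moa = c("has mode of action")
    resp = c("has percent response")
    inh = Named(c("inhibition"))
    act = Named(c("activation"))
    fifty_inh = c("fifty percent inhibition")
    fifty_act = c("fifty percent activation")

    # defined endpoint classes
    onto.define(c("fifty percent response"), OneOf(frozenset({fifty_inh, fifty_act})))
    onto.define(c("IC50"), Intersection((
        SomeValuesFrom(moa, inh),
        AllValuesFrom(moa, inh),
        HasValue(resp, fifty_inh),
    )))
    onto.define(c("EC50"), Intersection((
        SomeValuesFrom(moa, act),
        AllValuesFrom(moa, act),
        HasValue(resp, fifty_act),
    )))
    onto.define(c("AC50"), Intersection((
        SomeValuesFrom(moa, Union_((inh, act))),
        AllValuesFrom(moa, Union_((inh, act))),
        SomeValuesFrom(resp, Named(c("fifty percent response"))),
    )))

    # necessary-only (superclass) axioms on IC50
    ax(SubClassOf(Named(c("IC50")),
                  AllValuesFrom(c("has curvefit spec"), Named(c("curvefit spec")))))

    # constraints inherited by all concentration-type endpoints
    pce = Named(c("perturbagen concentration endpoint"))
    unit = c("has concentration unit")
    ax(SubClassOf(pce, SomeValuesFrom(unit, Named(c("concentration unit")))))
    ax(SubClassOf(pce, AllValuesFrom(unit, Named(c("concentration unit")))))
    ax(SubClassOf(pce, DataExact(c("has screening concentration value"), 1)))
    ax(SubClassOf(pce, AllValuesFrom(c("has specification"), Named(c("endpoint spec")))))
    ax(SubClassOf(pce, SomeValuesFrom(has_pert, Named(c("perturbagen")))))
    ax(SubClassOf(pce, ExactCardinality(has_pert, 1)))

    # schema-level individuals
    for label in ("nanomolar", "micromolar", "millimolar"):
        ax(ClassAssertion(Named(c("concentration unit")), c(label)))
    for label in ("fifty percent inhibition", "fifty percent activation",
                  "fifty percent viability"):
        ax(ClassAssertion(Named(c("endpoint spec")), c(label)))
    fifty = Literal("50", "float")
    ax(PropertyAssertion(c("has response value"), fifty_inh, fifty))
    ax(PropertyAssertion(c("has response value"), fifty_act, fifty))
    ax(PropertyAssertion(c("has response value"), c("fifty percent viability"), fifty))

    graph = ontology_to_graph(onto)
    return onto, graph


# ----------------------------------------------------------------------
# Axioms <-> triples (OWL vocabulary; anonymous nodes get minted IRIs
# since blank nodes are unsupported)
# ----------------------------------------------------------------------


class _NodeMinter:
    def __init__(self, base: str):
        self.base = base
        self.n = 0

    def __call__(self, kind: str) -> Iri:
        self.n += 1
        return Iri(f"{self.base}_anon_{kind}_{self.n}")


def _emit_expr(e: ClassExpression, g: Graph, mint: _NodeMinter) -> Iri:
    if isinstance(e, Named):
        return e.iri
    node = mint("expr")
    if isinstance(e, (Intersection, Union_)):
        g.add(Triple(node, RDF_TYPE, OWL_CLASS))
        pred = OWL_INTERSECTION_OF if isinstance(e, Intersection) else OWL_UNION_OF
        g.add(Triple(node, pred, _emit_list(
            [_emit_expr(m, g, mint) for m in e.members], g, mint)))
    elif isinstance(e, OneOf):
        g.add(Triple(node, RDF_TYPE, OWL_CLASS))
        g.add(Triple(node, OWL_ONE_OF, _emit_list(
            sorted(e.individuals, key=lambda i: i.value), g, mint)))
    else:
        g.add(Triple(node, RDF_TYPE, OWL_RESTRICTION))
        g.add(Triple(node, OWL_ON_PROPERTY, e.property))
        if isinstance(e, SomeValuesFrom):
            g.add(Triple(node, OWL_SOME_VALUES_FROM, _emit_expr(e.filler, g, mint)))
        elif isinstance(e, AllValuesFrom):
            g.add(Triple(node, OWL_ALL_VALUES_FROM, _emit_expr(e.filler, g, mint)))
        elif isinstance(e, HasValue):
            g.add(Triple(node, OWL_HAS_VALUE, e.individual))
        elif isinstance(e, ExactCardinality):
            if e.filler is None:
                g.add(Triple(node, OWL_CARDINALITY, Literal(str(e.n), "integer")))
            else:
                g.add(Triple(node, OWL_QUALIFIED_CARDINALITY, Literal(str(e.n), "integer")))
                g.add(Triple(node, OWL_ON_CLASS, _emit_expr(e.filler, g, mint)))
        elif isinstance(e, DataExact):
            g.add(Triple(node, OWL_CARDINALITY, Literal(str(e.n), "integer")))
        else:  # pragma: no cover
            raise TypeError(f"cannot emit {e!r}")
    return node


def _emit_list(items: list[Iri], g: Graph, mint: _NodeMinter) -> Iri:
    head: Iri = RDF_NIL
    for item in reversed(items):
        cell = mint("list")
        g.add(Triple(cell, RDF_FIRST, item))
        g.add(Triple(cell, RDF_REST, head))
        head = cell
    return head


_ROLE_TYPE = {
    "class": OWL_CLASS,
    "object property": OWL_OBJECT_PROPERTY,
    "datatype property": OWL_DATATYPE_PROPERTY,
    "individual": OWL_NAMED_INDIVIDUAL,
}
_TYPE_ROLE = {v: k for k, v in _ROLE_TYPE.items()}


def ontology_to_graph(onto: Ontology) -> Graph:
    g = Graph({"bao": onto.registry.base, "rdf": RDF_NS, "rdfs": RDFS_NS,
               "owl": OWL_NS})
    mint = _NodeMinter(onto.registry.base)
    for local_id, label, role in onto.registry.entries():
        iri = Iri(onto.registry.base + local_id)
        g.add(Triple(iri, RDF_TYPE, _ROLE_TYPE[role]))
        g.add(Triple(iri, RDFS_LABEL, Literal(label)))
    for a in onto.axioms:
        if isinstance(a, SubClassOf):
            g.add(Triple(_emit_expr(a.sub, g, mint), RDFS_SUBCLASSOF,
                         _emit_expr(a.sup, g, mint)))
        elif isinstance(a, EquivalentClasses):
            nodes = [_emit_expr(m, g, mint) for m in a.members]
            for x, y in zip(nodes, nodes[1:]):
                g.add(Triple(x, OWL_EQUIVALENT_CLASS, y))
        elif isinstance(a, DisjointClasses):
            nodes = [_emit_expr(m, g, mint) for m in a.members]
            for i, x in enumerate(nodes):
                for y in nodes[i + 1:]:
                    g.add(Triple(x, OWL_DISJOINT_WITH, y))
        elif isinstance(a, InverseProperties):
            g.add(Triple(a.p, OWL_INVERSE_OF, a.q))
        elif isinstance(a, PropertyDomain):
            g.add(Triple(a.property, RDFS_DOMAIN, a.domain))
        elif isinstance(a, PropertyRange):
            g.add(Triple(a.property, RDFS_RANGE, a.range))
        elif isinstance(a, ClassAssertion):
            g.add(Triple(a.individual, RDF_TYPE, _emit_expr(a.class_expr, g, mint)))
        elif isinstance(a, PropertyAssertion):
            g.add(Triple(a.subject, a.property, a.object))
    return g


def _read_list(g: Graph, head: Iri) -> list[Iri]:
    out = []
    while head != RDF_NIL:
        first = g.objects(head, RDF_FIRST)
        rest = g.objects(head, RDF_REST)
        if len(first) != 1 or len(rest) != 1:
            raise ValueError(f"malformed RDF list at {head}")
        out.append(first[0])
        head = rest[0]
    return out


def _read_expr(g: Graph, node: Iri, anon: set) -> ClassExpression:
    if node not in anon:
        return Named(node)
    inter = g.objects(node, OWL_INTERSECTION_OF)
    if inter:
        return Intersection(tuple(_read_expr(g, m, anon) for m in _read_list(g, inter[0])))
    union = g.objects(node, OWL_UNION_OF)
    if union:
        return Union_(tuple(_read_expr(g, m, anon) for m in _read_list(g, union[0])))
    oneof = g.objects(node, OWL_ONE_OF)
    if oneof:
        return OneOf(frozenset(_read_list(g, oneof[0])))
    props = g.objects(node, OWL_ON_PROPERTY)
    if props:
        p = props[0]
        some = g.objects(node, OWL_SOME_VALUES_FROM)
        if some:
            return SomeValuesFrom(p, _read_expr(g, some[0], anon))
        only = g.objects(node, OWL_ALL_VALUES_FROM)
        if only:
            return AllValuesFrom(p, _read_expr(g, only[0], anon))
        hv = g.objects(node, OWL_HAS_VALUE)
        if hv:
            return HasValue(p, hv[0])
        qc = g.objects(node, OWL_QUALIFIED_CARDINALITY)
        if qc:
            onc = g.objects(node, OWL_ON_CLASS)
            return ExactCardinality(p, int(qc[0].lexical), _read_expr(g, onc[0], anon))
        card = g.objects(node, OWL_CARDINALITY)
        if card:
            # object vs datatype property decided by the property typing
            if OWL_DATATYPE_PROPERTY in g.objects(p, RDF_TYPE):
                return DataExact(p, int(card[0].lexical))
            return ExactCardinality(p, int(card[0].lexical))
    raise ValueError(f"cannot reconstruct class expression at {node}")


def ontology_from_graph(g: Graph, base: str = BAO) -> Ontology:
    """Reconstruct an ontology from its OWL-vocabulary triple form.

    Inverse of :func:`ontology_to_graph` up to axiom order; used for the
    serialization round-trip guarantee and by the CLI when reloading a
    previously written schema file.
    """
    reg = IdRegistry(base)
    anon: set[Iri] = set()
    for t in g.match(None, RDF_TYPE, None):
        if not isinstance(t.subject, Iri):
            continue
        if t.subject.value.startswith(base + "_anon_"):
            anon.add(t.subject)
    for t in g.match(None, RDFS_LABEL, None):
        iri = t.subject
        types = set(g.objects(iri, RDF_TYPE))
        role = next((r for ty, r in _TYPE_ROLE.items() if ty in types), None)
        if role and isinstance(iri, Iri) and iri.value.startswith(base):
            reg.register(t.object.lexical, iri.value.removeprefix(base), role)
    onto = Ontology(registry=reg)
    seen_equiv: set[frozenset] = set()
    for t in g:
        s, p, o = t.subject, t.predicate, t.object
        if p == RDFS_SUBCLASSOF:
            onto.axioms.append(SubClassOf(_read_expr(g, s, anon), _read_expr(g, o, anon)))
        elif p == OWL_EQUIVALENT_CLASS:
            se, oe = _read_expr(g, s, anon), _read_expr(g, o, anon)
            if isinstance(se, Named) and not isinstance(oe, Named):
                if se.iri not in onto.definitions:
                    onto.define(se.iri, oe)
            else:
                key = frozenset({_expr_key(se), _expr_key(oe)})
                if key not in seen_equiv:
                    seen_equiv.add(key)
                    onto.axioms.append(EquivalentClasses((se, oe)))
        elif p == OWL_DISJOINT_WITH:
            onto.axioms.append(DisjointClasses((_read_expr(g, s, anon),
                                                _read_expr(g, o, anon))))
        elif p == OWL_INVERSE_OF:
            onto.axioms.append(InverseProperties(s, o))
        elif p == RDFS_DOMAIN:
            onto.axioms.append(PropertyDomain(s, o))
        elif p == RDFS_RANGE:
            onto.axioms.append(PropertyRange(s, o))
        elif p == RDF_TYPE and o not in _TYPE_ROLE and s not in anon:
            if o not in (OWL_RESTRICTION,):
                onto.axioms.append(ClassAssertion(_read_expr(g, o, anon), s))
        elif p not in (RDF_TYPE, RDFS_LABEL, RDF_FIRST, RDF_REST, OWL_ON_PROPERTY,
                       OWL_SOME_VALUES_FROM, OWL_ALL_VALUES_FROM, OWL_HAS_VALUE,
                       OWL_CARDINALITY, OWL_QUALIFIED_CARDINALITY, OWL_ON_CLASS,
                       OWL_INTERSECTION_OF, OWL_UNION_OF, OWL_ONE_OF):
            if s not in anon:
                onto.axioms.append(PropertyAssertion(p, s, o))
    return onto
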