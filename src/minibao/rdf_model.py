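"""Minimal RDF triple-store data model.

Terms are IRIs, CURIEs (compact IRIs, expanded against a prefix map on
insertion), typed literals, and query variables.  A :class:`Graph` is a set
of ground triples with deterministic, canonical iteration order so that
serializations are byte-reproducible regardless of insertion order.

Float literals are compared numerically by downstream filters but stored and
serialized by their *lexical form*: a value written ``"6.3096"`` stays the
string ``6.3096`` through any number of round-trips.  Blank nodes are not
supported; every individual carries a minted IRI.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Union

__all__ = [
    "Iri",
    "Curie",
    "Literal",
    "Variable",
    "Term",
    "Triple",
    "Graph",
    "RdfSyntaxError",
    "RDF_TYPE",
    "RDFS_SUBCLASSOF",
    "XSD",
    "RDF_NS",
    "RDFS_NS",
    "OWL_NS",
    "parse_ntriples",
    "serialize_ntriples",
    "parse_turtle_subset",
    "serialize_turtle",
]

RDF_NS = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
RDFS_NS = "http://www.w3.org/2000/01/rdf-schema#"
OWL_NS = "http://www.w3.org/2002/07/owl#"
XSD = "http://www.w3.org/2001/XMLSchema#"

#: datatype tag -> XSD datatype IRI
_DATATYPE_IRI = {
    "float": XSD + "float",
    "integer": XSD + "integer",
    "string": XSD + "string",
}
_IRI_DATATYPE = {v: k for k, v in _DATATYPE_IRI.items()}
_IRI_DATATYPE[XSD + "double"] = "float"
_IRI_DATATYPE[XSD + "int"] = "integer"


class RdfSyntaxError(ValueError):
    """Malformed N-Triples/Turtle input; carries the offending line number."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass(frozen=True, order=True)
class Iri:
    value: str

    def __repr__(self) -> str:
        return f"<{self.value}>"


@dataclass(frozen=True, order=True)
class Curie:
    """Compact IRI; expanded against a graph's prefix map on insertion."""

    prefix: str
    local: str

    def expand(self, prefix_map: dict[str, str]) -> Iri:
        if self.prefix not in prefix_map:
            raise KeyError(f"unknown prefix {self.prefix!r}")
        return Iri(prefix_map[self.prefix] + self.local)

    def __repr__(self) -> str:
        return f"{self.prefix}:{self.local}"


@dataclass(frozen=True, order=True)
class Literal:
    """Typed literal; datatype tag is one of float/integer/string.

    Equality and hashing are on the lexical form, so ``"4.0"`` and ``"4"``
    are distinct terms even though they compare numerically equal in
    filters (use :meth:`as_float` for numeric comparison).
    """

    lexical: str
    datatype: str = "string"

    def __post_init__(self):
        if self.datatype not in _DATATYPE_IRI:
            raise ValueError(f"unsupported literal datatype {self.datatype!r}")

    def as_float(self) -> float:
        return float(self.lexical)

    def is_numeric(self) -> bool:
        if self.datatype in ("float", "integer"):
            return True
        try:
            float(self.lexical)
            return True
        except ValueError:
            return False

    def __repr__(self) -> str:
        if self.datatype == "string":
            return f'"{self.lexical}"'
        return f'"{self.lexical}"^^xsd:{self.datatype}'


@dataclass(frozen=True, order=True)
class Variable:
    """Query variable; only valid inside query patterns, never in a Graph."""

    name: str

    def __repr__(self) -> str:
        return f"?{self.name}"


Term = Union[Iri, Curie, Literal, Variable]

RDF_TYPE = Iri(RDF_NS + "type")
RDFS_SUBCLASSOF = Iri(RDFS_NS + "subClassOf")

# canonical sort rank per term kind (graphs only ever hold Iri/Literal)
_RANK = {Iri: 0, Literal: 1, Curie: 2, Variable: 3}


def term_key(t: Term) -> tuple:
    """Total order over terms used for canonical graph iteration."""
    if isinstance(t, Iri):
        return (0, t.value)
    if isinstance(t, Literal):
        return (1, t.lexical, t.datatype)
    if isinstance(t, Curie):
        return (2, t.prefix, t.local)
    return (3, t.name)


@dataclass(frozen=True)
class Triple:
    subject: Term
    predicate: Term
    object: Term

    def __post_init__(self):
        if isinstance(self.subject, Literal):
            raise ValueError("triple subject must not be a literal")
        if isinstance(self.predicate, (Literal, Variable)):
            raise ValueError("triple predicate must be an IRI or CURIE")

    def is_ground(self) -> bool:
        return not any(
            isinstance(t, Variable) for t in (self.subject, self.predicate, self.object)
        )

    def key(self) -> tuple:
        return (term_key(self.subject), term_key(self.predicate), term_key(self.object))

    def __iter__(self) -> Iterator[Term]:
        yield self.subject
        yield self.predicate
        yield self.object


class Graph:
    """Set-semantics triple store with simple per-position indexes.

    CURIE terms are expanded to full IRIs when a triple is added, so stored
    graphs contain only :class:`Iri` and :class:`Literal` terms.  Iteration
    is in canonical (subject, predicate, object) lexical order.
    """

    def __init__(self, prefix_map: Optional[dict[str, str]] = None):
        self.prefix_map: dict[str, str] = dict(prefix_map or {})
        self._triples: set[Triple] = set()
        self._by_s: dict[Term, set[Triple]] = {}
        self._by_p: dict[Term, set[Triple]] = {}
        self._by_o: dict[Term, set[Triple]] = {}

    # -- construction -------------------------------------------------

    def bind(self, prefix: str, base: str) -> None:
        self.prefix_map[prefix] = base

    def resolve(self, t: Term) -> Term:
        """Expand a CURIE against this graph's prefix map; other terms pass."""
        if isinstance(t, Curie):
            try:
                return t.expand(self.prefix_map)
            except KeyError as exc:
                raise RdfSyntaxError(str(exc.args[0])) from None
        return t

    def add(self, t: Triple) -> "Graph":
        if not t.is_ground():
            raise ValueError(f"cannot store non-ground triple {t}")
        t = Triple(self.resolve(t.subject), self.resolve(t.predicate), self.resolve(t.object))
        if t not in self._triples:
            self._triples.add(t)
            self._by_s.setdefault(t.subject, set()).add(t)
            self._by_p.setdefault(t.predicate, set()).add(t)
            self._by_o.setdefault(t.object, set()).add(t)
        return self

    def add_all(self, triples: Iterable[Triple]) -> "Graph":
        for t in triples:
            self.add(t)
        return self

    def copy(self) -> "Graph":
        g = Graph(self.prefix_map)
        g.add_all(self._triples)
        return g

    # -- queries ------------------------------------------------------

    def __contains__(self, t: Triple) -> bool:
        t = Triple(self.resolve(t.subject), self.resolve(t.predicate), self.resolve(t.object))
        return t in self._triples

    def __len__(self) -> int:
        return len(self._triples)

    def __iter__(self) -> Iterator[Triple]:
        return iter(sorted(self._triples, key=Triple.key))

    def __eq__(self, other) -> bool:
        return isinstance(other, Graph) and self._triples == other._triples

    def match(
        self,
        subject: Optional[Term] = None,
        predicate: Optional[Term] = None,
        object: Optional[Term] = None,
    ) -> list[Triple]:
        """All triples unifying with the pattern, in canonical order.

        ``None`` (or a :class:`Variable`) in any position is a wildcard.
        """
        pat = [subject, predicate, object]
        for i, t in enumerate(pat):
            if isinstance(t, Variable):
                pat[i] = None
            elif t is not None:
                pat[i] = self.resolve(t)
        s, p, o = pat
        candidates: Optional[set[Triple]] = None
        for term, index in ((s, self._by_s), (p, self._by_p), (o, self._by_o)):
            if term is not None:
                bucket = index.get(term, set())
                if candidates is None or len(bucket) < len(candidates):
                    candidates = bucket
        if candidates is None:
            candidates = self._triples
        out = [
            t
            for t in candidates
            if (s is None or t.subject == s)
            and (p is None or t.predicate == p)
            and (o is None or t.object == o)
        ]
        out.sort(key=Triple.key)
        return out

    def subjects(self, predicate: Term, object: Term) -> list[Term]:
        return [t.subject for t in self.match(None, predicate, object)]

    def objects(self, subject: Term, predicate: Term) -> list[Term]:
        return [t.object for t in self.match(subject, predicate, None)]


# ----------------------------------------------------------------------
# N-Triples
# ----------------------------------------------------------------------

_ESCAPES = {"\\": "\\\\", '"': '\\"', "\n": "\\n", "\r": "\\r", "\t": "\\t"}
_UNESCAPES = {"\\": "\\", '"': '"', "n": "\n", "r": "\r", "t": "\t"}


def _escape(s: str) -> str:
    return "".join(_ESCAPES.get(c, c) for c in s)


def _unescape(s: str, line: int) -> str:
    out, i = [], 0
    while i < len(s):
        c = s[i]
        if c == "\\":
            if i + 1 >= len(s) or s[i + 1] not in _UNESCAPES:
                raise RdfSyntaxError("bad escape sequence in literal", line)
            out.append(_UNESCAPES[s[i + 1]])
            i += 2
        else:
            out.append(c)
            i += 1
    return "".join(out)


def _nt_term(t: Term) -> str:
    if isinstance(t, Iri):
        return f"<{t.value}>"
    if isinstance(t, Literal):
        if t.datatype == "string":
            return f'"{_escape(t.lexical)}"'
        return f'"{_escape(t.lexical)}"^^<{_DATATYPE_IRI[t.datatype]}>'
    raise ValueError(f"cannot serialize term {t!r} to N-Triples")


def serialize_ntriples(graph: Graph) -> str:
    lines = [
        f"{_nt_term(t.subject)} {_nt_term(t.predicate)} {_nt_term(t.object)} ."
        for t in graph
    ]
    return "\n".join(lines) + ("\n" if lines else "")


_NT_IRI = r"<([^<>\s]*)>"
_NT_LIT = r'"((?:[^"\\]|\\.)*)"(?:\^\^<([^<>\s]*)>)?'
_NT_LINE = re.compile(rf"^\s*{_NT_IRI}\s+{_NT_IRI}\s+(?:{_NT_IRI}|{_NT_LIT})\s*\.\s*$")


def _datatype_tag(dt_iri: Optional[str], line: int) -> str:
    if dt_iri is None:
        return "string"
    if dt_iri not in _IRI_DATATYPE:
        raise RdfSyntaxError(f"unsupported literal datatype <{dt_iri}>", line)
    return _IRI_DATATYPE[dt_iri]


def parse_ntriples(text: str, prefix_map: Optional[dict[str, str]] = None) -> Graph:
    g = Graph(prefix_map)
    for lineno, raw in enumerate(text.splitlines(), start=1):
        stripped = raw.strip()
        if not stripped or stripped.startswith("#"):
            continue
        m = _NT_LINE.match(raw)
        if not m:
            raise RdfSyntaxError(f"malformed N-Triples statement: {stripped!r}", lineno)
        s_iri, p_iri, o_iri, o_lex, o_dt = m.groups()
        obj: Term
        if o_iri is not None:
            obj = Iri(o_iri)
        else:
            obj = Literal(_unescape(o_lex, lineno), _datatype_tag(o_dt, lineno))
        g.add(Triple(Iri(s_iri), Iri(p_iri), obj))
    return g


# ----------------------------------------------------------------------
# Turtle subset: @prefix, CURIEs, 'a', object lists (','), predicate
# lists (';'), typed literals with xsd: CURIE or full IRI datatypes.
# ----------------------------------------------------------------------


def _curie_or_iri(t: Iri, prefix_map: dict[str, str]) -> str:
    # longest-base-wins compression; local names must be CURIE-safe
    best = None
    for prefix, base in prefix_map.items():
        if t.value.startswith(base):
            local = t.value[len(base):]
            if re.fullmatch(r"[A-Za-z0-9_.\-]*", local) and (
                best is None or len(base) > best[2]
            ):
                best = (prefix, local, len(base))
    if best is not None:
        return f"{best[0]}:{best[1]}"
    return f"<{t.value}>"


def _ttl_term(t: Term, prefix_map: dict[str, str]) -> str:
    if isinstance(t, Iri):
        if t == RDF_TYPE:
            return "a"
        return _curie_or_iri(t, prefix_map)
    if isinstance(t, Literal):
        if t.datatype == "string":
            return f'"{_escape(t.lexical)}"'
        return f'"{_escape(t.lexical)}"^^xsd:{t.datatype}'
    raise ValueError(f"cannot serialize term {t!r} to Turtle")


def serialize_turtle(graph: Graph) -> str:
    pm = dict(graph.prefix_map)
    pm.setdefault("xsd", XSD)
    out = [f"@prefix {p}: <{b}> ." for p, b in sorted(pm.items())]
    if out:
        out.append("")
    # group by subject, then predicate, keeping canonical order
    by_subject: dict[Term, dict[Term, list[Term]]] = {}
    for t in graph:
        by_subject.setdefault(t.subject, {}).setdefault(t.predicate, []).append(t.object)
    for subject in sorted(by_subject, key=term_key):
        preds = by_subject[subject]
        lines = []
        for predicate in sorted(preds, key=term_key):
            objs = ", ".join(_ttl_term(o, pm) for o in preds[predicate])
            lines.append(f"    {_ttl_term(predicate, pm)} {objs}")
        out.append(f"{_ttl_term(subject, pm)}\n" + " ;\n".join(lines) + " .")
    return "\n".join(out) + ("\n" if out else "")


_TOKEN = re.compile(
    r"""
    (?P<ws>\s+|\#[^\n]*)
  | (?P<prefix_decl>@prefix)
  | (?P<iri><[^<>\s]*>)
  | (?P<literal>"(?:[^"\\]|\\.)*"(?:\^\^(?:<[^<>\s]*>|[A-Za-z][\w\-]*:[A-Za-z0-9_.\-]+))?)
  | (?P<punct>[.;,])
  | (?P<curie>[A-Za-z][\w\-]*:[A-Za-z0-9_.\-]*)
  | (?P<a>a\b)
    """,
    re.VERBOSE,
)


def _tokenize_turtle(text: str) -> list[tuple[str, str, int]]:
    tokens, pos, line = [], 0, 1
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m:
            raise RdfSyntaxError(f"unexpected character {text[pos]!r}", line)
        kind = m.lastgroup
        value = m.group()
        if kind != "ws":
            tokens.append((kind, value, line))
        line += value.count("\n")
        pos = m.end()
    return tokens


def parse_turtle_subset(text: str) -> Graph:
    g = Graph()
    tokens = _tokenize_turtle(text)
    i = 0

    def expect(kind: str) -> tuple[str, str, int]:
        nonlocal i
        if i >= len(tokens):
            raise RdfSyntaxError("unexpected end of input", tokens[-1][2] if tokens else 1)
        tok = tokens[i]
        if tok[0] != kind:
            raise RdfSyntaxError(f"expected {kind}, got {tok[1]!r}", tok[2])
        i += 1
        return tok

    def parse_term() -> Term:
        nonlocal i
        if i >= len(tokens):
            raise RdfSyntaxError("unexpected end of input", tokens[-1][2] if tokens else 1)
        kind, value, line = tokens[i]
        i += 1
        if kind == "iri":
            return Iri(value[1:-1])
        if kind == "a":
            return RDF_TYPE
        if kind == "curie":
            prefix, local = value.split(":", 1)
            if prefix not in g.prefix_map:
                raise RdfSyntaxError(f"unknown prefix {prefix!r}", line)
            return Iri(g.prefix_map[prefix] + local)
        if kind == "literal":
            m = re.fullmatch(r'"((?:[^"\\]|\\.)*)"(?:\^\^(.+))?', value, re.S)
            lex = _unescape(m.group(1), line)
            dt = m.group(2)
            if dt is None:
                return Literal(lex, "string")
            if dt.startswith("<"):
                return Literal(lex, _datatype_tag(dt[1:-1], line))
            prefix, local = dt.split(":", 1)
            if prefix not in g.prefix_map:
                raise RdfSyntaxError(f"unknown prefix {prefix!r}", line)
            return Literal(lex, _datatype_tag(g.prefix_map[prefix] + local, line))
        raise RdfSyntaxError(f"unexpected token {value!r}", line)

    while i < len(tokens):
        kind, value, line = tokens[i]
        if kind == "prefix_decl":
            i += 1
            name = expect("curie")[1]
            if not name.endswith(":") and ":" in name:
                # token grammar captures "p:" as curie with empty local
                pass
            prefix = name[:-1] if name.endswith(":") else name.split(":", 1)[0]
            base = expect("iri")[1][1:-1]
            expect("punct")  # '.'
            g.bind(prefix, base)
            continue
        subject = parse_term()
        while True:
            predicate = parse_term()
            while True:
                obj = parse_term()
                g.add(Triple(subject, predicate, obj))
                kind2, value2, line2 = (
                    tokens[i] if i < len(tokens) else ("punct", ".", line)
                )
                if kind2 == "punct" and value2 == ",":
                    i += 1
                    continue
                break
            kind2, value2, line2 = tokens[i] if i < len(tokens) else (None, None, line)
            if kind2 == "punct" and value2 == ";":
                i += 1
                # tolerate trailing ';' before '.'
                if i < len(tokens) and tokens[i][0] == "punct" and tokens[i][1] == ".":
                    i += 1
                    break
                continue
            if kind2 == "punct" and value2 == ".":
                i += 1
                break
            raise RdfSyntaxError(
                f"expected ';', ',' or '.', got {value2!r}", line2 or line
            )
    return g
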