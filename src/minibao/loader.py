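"""Curated assay-annotation tables -> instance triples, plus QC cross-checks.

Each accepted row (one assay / measure-group / endpoint record) becomes a
small star of triples following the schema's indirection:

    assay --has measure group--> measure group --has endpoint--> endpoint

with the endpoint typed by its standardized endpoint class, linked to its
perturbagen (forward direction only; the inverse *is perturbagen of* edge
is left to the reasoner), to a mode-of-action individual, and to its
concentration/response payload.  Concentration-type endpoints carry the
screening concentration directly and point at the shared 50%-response
nominal individual; response-type endpoints carry the response value
directly and hang the concentration off a specification node.

All concentrations are normalized to micromolar.  Literal lexical forms
from the input table are preserved verbatim (a concentration written
``6.3096`` serializes as ``"6.3096"^^xsd:float``).
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .rdf_model import Graph, Iri, Literal, RDF_TYPE, Triple
from .schema import ENDPOINT_FAMILIES, Ontology

__all__ = [
    "AssayAnnotation",
    "LoadResult",
    "DiscrepancyReport",
    "UNMAPPED",
    "CSV_COLUMNS",
    "standardize_endpoint",
    "load_annotations",
    "annotations_from_csv",
    "annotations_to_csv",
    "qc_crosscheck",
]

UNMAPPED = "unmapped"

#: μM-relative factors for accepted concentration units
UNIT_TO_MICROMOLAR = {
    "uM": 1.0,
    "um": 1.0,
    "µM": 1.0,
    "μM": 1.0,
    "micromolar": 1.0,
    "nM": 1e-3,
    "nm": 1e-3,
    "nanomolar": 1e-3,
    "mM": 1e3,
    "mm": 1e3,
    "millimolar": 1e3,
}

CSV_COLUMNS = [
    "assay_id",
    "measure_group",
    "compound_id",
    "endpoint_raw",
    "endpoint_std",
    "moa",
    "conc_value",
    "conc_unit",
    "response_value",
    "endpoint_uid",
]


@dataclass
class AssayAnnotation:
    """One curated annotation record (PubChem-style AID/CID identifiers)."""

    assay_id: str
    measure_group_index: int
    compound_id: str
    endpoint_raw: str
    endpoint_std: Optional[str]
    mode_of_action: str
    concentration_value: str  # lexical form, in concentration_unit
    concentration_unit: str
    response_value: str  # lexical form, percent scale (may exceed 100)
    #: optional explicit endpoint IRI suffix (``<family>_<counter>``);
    #: minted from a running counter when absent
    endpoint_uid: Optional[str] = None


# ----------------------------------------------------------------------
# Endpoint standardization
# ----------------------------------------------------------------------

#: curated exact synonyms, checked first (case-insensitive)
_SYNONYMS = {
    "potency": "AC50",
    "ic50_mean": "IC50",
    "mean ic50": "IC50",
    "ec50_mean": "EC50",
    "mean ec50": "EC50",
    "% inhibition": "percent inhibition",
    "% activation": "percent activation",
    "% stimulation": "percent stimulation",
    "% viability": "percent viability",
}

_STOP_TOKENS = {
    "mean", "best", "fit", "bestfit", "value", "values", "um", "nm", "mm",
    "m", "at", "of", "the", "qualified", "modifier", "replicate", "assay",
}

_CORE = {
    "ic50": "IC50",
    "ec50": "EC50",
    "ac50": "AC50",
    "cc50": "CC50",
}


def standardize_endpoint(raw: str) -> str:
    """Map a free-text endpoint name onto a standardized endpoint label.

    Dictionary first (curated synonyms), then token rules; anything not
    recognized maps to the ``unmapped`` sentinel, never to a guess.
    """
    key = raw.strip().lower()
    if key in _SYNONYMS:
        return _SYNONYMS[key]
    tokens = [t for t in re.split(r"[^a-z0-9%]+", key) if t]
    tokens = [t for t in tokens if t not in _STOP_TOKENS]
    for t in tokens:
        if t in _CORE:
            return _CORE[t]
    tset = set(tokens)
    if "percent" in tset or "%" in tset or "percentage" in tset:
        for kind in ("inhibition", "activation", "stimulation", "viability"):
            if kind in tset:
                return f"percent {kind}"
    if "fold" in tset and "activation" in tset:
        return "fold activation"
    return UNMAPPED


# ----------------------------------------------------------------------
# Loading
# ----------------------------------------------------------------------


@dataclass
class LoadResult:
    graph: Graph
    accepted: list
    rejected: list  # (AssayAnnotation, reason)


def _format_micromolar(lexical: str, unit: str) -> str:
    """Normalize a concentration lexical form to μM, preserving the input
    spelling when the unit already is μM."""
    factor = UNIT_TO_MICROMOLAR[unit]
    if factor == 1.0:
        return lexical.strip()
    return repr(float(lexical) * factor)


def load_annotations(rows: Iterable[AssayAnnotation], onto: Ontology) -> LoadResult:
    """Convert annotation rows to instance triples.

    Rows with an unmapped endpoint, a non-positive or non-numeric
    concentration, or an unknown unit are rejected with a reason;
    accepted + rejected partition the input.
    """
    reg = onto.registry
    base = reg.base
    g = Graph({"bao": base})
    c = reg.iri

    bioassay_cls = c("bioassay")
    perturbagen_cls = c("perturbagen")
    mg_cls = c("measure group")
    spec_cls = c("endpoint spec")
    micromolar = c("micromolar")
    has_mg = c("has measure group")
    has_ep = c("has endpoint")
    has_pert = c("has perturbagen")
    has_moa = c("has mode of action")
    has_conc = c("has screening concentration value")
    has_unit = c("has concentration unit")
    has_resp_nom = c("has percent response")
    has_value = c("has response value")
    has_spec = c("has screening concentration spec")
    fifty = Literal("50", "float")
    nominal_value_emitted = set()

    accepted: list[AssayAnnotation] = []
    rejected: list[tuple[AssayAnnotation, str]] = []
    counter = 0

    for row in rows:
        std = row.endpoint_std
        if not std or std == UNMAPPED or std not in ENDPOINT_FAMILIES:
            rejected.append((row, f"unmapped endpoint {row.endpoint_raw!r}"))
            continue
        if std not in reg:
            rejected.append((row, f"endpoint {std!r} not registered"))
            continue
        if row.mode_of_action not in reg:
            rejected.append((row, f"unknown mode of action {row.mode_of_action!r}"))
            continue
        if row.concentration_unit not in UNIT_TO_MICROMOLAR:
            rejected.append((row, f"unknown unit {row.concentration_unit!r}"))
            continue
        try:
            conc_um = float(row.concentration_value) * \
                UNIT_TO_MICROMOLAR[row.concentration_unit]
        except (TypeError, ValueError):
            rejected.append(
                (row, f"non-numeric concentration {row.concentration_value!r}"))
            continue
        if conc_um <= 0:
            rejected.append((row, f"non-positive concentration {conc_um} uM"))
            continue

        family = ENDPOINT_FAMILIES[std]
        counter += 1
        uid = row.endpoint_uid or \
            f"{2 if family == 'concentration' else 1}_{counter}"
        assay = Iri(f"{base}individual_{reg.local_id('bioassay')}_{row.assay_id}")
        compound = Iri(
            f"{base}individual_{reg.local_id('perturbagen')}_{row.compound_id}")
        mg = Iri(f"{base}individual_{reg.local_id('measure group')}_"
                 f"{row.assay_id}_{row.measure_group_index}")
        endpoint = Iri(f"{base}individual_{reg.local_id(std)}_{uid}")
        moa_node = Iri(
            f"{base}individual_{reg.local_id(row.mode_of_action)}_{uid}")
        conc_lit = Literal(
            _format_micromolar(row.concentration_value, row.concentration_unit),
            "float")

        g.add(Triple(assay, RDF_TYPE, bioassay_cls))
        g.add(Triple(compound, RDF_TYPE, perturbagen_cls))
        g.add(Triple(assay, has_mg, mg))
        g.add(Triple(mg, RDF_TYPE, mg_cls))
        g.add(Triple(mg, has_ep, endpoint))
        g.add(Triple(endpoint, RDF_TYPE, c(std)))
        # forward direction only; the inverse edge is the reasoner's job
        g.add(Triple(endpoint, has_pert, compound))
        g.add(Triple(assay, has_pert, compound))
        g.add(Triple(endpoint, has_moa, moa_node))
        g.add(Triple(moa_node, RDF_TYPE, c(row.mode_of_action)))

        if family == "concentration":
            if std == "CC50":
                nominal = c("fifty percent viability")
            elif row.mode_of_action == "inhibition":
                nominal = c("fifty percent inhibition")
            else:
                nominal = c("fifty percent activation")
            g.add(Triple(endpoint, has_conc, conc_lit))
            g.add(Triple(endpoint, has_unit, micromolar))
            g.add(Triple(endpoint, has_resp_nom, nominal))
            if nominal not in nominal_value_emitted:
                nominal_value_emitted.add(nominal)
                g.add(Triple(nominal, has_value, fifty))
        else:
            resp_lit = Literal(row.response_value.strip(), "float")
            spec = Iri(f"{base}individual_{reg.local_id('endpoint spec')}_{uid}")
            g.add(Triple(endpoint, has_value, resp_lit))
            g.add(Triple(endpoint, has_spec, spec))
            g.add(Triple(spec, RDF_TYPE, spec_cls))
            g.add(Triple(spec, has_conc, conc_lit))
            g.add(Triple(spec, has_unit, micromolar))
        accepted.append(row)

    return LoadResult(graph=g, accepted=accepted, rejected=rejected)


# ----------------------------------------------------------------------
# CSV interchange
# ----------------------------------------------------------------------


def annotations_from_csv(text: str) -> list[AssayAnnotation]:
    """Parse the documented CSV dialect (UTF-8, header required).

    All values are kept as strings so literal lexical forms survive.
    """
    reader = csv.DictReader(io.StringIO(text))
    required = set(CSV_COLUMNS) - {"endpoint_uid", "endpoint_std"}
    if reader.fieldnames is None or not required <= set(reader.fieldnames):
        missing = sorted(required - set(reader.fieldnames or []))
        raise ValueError(f"CSV header missing required columns: {missing}")
    rows = []
    for rec in reader:
        std = (rec.get("endpoint_std") or "").strip() or None
        if std is None and rec.get("endpoint_raw"):
            std = standardize_endpoint(rec["endpoint_raw"])
        rows.append(AssayAnnotation(
            assay_id=rec["assay_id"].strip(),
            measure_group_index=int(rec["measure_group"] or 1),
            compound_id=rec["compound_id"].strip(),
            endpoint_raw=rec["endpoint_raw"].strip(),
            endpoint_std=std,
            mode_of_action=rec["moa"].strip(),
            concentration_value=rec["conc_value"].strip(),
            concentration_unit=rec["conc_unit"].strip(),
            response_value=rec["response_value"].strip(),
            endpoint_uid=(rec.get("endpoint_uid") or "").strip() or None,
        ))
    return rows


def annotations_to_csv(rows: Iterable[AssayAnnotation]) -> str:
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(CSV_COLUMNS)
    for r in rows:
        w.writerow([
            r.assay_id, r.measure_group_index, r.compound_id, r.endpoint_raw,
            r.endpoint_std or "", r.mode_of_action, r.concentration_value,
            r.concentration_unit, r.response_value, r.endpoint_uid or "",
        ])
    return buf.getvalue()


# ----------------------------------------------------------------------
# QC cross-check against the source table
# ----------------------------------------------------------------------


@dataclass
class DiscrepancyReport:
    """(row index, field, annotated value, source value, category) entries;
    category is one of mismatch / missing / non-atomic.  An empty report
    means every cross-checked field agreed."""

    entries: list = field(default_factory=list)

    def __bool__(self) -> bool:
        return bool(self.entries)

    def to_tsv(self) -> str:
        lines = ["row\tfield\tannotated\tsource\tcategory"]
        for e in self.entries:
            lines.append("\t".join(str(x) for x in e))
        return "\n".join(lines) + "\n"


_ATOMIC_SPLIT = re.compile(r"[;|]|,\s")


def _is_blank(v) -> bool:
    return v is None or (isinstance(v, float) and pd.isna(v)) or str(v).strip() == ""


def _numeric_eq(a: str, b: str) -> bool:
    try:
        return float(a) == float(b)
    except (TypeError, ValueError):
        return str(a).strip() == str(b).strip()


def qc_crosscheck(
    annotations: Iterable[AssayAnnotation], source_table: pd.DataFrame
) -> DiscrepancyReport:
    """Cross-reference curated rows against the original source table.

    ``source_table`` is keyed by (assay_id, compound_id) and provides the
    redundant columns ``endpoint``, ``conc_value``, ``conc_unit``.  Flags:
    ``non-atomic`` when a source cell packs several delimiter-separated
    values, ``missing`` when a source cell (or the whole source row) is
    absent, ``mismatch`` when values disagree.
    """
    report = DiscrepancyReport()
    src = {
        (str(rec["assay_id"]).strip(), str(rec["compound_id"]).strip()): rec
        for rec in source_table.to_dict("records")
    }
    checks = [
        ("endpoint", lambda r: r.endpoint_raw, lambda a, b: a.strip() == str(b).strip()),
        ("conc_value", lambda r: r.concentration_value, _numeric_eq),
        ("conc_unit", lambda r: r.concentration_unit,
         lambda a, b: a.strip() == str(b).strip()),
    ]
    for i, row in enumerate(annotations):
        key = (str(row.assay_id).strip(), str(row.compound_id).strip())
        rec = src.get(key)
        if rec is None:
            report.entries.append((i, "row", key, None, "missing"))
            continue
        for fname, getter, eq in checks:
            annotated = getter(row)
            source = rec.get(fname)
            if _is_blank(source):
                report.entries.append((i, fname, annotated, source, "missing"))
            elif len([p for p in _ATOMIC_SPLIT.split(str(source)) if p.strip()]) > 1:
                report.entries.append((i, fname, annotated, source, "non-atomic"))
            elif not eq(str(annotated), source):
                report.entries.append((i, fname, annotated, source, "mismatch"))
    return report
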