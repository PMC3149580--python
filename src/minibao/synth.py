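"""Deterministic fixtures and random assay-annotation generators.

Two kinds of data:

* ``fixture_example1/2/3`` return small hand-built annotation tables whose
  materialized graphs reproduce the worked-query result tuples exactly
  (same compound/assay identifiers and literal lexical forms), plus
  distractor rows that probe each filter: above-threshold concentrations,
  below-threshold responses, the wrong mode of action, and rows sitting
  exactly on the inclusive <=10 uM / >=50 % boundaries.

* ``generate`` produces a parameterized random dataset emulating a
  PubChem-style curated set (mixed endpoint types, log-uniform micromolar
  concentrations, percent responses, a few planted promiscuous compounds)
  together with its ground truth.  The pseudo-random source is Python's
  Mersenne Twister seeded from the config, so identical configs yield
  byte-identical tables.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

from .loader import AssayAnnotation
from .schema import BAO, ENDPOINT_FAMILIES

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "fixture_example1",
    "fixture_example2",
    "fixture_example3",
    "generate",
]


def _row(assay, compound, raw, std, moa, conc, resp, uid, mg=1):
    return AssayAnnotation(
        assay_id=str(assay), measure_group_index=mg, compound_id=str(compound),
        endpoint_raw=raw, endpoint_std=std, mode_of_action=moa,
        concentration_value=conc, concentration_unit="uM",
        response_value=resp, endpoint_uid=uid,
    )


def _iri(local: str) -> str:
    return BAO + local


def _ind(class_id: str, suffix) -> str:
    return _iri(f"individual_{class_id}_{suffix}")


_ASSAY = "BAO_0000015"
_PERT = "BAO_0000021"
_MOA_TYPES = ["BAO_0000084", "BAO_0000087", "BAO_0000093", "BAO_0000094"]


def _expected_rows(records, with_moa=False):
    """Expand (compound, ep_class, ep_uid, types, resp, conc, assay) records
    into plain-string result rows (one per type x moaType combination)."""
    rows = []
    for compound, ep_class, uid, types, resp, conc, assay in records:
        for t in types:
            combos = _MOA_TYPES if with_moa else [None]
            for m in combos:
                row = {
                    "compound": _ind(_PERT, compound),
                    "endpoint": _ind(ep_class, uid),
                    "type": _iri(t),
                    "responseValue": resp,
                    "screeningConc": conc,
                    "assay": _ind(_ASSAY, assay),
                }
                if with_moa:
                    row["moaType"] = _iri(m)
                rows.append(row)
    return rows


_CONC_TYPES_IC50 = ["BAO_0000190", "BAO_0000186", "BAO_0000180"]
_RESP_TYPES_PI = ["BAO_0000201", "BAO_0000181"]


def fixture_example1():
    """Active-inhibitor fixture: the four printed result tuples plus
    distractors (50 uM concentration, 20 % response, activation mode of
    action) and two rows on the inclusive 10 uM / 50 % boundaries."""
    rows = [
        _row(1293, 2858522, "Mean IC50", "IC50", "inhibition", "4.0", "50", "2_2357"),
        _row(2409, 133407, "IC50", "IC50", "inhibition", "8.59", "50", "2_2533"),
        # "potency" standardizes to AC50; the record is asserted IC50 (its
        # minted IRI carries the IC50 accession) and surfaces as an
        # AC50-typed result row through the inferred taxonomy
        _row(948, 11057, "potency", "IC50", "inhibition", "6.3096", "50", "2_4122"),
        _row(834, 657680, "percent inhibition", "percent inhibition", "inhibition",
             "4.0", "63.48", "1_1670"),
        # distractors
        _row(9001, 900001, "IC50", "IC50", "inhibition", "50.0", "50", "2_9001"),
        _row(9002, 900002, "percent inhibition", "percent inhibition", "inhibition",
             "4.0", "20", "1_9002"),
        _row(9003, 900003, "EC50", "EC50", "activation", "4.0", "50", "2_9003"),
        # inclusive boundaries: conc == 10 and response == 50 pass
        _row(9004, 900004, "IC50", "IC50", "inhibition", "10", "50", "2_9004"),
        _row(9005, 900005, "percent inhibition", "percent inhibition", "inhibition",
             "10", "50", "1_9005"),
    ]
    expected = _expected_rows([
        ("2858522", "BAO_0000190", "2_2357", _CONC_TYPES_IC50, "50", "4.0", "1293"),
        ("133407", "BAO_0000190", "2_2533", _CONC_TYPES_IC50, "50", "8.59", "2409"),
        ("11057", "BAO_0000190", "2_4122", _CONC_TYPES_IC50, "50", "6.3096", "948"),
        ("657680", "BAO_0000201", "1_1670", _RESP_TYPES_PI, "63.48", "4.0", "834"),
        ("900004", "BAO_0000190", "2_9004", _CONC_TYPES_IC50, "50", "10", "9004"),
        ("900005", "BAO_0000201", "1_9005", _RESP_TYPES_PI, "50", "10", "9005"),
    ])
    return rows, expected


def fixture_example2():
    """Activator fixture: one EC50 row asserted with mode of action
    *activation* and one percent-activation row asserted with
    *stimulation* only -- the second is retrievable by an activation query
    only through class equivalence."""
    rows = [
        _row(695, 653469, "EC50", "EC50", "activation", "2.154", "50", "2_5524"),
        _row(1318, 645132, "percent activation", "percent activation",
             "stimulation", "5.7", "132.52", "1_464"),
        # distractors
        _row(9101, 910001, "EC50", "EC50", "activation", "40", "50", "2_9101"),
        _row(9102, 910002, "percent activation", "percent activation",
             "stimulation", "5.0", "30", "1_9102"),
        _row(9103, 910003, "IC50", "IC50", "inhibition", "5.0", "50", "2_9103"),
    ]
    expected = _expected_rows([
        ("653469", "BAO_0000188", "2_5524",
         ["BAO_0000188", "BAO_0000186", "BAO_0000180"], "50", "2.154", "695"),
        ("645132", "BAO_0000200", "1_464",
         ["BAO_0000200", "BAO_0000181"], "132.52", "5.7", "1318"),
    ], with_moa=True)
    return rows, expected


def fixture_example3():
    """Promiscuity fixture: compound 646704 responds >= 50 % in three
    assays; a two-assay compound and a three-assay sub-threshold compound
    must stay below the HAVING cut.  Only forward has-perturbagen edges
    are asserted."""
    rows = [
        _row(1262, 646704, "percent inhibition", "percent inhibition",
             "inhibition", "1.0", "116.84", "1_7001"),
        _row(1306, 646704, "percent inhibition", "percent inhibition",
             "inhibition", "1.0", "106.48", "1_7002"),
        _row(1316, 646704, "percent inhibition", "percent inhibition",
             "inhibition", "1.0", "99.42", "1_7003"),
        # active in only two assays
        _row(9201, 700001, "percent inhibition", "percent inhibition",
             "inhibition", "1.0", "80", "1_9201"),
        _row(9202, 700001, "percent inhibition", "percent inhibition",
             "inhibition", "1.0", "80", "1_9202"),
        # three assays but sub-threshold responses
        _row(9203, 700002, "percent inhibition", "percent inhibition",
             "inhibition", "1.0", "20", "1_9203"),
        _row(9204, 700002, "percent inhibition", "percent inhibition",
             "inhibition", "1.0", "20", "1_9204"),
        _row(9205, 700002, "percent inhibition", "percent inhibition",
             "inhibition", "1.0", "20", "1_9205"),
    ]
    expected_promiscuous = [_ind(_PERT, "646704")]
    expected_profile = [
        {"assay": _ind(_ASSAY, "1262"), "percentResponseValue": "116.84"},
        {"assay": _ind(_ASSAY, "1306"), "percentResponseValue": "106.48"},
        {"assay": _ind(_ASSAY, "1316"), "percentResponseValue": "99.42"},
    ]
    return rows, {"promiscuous": expected_promiscuous, "profile": expected_profile}


# ----------------------------------------------------------------------
# Random datasets with planted ground truth
# ----------------------------------------------------------------------


@dataclass
class GeneratorConfig:
    """Study-shaped defaults: 194 assays with ~20 endpoint records each,
    the six standardized endpoint types of the curated set, log-uniform
    micromolar screening concentrations, and a handful of planted
    promiscuous compounds responding >= 50 % in at least
    ``promiscuity_degree`` distinct assays."""

    seed: int = 0
    n_assays: int = 194
    endpoints_per_assay: int = 20
    endpoint_type_mix: dict = field(default_factory=lambda: {
        "IC50": 0.25, "EC50": 0.15, "AC50": 0.10,
        "percent inhibition": 0.25, "percent activation": 0.15,
        "percent stimulation": 0.10,
    })
    conc_range_um: tuple = (0.01, 100.0)
    #: (mean, sd) percent response for inactive / active response rows
    inactive_response: tuple = (0.0, 15.0)
    active_response: tuple = (80.0, 15.0)
    active_fraction: float = 0.1
    n_promiscuous_compounds: int = 5
    promiscuity_degree: int = 4

    def validate(self) -> None:
        if self.promiscuity_degree > self.n_assays:
            raise ValueError(
                "promiscuity_degree cannot exceed n_assays "
                f"({self.promiscuity_degree} > {self.n_assays})")
        if not self.endpoint_type_mix:
            raise ValueError("endpoint_type_mix must be non-empty")
        for label in self.endpoint_type_mix:
            if label not in ENDPOINT_FAMILIES:
                raise ValueError(f"unknown endpoint type {label!r}")


_MOA_FOR_ENDPOINT = {
    "IC50": ["inhibition"],
    "EC50": ["activation", "stimulation"],
    "AC50": ["inhibition", "activation"],
    "CC50": ["inhibition"],
    "percent inhibition": ["inhibition"],
    "percent activation": ["activation", "stimulation"],
    "percent stimulation": ["stimulation"],
    "percent viability": ["inhibition"],
    "fold activation": ["activation"],
}


@dataclass
class GroundTruth:
    planted_promiscuous: list  # compound id strings
    #: endpoint_uid -> set of standardized endpoint labels the endpoint
    #: individual must be realized into (family roots excluded)
    expected_realized: dict


def _expected_classes(std: str, moa: str) -> set:
    out = {std}
    if ENDPOINT_FAMILIES[std] == "concentration" and std != "CC50":
        out.add("AC50")
        out.add("IC50" if moa == "inhibition" else "EC50")
    return out


def generate(config: GeneratorConfig) -> tuple[list, GroundTruth]:
    """Reproducible random annotation table + ground truth.

    Planted promiscuous compounds get ``promiscuity_degree`` qualifying
    response rows in distinct assays; every background compound appears in
    at most two assays, so with the usual HAVING threshold of three the
    planted set is exactly recoverable.
    """
    config.validate()
    rng = random.Random(config.seed)
    labels = sorted(config.endpoint_type_mix)
    weights = [config.endpoint_type_mix[k] for k in labels]
    lo, hi = config.conc_range_um

    rows: list[AssayAnnotation] = []
    expected_realized: dict = {}
    assay_ids = [str(10000 + i) for i in range(config.n_assays)]
    next_compound = [500000]
    compound_uses: dict = {}
    reusable: list = []

    def fresh_compound() -> str:
        # reuse a previous compound for a second (never third) appearance
        if reusable and rng.random() < 0.3:
            cid = reusable.pop(rng.randrange(len(reusable)))
        else:
            next_compound[0] += 1
            cid = str(next_compound[0])
            reusable.append(cid)
        compound_uses[cid] = compound_uses.get(cid, 0) + 1
        if compound_uses[cid] >= 2 and cid in reusable:
            reusable.remove(cid)
        return cid

    uid_counter = [0]

    def make_row(assay_id, compound_id, std, response=None):
        moa = rng.choice(_MOA_FOR_ENDPOINT[std])
        family = ENDPOINT_FAMILIES[std]
        conc = math.exp(rng.uniform(math.log(lo), math.log(hi)))
        uid_counter[0] += 1
        uid = f"{2 if family == 'concentration' else 1}_{uid_counter[0]}"
        if family == "concentration":
            resp = "50"
        elif response is not None:
            resp = f"{response:.2f}"
        else:
            if rng.random() < config.active_fraction:
                mu, sd = config.active_response
            else:
                mu, sd = config.inactive_response
            resp = f"{rng.gauss(mu, sd):.2f}"
        row = _row(assay_id, compound_id, std, std, moa,
                   f"{conc:.4g}", resp, uid)
        expected_realized[uid] = _expected_classes(std, moa)
        return row

    # planted promiscuous compounds: qualifying response rows in distinct
    # assays (response family so the >=50% value is the measured response)
    planted = []
    resp_labels = [l for l in labels
                   if ENDPOINT_FAMILIES[l] == "response"] or ["percent inhibition"]
    for k in range(config.n_promiscuous_compounds):
        next_compound[0] += 1
        cid = str(next_compound[0])
        planted.append(cid)
        for assay_id in rng.sample(assay_ids, config.promiscuity_degree):
            std = rng.choice(resp_labels)
            response = min(150.0, max(50.0, rng.gauss(*config.active_response)))
            rows.append(make_row(assay_id, cid, std, response=response))

    # background rows; background compounds appear in <= 2 assays and, when
    # they carry a concentration-type endpoint (which always qualifies via
    # its 50% nominal), still stay under a >=3 HAVING threshold
    for assay_id in assay_ids:
        for _ in range(config.endpoints_per_assay):
            std = rng.choices(labels, weights=weights, k=1)[0]
            rows.append(make_row(assay_id, fresh_compound(), std))

    return rows, GroundTruth(planted_promiscuous=planted,
                             expected_realized=expected_realized)
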