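"""Clinical Risk Score and the integrated subtype x CRS risk stratification.

The CRS counts five adverse clinicopathological features: disease-free
interval from primary diagnosis to metastasis under 12 months, more than
one liver metastasis, largest metastasis over 5 cm, node-positive primary
tumor, and high CEA (200 ng/mL threshold). Low CRS means a score below
two. Crossing the three molecular subtypes with the binary CRS class gives
the three-tier integrated risk rule:

    low:          subtype 1 or 2 with low CRS
    intermediate: subtype 2 with high CRS, or subtype 3 with low CRS
    high:         subtype 1 or 3 with high CRS
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CRS_FEATURES, PatientRecord
from .stats import TestResult, chisq_test, fisher_exact

CRS_LOW_THRESHOLD = 2  # low CRS = score strictly below 2

#: (subtype, crs_class) -> integrated risk tier, total over all six cells
RISK_RULE: dict[tuple[int, str], str] = {
    (1, "low"): "low",
    (2, "low"): "low",
    (2, "high"): "intermediate",
    (3, "low"): "intermediate",
    (1, "high"): "high",
    (3, "high"): "high",
}

RISK_TIERS = ("low", "intermediate", "high")
RECURRENCE_CATEGORIES = ("none", "limited", "widespread")
LIMITED_MAX = 3  # limited recurrence: 1-3 subsequent metastases


@dataclasses.dataclass
class RiskAssignment:
    sample_id: str
    crs_score: int
    crs_class: str
    subtype: int
    integrated_risk: str


def compute_crs(record: PatientRecord | Mapping[str, bool]) -> tuple[int, str]:
    """CRS = number of adverse features present; class 'low' iff score < 2.

    All five features must be present; a missing feature is an error (no
    imputation), named in the message.
    """
    feats = record.crs_features if isinstance(record, PatientRecord) else record
    sample = record.sample_id if isinstance(record, PatientRecord) else "<record>"
    missing = [k for k in CRS_FEATURES if k not in feats or feats[k] is None]
    if missing:
        raise ValueError(f"{sample}: missing CRS feature(s) {missing}")
    score = int(sum(bool(feats[k]) for k in CRS_FEATURES))
    return score, ("low" if score < CRS_LOW_THRESHOLD else "high")


def threshold_features(
    dfi_months: float,
    n_metastases: int,
    largest_cm: float,
    node_positive: bool,
    cea_ng_ml: float,
    cea_inclusive: bool = False,
) -> dict[str, bool]:
    """Adapter from raw clinical values to the five CRS booleans.

    Boundaries: DFI strictly under 12 months; more than one metastasis;
    size strictly over 5 cm; CEA strictly over 200 ng/mL by default
    (``cea_inclusive=True`` counts exactly 200 as adverse).
    """
    return {
        "dfi_lt_12mo": dfi_months < 12.0,
        "mets_gt_1": n_metastases > 1,
        "size_gt_5cm": largest_cm > 5.0,
        "node_positive": bool(node_positive),
        "cea_ge_200": cea_ng_ml >= 200.0 if cea_inclusive else cea_ng_ml > 200.0,
    }


def integrate_risk(subtype: int, crs_class: str) -> str:
    """Map (molecular subtype, CRS class) to the integrated risk tier."""
    if subtype not in (1, 2, 3):
        raise ValueError(f"unknown subtype label {subtype!r}")
    if crs_class not in ("low", "high"):
        raise ValueError(f"crs_class must be 'low' or 'high', got {crs_class!r}")
    return RISK_RULE[(int(subtype), crs_class)]


def assign_risk(
    records: Sequence[PatientRecord], subtypes: Sequence[int]
) -> list[RiskAssignment]:
    """Per-patient CRS and integrated risk for an aligned cohort."""
    if len(records) != len(subtypes):
        raise ValueError("records and subtype labels differ in length")
    out = []
    for rec, s in zip(records, subtypes):
        score, cls = compute_crs(rec)
        out.append(RiskAssignment(rec.sample_id, score, cls, int(s),
                                  integrate_risk(int(s), cls)))
    return out


def recurrence_category(count: int | None) -> str:
    if count is None:
        raise ValueError("recurrence_count missing")
    if count == 0:
        return "none"
    return "limited" if count <= LIMITED_MAX else "widespread"


def recurrence_pattern_table(
    assignments: Sequence[RiskAssignment],
    records: Sequence[PatientRecord],
    group_by: str = "integrated_risk",
) -> tuple[pd.DataFrame, TestResult | None, dict[str, dict[str, TestResult]]]:
    """Cross-tabulate risk tier (or subtype) against recurrence pattern.

    Returns the tier x {none, limited, widespread} count table, the
    chi-square test across tiers, and per-tier Fisher tests: "vs_rest"
    (this tier's limited-vs-widespread split among recurrent patients
    against all other tiers pooled). If no patient recurred the table is
    returned with the tests skipped (None / empty).
    """
    if len(assignments) != len(records):
        raise ValueError("assignments and records differ in length")
    if group_by == "integrated_risk":
        groups = [a.integrated_risk for a in assignments]
        levels = [t for t in RISK_TIERS if t in set(groups)]
    elif group_by == "subtype":
        groups = [str(a.subtype) for a in assignments]
        levels = sorted(set(groups))
    else:
        raise ValueError("group_by must be 'integrated_risk' or 'subtype'")

    cats = [recurrence_category(r.recurrence_count) for r in records]
    table = pd.DataFrame(0, index=levels, columns=list(RECURRENCE_CATEGORIES))
    for g, c in zip(groups, cats):
        table.loc[g, c] += 1

    recurrent = table[["limited", "widespread"]]
    if recurrent.to_numpy().sum() == 0:
        return table, None, {}

    overall = None
    lw = recurrent.loc[(recurrent.sum(axis=1) > 0)]
    if len(lw) >= 2 and (lw.sum(axis=0) > 0).all():
        overall = chisq_test(lw.to_numpy())

    per_tier: dict[str, dict[str, TestResult]] = {}
    for tier in levels:
        this = recurrent.loc[tier].to_numpy()
        rest = recurrent.drop(index=tier).sum(axis=0).to_numpy()
        if this.sum() == 0 and rest.sum() == 0:
            continue
        per_tier[tier] = {"vs_rest": fisher_exact(np.array([this, rest], dtype=int))}
    return table, overall, per_tier


def risk_table(assignments: Sequence[RiskAssignment]) -> pd.DataFrame:
    """Per-sample TSV-ready table: sample_id, crs_score, crs_class, subtype, tier."""
    return pd.DataFrame(
        [
            {
                "sample_id": a.sample_id,
                "crs_score": a.crs_score,
                "crs_class": a.crs_class,
                "subtype": a.subtype,
                "integrated_risk": a.integrated_risk,
            }
            for a in assignments
        ]
    )
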