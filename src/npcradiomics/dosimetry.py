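"""Dosimetric recurrence-pattern classification and cohort tabulation.

A recurrence volume (V_recur), delineated on recurrence imaging and mapped
onto the planning dose grid (registration is an input contract, not a
computation here), is classified by the fraction of its voxels receiving at
least 95% of the prescribed dose:

* in-field: fraction >= 0.95
* marginal miss: 0.20 <= fraction < 0.95
* out-of-field: fraction < 0.20

Both boundaries are left-closed ("95% or more" puts 0.95 in-field; "20 to
95%" puts 0.20 in marginal) and the dose threshold is inclusive (an isodose
surface includes its level). Volume fractions are voxel-counted: after
isotropic resampling all voxels carry equal volume, and sub-voxel
interpolation would be spurious precision.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import ImageVolume, RoiMask, check_congruent

__all__ = [
    "IN_FIELD",
    "MARGINAL",
    "OUT_OF_FIELD",
    "RecurrenceCase",
    "FailurePattern",
    "fraction_in_isodose",
    "classify_pattern",
    "tabulate_cohort",
    "load_clinical_table",
]

IN_FIELD = "in_field"
MARGINAL = "marginal"
OUT_OF_FIELD = "out_of_field"

SITES = ("local", "regional", "local_regional")
PATTERNS = (IN_FIELD, MARGINAL, OUT_OF_FIELD)


@dataclass
class RecurrenceCase:
    dose: ImageVolume  # Gy
    prescription_gy: float
    recur_mask: RoiMask
    site: str | None = None
    time_to_failure_months: float | None = None
    achieved_fraction_in: float | None = None  # generator ground truth

    def __post_init__(self) -> None:
        check_congruent(self.dose, self.recur_mask)
        if self.prescription_gy <= 0:
            raise ValueError("prescription_gy must be positive")
        if np.any(np.asarray(self.dose.values) < 0):
            raise ValueError("dose grid contains negative values")


@dataclass
class FailurePattern:
    category: str
    fraction_in: float


def fraction_in_isodose(case: RecurrenceCase, isodose_fraction: float = 0.95) -> float:
    """Fraction of V_recur voxels with dose >= isodose_fraction * prescription.

    This is the recurrence-volume DVH evaluated at the isodose level; the
    threshold is inclusive.
    """
    if case.recur_mask.is_empty():
        raise ValueError("recurrence mask is empty")
    threshold = isodose_fraction * case.prescription_gy
    in_mask = np.asarray(case.dose.values)[case.recur_mask.values]
    return float((in_mask >= threshold).sum() / in_mask.size)


def classify_pattern(fraction_in: float) -> FailurePattern:
    if not 0.0 <= fraction_in <= 1.0:
        raise ValueError(f"fraction_in must be in [0, 1], got {fraction_in}")
    if fraction_in >= 0.95:
        category = IN_FIELD
    elif fraction_in >= 0.20:
        category = MARGINAL
    else:
        category = OUT_OF_FIELD
    return FailurePattern(category=category, fraction_in=fraction_in)


def load_clinical_table() -> pd.DataFrame:
    """The packaged 20-patient recurrent-NPC clinical table."""
    ref = importlib.resources.files("npcradiomics.data") / "recurrent_cohort_clinical.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


def tabulate_cohort(clinical: pd.DataFrame) -> dict:
    """Failure-pattern summary: counts by pattern and site, time-to-failure stats.

    Rows missing site or time-to-failure are flagged, not dropped.
    """
    flagged = clinical[
        clinical["site"].isna() | clinical["time_to_failure_months"].isna()
    ]["id"].tolist() if len(clinical) else []

    pattern_counts = {p: int((clinical.get("pattern", pd.Series(dtype=str)) == p).sum()) for p in PATTERNS}
    site_counts = {s: int((clinical.get("site", pd.Series(dtype=str)) == s).sum()) for s in SITES}

    ttf = clinical["time_to_failure_months"].dropna() if "time_to_failure_months" in clinical else pd.Series(dtype=float)
    if len(ttf):
        ttf_summary = {
            "median": float(ttf.median()),
            "min": float(ttf.min()),
            "max": float(ttf.max()),
        }
    else:
        ttf_summary = {"median": None, "min": None, "max": None}

    return {
        "n_cases": int(len(clinical)),
        "pattern_counts": pattern_counts,
        "site_counts": site_counts,
        "time_to_failure_months": ttf_summary,
        "flagged_rows": flagged,
    }
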