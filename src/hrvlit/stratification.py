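"""Sigma-threshold risk stratification with literature-aligned prediction.

Subjects are placed in one of three strata of the selected HRV feature —
more than k·SD above the reference mean, more than k·SD below, or within
±k·SD (boundary values fall *within*, since the strata are defined by strict
"more than" inequalities).  A subject is predicted event-positive exactly
when their stratum agrees with the literature's dominant risk direction:
a negatively associated parameter predicts events in the *below* stratum, a
positively associated one in the *above* stratum.

The reference mean/SD may be computed over all subjects or, by default, over
non-event (control) subjects only — the latter avoids letting the events
shift their own reference.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("hrvlit.stratification")

REFERENCE_MODES = ("all_subjects", "non_event_only")
STRATA = ("above", "within", "below")


class DegenerateDistributionError(ValueError):
    """Reference feature distribution has zero spread or too few subjects."""


@dataclass
class ReferenceStats:
    mean: float
    sd: float
    reference_mode: str
    n_reference: int


def reference_stats(
    cohort: pd.DataFrame,
    feature: str,
    reference_mode: str = "non_event_only",
) -> ReferenceStats:
    """Sample mean and SD (ddof=1) of the feature over the reference set."""
    if reference_mode not in REFERENCE_MODES:
        raise ValueError(f"unknown reference_mode {reference_mode!r}")
    if feature not in cohort.columns:
        raise KeyError(f"cohort has no feature column {feature!r}")
    values = cohort[feature].to_numpy(dtype=float)
    finite = np.isfinite(values)
    if reference_mode == "non_event_only":
        ref_mask = finite & ~cohort["event"].to_numpy(dtype=bool)
    else:
        ref_mask = finite
    ref = values[ref_mask]
    if ref.size < 2:
        raise DegenerateDistributionError(
            f"need >= 2 reference subjects, got {ref.size}"
        )
    sd = float(np.std(ref, ddof=1))
    if sd == 0:
        raise DegenerateDistributionError("reference feature values are identical")
    return ReferenceStats(
        mean=float(np.mean(ref)),
        sd=sd,
        reference_mode=reference_mode,
        n_reference=int(ref.size),
    )


def stratify(value: float, ref: ReferenceStats, k: float = 1.0) -> str:
    """Assign 'above' / 'within' / 'below' relative to mean ± k·SD (strict)."""
    if not math.isfinite(value):
        raise ValueError("cannot stratify a non-finite value")
    if k <= 0:
        raise ValueError("k must be positive")
    if value > ref.mean + k * ref.sd:
        return "above"
    if value < ref.mean - k * ref.sd:
        return "below"
    return "within"


def predict(stratum: str, dominant_direction: str) -> bool:
    """Event prediction: positive iff the stratum matches the risk direction."""
    if stratum not in STRATA:
        raise ValueError(f"unknown stratum {stratum!r}")
    if dominant_direction == "negative":
        return stratum == "below"
    if dominant_direction == "positive":
        return stratum == "above"
    raise ValueError(f"unknown direction {dominant_direction!r}")


def classify_cohort(
    cohort: pd.DataFrame,
    feature: str,
    dominant_direction: str,
    reference_mode: str = "non_event_only",
    k: float = 1.0,
) -> pd.DataFrame:
    """Stratify and predict every subject; returns a per-subject table.

    Subjects with a missing (non-finite) feature value are excluded with a
    logged count rather than imputed.  Output columns: subject_id, stratum,
    prediction, plus event carried through for evaluation.
    """
    if cohort.empty:
        raise ValueError("cohort is empty")
    ref = reference_stats(cohort, feature, reference_mode)
    values = cohort[feature].to_numpy(dtype=float)
    usable = np.isfinite(values)
    n_missing = int(np.count_nonzero(~usable))
    if n_missing:
        logger.warning("classify_cohort: %d subjects excluded (missing %s)",
                       n_missing, feature)
    sub = cohort.loc[usable].reset_index(drop=True)
    strata = [stratify(v, ref, k) for v in values[usable]]
    preds = [predict(s, dominant_direction) for s in strata]
    return pd.DataFrame(
        {
            "subject_id": sub["subject_id"],
            "stratum": strata,
            "prediction": preds,
            "event": sub["event"].astype(bool),
        }
    )
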