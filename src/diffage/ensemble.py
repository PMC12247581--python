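"""Consensus of per-slice age predictions.

Plain averaging and the outlier-exclusion rule: compute the mean and sample
standard deviation of the slice predictions, drop any prediction deviating
from the mean by strictly more than one SD (single pass), and average the
rest.  With the sample-SD convention and a strict inequality at least one
prediction always survives, so the consensus is well defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["EnsembleResult", "mean_ensemble", "outlier_excluded_ensemble",
           "ensemble_cohort"]


@dataclass(frozen=True)
class EnsembleResult:
    final_age: float
    included_mask: tuple[bool, ...]
    ensemble_mean: float
    ensemble_sd: float
    method: str

    def __post_init__(self):
        if not any(self.included_mask):
            raise ValueError("at least one prediction must be included")


def mean_ensemble(predictions) -> EnsembleResult:
    """Arithmetic mean of all slice predictions."""
    p = np.asarray(predictions, dtype=np.float64)
    if p.size == 0:
        raise ValueError("no predictions to ensemble")
    sd = float(p.std(ddof=1)) if p.size > 1 else 0.0
    return EnsembleResult(final_age=float(p.mean()),
                          included_mask=tuple([True] * p.size),
                          ensemble_mean=float(p.mean()), ensemble_sd=sd,
                          method="mean")


def outlier_excluded_ensemble(predictions) -> EnsembleResult:
    """Drop predictions deviating more than one sample SD, then average.

    Exclusion is single-pass: the mean/SD used for the rule are computed on
    the full prediction set.  With fewer than 2 predictions the rule is
    meaningless and the plain mean is returned with a warning; with zero SD
    nothing is excluded.
    """
    p = np.asarray(predictions, dtype=np.float64)
    if p.size < 2:
        warnings.warn("outlier exclusion needs >= 2 predictions; "
                      "falling back to mean ensemble", stacklevel=2)
        return mean_ensemble(p)
    m = p.mean()
    s = p.std(ddof=1)
    mask = np.abs(p - m) <= s if s > 0 else np.ones(p.size, bool)
    return EnsembleResult(final_age=float(p[mask].mean()),
                          included_mask=tuple(bool(b) for b in mask),
                          ensemble_mean=float(m), ensemble_sd=float(s),
                          method="outlier_excluded")


_METHODS = {"mean": mean_ensemble, "outlier_excluded": outlier_excluded_ensemble}


def ensemble_cohort(predictions: pd.DataFrame, method: str = "outlier_excluded",
                    percentiles=None) -> pd.DataFrame:
    """Per-subject consensus from a long table of slice predictions.

    ``predictions`` needs columns subject_id, percentile, predicted_age.
    Subjects missing any requested percentile are flagged (``complete`` is
    False) rather than silently dropped.
    """
    if method not in _METHODS:
        raise ValueError(f"unknown ensembling method {method!r}")
    fn = _METHODS[method]
    required = None if percentiles is None else set(percentiles)
    rows = []
    for sid, grp in predictions.groupby("subject_id", sort=True):
        have = set(grp["percentile"])
        if required is not None:
            grp = grp[grp["percentile"].isin(required)]
        complete = required is None or required <= have
        res = fn(grp["predicted_age"].to_numpy())
        rows.append({"subject_id": sid, "final_age": res.final_age,
                     "ensemble_mean": res.ensemble_mean,
                     "ensemble_sd": res.ensemble_sd,
                     "n_included": int(sum(res.included_mask)),
                     "method": res.method, "complete": complete})
    return pd.DataFrame(rows)
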