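"""Brain-age-gap statistics and volumetric association analyses.

Covers accuracy metrics (MAE with IQR of absolute errors), the brain-age gap
(predicted minus chronological age), Younger/Average/Older outlier grouping
within (age-bin, sex) strata, pairwise Mann-Whitney U comparisons of
volumetric measures with Bonferroni correction and Cohen's d effect sizes,
longitudinal rate categorization (Accelerated/Decelerated/Stable), a
comparison of chronological-age vs brain-age linear models on volumetrics,
and an optional linear age-bias correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .phantom import VOLUMETRIC_MEASURES

__all__ = [
    "compute_gap", "mae_iqr", "classify_gap_outliers", "cohens_d",
    "group_compare", "categorize_longitudinal", "compare_age_models",
    "age_bias_correct", "BiasModel",
]


def compute_gap(predicted, chronological):
    """Brain-age gap in years: predicted brain age minus chronological age."""
    return np.asarray(predicted, dtype=np.float64) - np.asarray(chronological,
                                                                dtype=np.float64)


def mae_iqr(predicted, chronological) -> dict:
    """MAE and the [25th, 75th] percentiles of the absolute error.

    Percentiles use the linear-interpolation convention.
    """
    err = np.abs(compute_gap(predicted, chronological))
    if err.size == 0:
        raise ValueError("no records")
    q1, q3 = np.percentile(err, [25, 75])
    return {"MAE": float(err.mean()), "IQR": (float(q1), float(q3))}


def classify_gap_outliers(records: pd.DataFrame, sd_multiplier: float = 1.0) -> pd.DataFrame:
    """Label records Younger/Average/Older within (age-bin, sex) strata.

    Within each stratum (integer-year chronological age bin x sex), a record
    is Older when its predicted age exceeds the stratum mean prediction by
    more than ``sd_multiplier`` sample SDs, Younger when below by more than
    that, else Average.  Strata with fewer than 3 records have no meaningful
    SD and are labeled Average with a warning.
    """
    req = {"chronological_age", "predicted_age", "sex"}
    if not req <= set(records.columns):
        raise ValueError(f"records must have columns {sorted(req)}")
    if records[list(req)].isna().any().any():
        raise ValueError("missing chronological_age/predicted_age/sex values")
    out = records.copy()
    out["age_bin"] = np.floor(out["chronological_age"]).astype(int)
    out["group"] = "Average"
    small = 0
    for (_, _), idx in out.groupby(["age_bin", "sex"], sort=False).groups.items():
        pred = out.loc[idx, "predicted_age"].to_numpy()
        if len(pred) < 3:
            small += len(pred)
            continue
        m, s = pred.mean(), pred.std(ddof=1)
        if s == 0:
            continue
        labels = np.where(pred > m + sd_multiplier * s, "Older",
                          np.where(pred < m - sd_multiplier * s, "Younger", "Average"))
        out.loc[idx, "group"] = labels
    if small:
        warnings.warn(f"{small} records in strata of size < 3 labeled Average",
                      stacklevel=2)
    out["gap"] = compute_gap(out["predicted_age"], out["chronological_age"])
    return out


def cohens_d(a, b) -> float:
    """Standardized mean difference with pooled sample SD."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    na, nb = len(a), len(b)
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                     / (na + nb - 2))
    if pooled == 0:
        return 0.0
    return float((a.mean() - b.mean()) / pooled)


def group_compare(records: pd.DataFrame,
                  measures=VOLUMETRIC_MEASURES,
                  group_col: str = "group",
                  pairs=(("Older", "Average"), ("Younger", "Average")),
                  alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise Mann-Whitney U tests of volumetrics across gap groups.

    One two-sided test per (measure, sex, group pair) with tie handling;
    the Bonferroni-adjusted significance level is
    ``alpha / (n_measures * n_sexes * n_pairs)`` — 0.05/16 = 0.003125 for
    the default 4 x 2 x 2 design.  Cohen's d uses the pooled sample SD.
    Comparisons with an empty group are reported with NaN statistics.
    """
    sexes = sorted(records["sex"].unique())
    n_comparisons = len(measures) * len(sexes) * len(pairs)
    alpha_adj = alpha / n_comparisons
    rows = []
    for measure in measures:
        for sex in sexes:
            sub = records[records["sex"] == sex]
            for g1, g2 in pairs:
                a = sub.loc[sub[group_col] == g1, measure].to_numpy()
                b = sub.loc[sub[group_col] == g2, measure].to_numpy()
                if len(a) == 0 or len(b) == 0:
                    rows.append({"measure": measure, "sex": sex, "group1": g1,
                                 "group2": g2, "n1": len(a), "n2": len(b),
                                 "U": np.nan, "p": np.nan, "cohens_d": np.nan,
                                 "significant": False, "alpha_adj": alpha_adj})
                    continue
                U, p = stats.mannwhitneyu(a, b, alternative="two-sided")
                rows.append({"measure": measure, "sex": sex, "group1": g1,
                             "group2": g2, "n1": len(a), "n2": len(b),
                             "U": float(U), "p": float(p),
                             "cohens_d": cohens_d(a, b),
                             "significant": bool(p < alpha_adj),
                             "alpha_adj": alpha_adj})
    return pd.DataFrame(rows)


def _subject_rates(grp: pd.DataFrame, value_col: str) -> float:
    """Mean of the per-interval rates Delta(value)/Delta(age)."""
    ages = grp["age"].to_numpy()
    vals = grp[value_col].to_numpy()
    rates = []
    for i in range(1, len(ages)):
        da = ages[i] - ages[i - 1]
        if da <= 0:
            warnings.warn("non-increasing visit ages; interval skipped",
                          stacklevel=2)
            continue
        rates.append((vals[i] - vals[i - 1]) / da)
    return float(np.mean(rates)) if rates else np.nan


def categorize_longitudinal(visits: pd.DataFrame,
                            measures=VOLUMETRIC_MEASURES,
                            sd_multiplier: float = 1.0,
                            alpha: float = 0.05) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rates of change per subject, Accelerated/Decelerated/Stable labels
    and group comparisons of volumetric rates.

    Subjects are categorized by their brain-age rate of change: Accelerated
    when above the cohort mean by more than ``sd_multiplier`` SDs,
    Decelerated when below by more than that, else Stable.  For each
    volumetric rate, two-sided Mann-Whitney U tests compare Stable vs
    Accelerated and Stable vs Decelerated at the Bonferroni-adjusted level
    ``alpha / (n_measures * 2)`` (0.05/8 ~= 0.006 for the default design).

    Returns (per-subject rate table, comparison table).
    """
    rows = []
    for sid, grp in visits.groupby("subject_id", sort=True):
        grp = grp.sort_values("age")
        if len(grp) < 2:
            raise ValueError(f"subject {sid} has fewer than 2 visits")
        row = {"subject_id": sid,
               "brainage_rate": _subject_rates(grp, "predicted_age")}
        for m in measures:
            row[f"{m}_rate"] = _subject_rates(grp, m)
        rows.append(row)
    subjects = pd.DataFrame(rows)
    r = subjects["brainage_rate"].to_numpy()
    finite = r[~np.isnan(r)]
    m = finite.mean() if len(finite) else np.nan
    s = finite.std(ddof=1) if len(finite) > 1 else 0.0
    if s == 0 or np.isnan(s):
        subjects["category"] = "Stable"
    else:
        subjects["category"] = np.where(
            r > m + sd_multiplier * s, "Accelerated",
            np.where(r < m - sd_multiplier * s, "Decelerated", "Stable"))

    n_comparisons = len(measures) * 2
    alpha_adj = alpha / n_comparisons
    comp_rows = []
    stable = subjects[subjects["category"] == "Stable"]
    for measure in measures:
        for other in ("Accelerated", "Decelerated"):
            grp = subjects[subjects["category"] == other]
            a = grp[f"{measure}_rate"].dropna().to_numpy()
            b = stable[f"{measure}_rate"].dropna().to_numpy()
            if len(a) == 0 or len(b) == 0:
                comp_rows.append({"measure": measure, "comparison": f"Stable-vs-{other}",
                                  "n_other": len(a), "n_stable": len(b),
                                  "U": np.nan, "p": np.nan, "significant": False,
                                  "alpha_adj": alpha_adj})
                continue
            U, p = stats.mannwhitneyu(a, b, alternative="two-sided")
            comp_rows.append({"measure": measure, "comparison": f"Stable-vs-{other}",
                              "n_other": len(a), "n_stable": len(b),
                              "U": float(U), "p": float(p),
                              "significant": bool(p < alpha_adj),
                              "alpha_adj": alpha_adj})
    return subjects, pd.DataFrame(comp_rows)


def compare_age_models(volumetrics: pd.DataFrame, chronological, predicted) -> dict:
    """R^2 of OLS fits of chronological vs predicted age on volumetrics + sex."""
    if len(volumetrics) < 10:
        raise ValueError("need >= 10 rows")
    X = volumetrics[list(VOLUMETRIC_MEASURES) + ["sex"]].to_numpy(dtype=np.float64)
    X = sm.add_constant(X)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    r2 = {}
    for name, y in (("R2_chrono", chronological), ("R2_brainage", predicted)):
        fit = sm.OLS(np.asarray(y, dtype=np.float64), X).fit()
        r2[name] = float(fit.rsquared)
    return r2


@dataclass(frozen=True)
class BiasModel:
    """Linear age-bias model gap = slope * age + intercept fit on a held-out set."""

    slope: float
    intercept: float

    def correct(self, predictions, ages) -> np.ndarray:
        predictions = np.asarray(predictions, dtype=np.float64)
        ages = np.asarray(ages, dtype=np.float64)
        return predictions - (self.slope * ages + self.intercept)


def age_bias_correct(predictions, chronological, fit_predictions, fit_ages):
    """Fit the linear bias on a fit set and apply the correction elsewhere.

    Returns (corrected predictions, BiasModel).  The transform is optional
    and off by default in the pipeline.
    """
    fit_ages = np.asarray(fit_ages, dtype=np.float64)
    if np.ptp(fit_ages) == 0:
        raise ValueError("cannot fit age bias on constant ages")
    gap = compute_gap(fit_predictions, fit_ages)
    res = stats.linregress(fit_ages, gap)
    model = BiasModel(slope=float(res.slope), intercept=float(res.intercept))
    return model.correct(predictions, chronological), model
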