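"""Brain-age-gap metrics, grouping, group tests and longitudinal rates."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from diffage.analysis import (age_bias_correct, categorize_longitudinal,
                              classify_gap_outliers, cohens_d,
                              compare_age_models, compute_gap, group_compare,
                              mae_iqr)
from diffage.phantom import (VOLUMETRIC_MEASURES, generate_longitudinal_cohort,
                             generate_volumetric_table)


def _u_oracle(a, b):
    """U statistic by exhaustive pair counting (ties count half)."""
    u = 0.0
    for x in a:
        for y in b:
            u += 1.0 if x > y else (0.5 if x == y else 0.0)
    return u


class TestComputeGap:
    @pytest.mark.parametrize("pred,chrono,expected",
                             [(12.0, 10.0, 2.0), (10.0, 10.0, 0.0),
                              (8.5, 10.0, -1.5)])
    def test_examples(self, pred, chrono, expected):
        assert compute_gap(pred, chrono) == expected

    def test_antisymmetric(self, rng):
        a, b = rng.normal(size=10), rng.normal(size=10)
        assert np.allclose(compute_gap(a, b), -compute_gap(b, a))


class TestMaeIqr:
    def test_simple_mean(self):
        out = mae_iqr([11.0, 12.0, 13.0], [10.0, 10.0, 10.0])
        assert out["MAE"] == pytest.approx(2.0)

    def test_zero_gaps(self):
        out = mae_iqr([5.0, 6.0], [5.0, 6.0])
        assert out["MAE"] == 0.0
        assert out["IQR"] == (0.0, 0.0)

    def test_matches_percentile_oracle(self, rng):
        pred, chrono = rng.uniform(3, 30, 50), rng.uniform(3, 30, 50)
        out = mae_iqr(pred, chrono)
        err = np.sort(np.abs(pred - chrono))
        # linear-interpolation percentile oracle
        def pct(q):
            pos = q * (len(err) - 1)
            lo, frac = int(np.floor(pos)), pos - int(np.floor(pos))
            return err[lo] * (1 - frac) + err[min(lo + 1, len(err) - 1)] * frac
        assert out["IQR"][0] == pytest.approx(pct(0.25), abs=1e-9)
        assert out["IQR"][1] == pytest.approx(pct(0.75), abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mae_iqr([], [])


def _records(pred, ages=None, sex=0):
    n = len(pred)
    return pd.DataFrame({"subject_id": [f"s{i}" for i in range(n)],
                         "chronological_age": ages if ages is not None
                         else [10.2] * n,
                         "predicted_age": pred, "sex": [sex] * n})


class TestClassifyGapOutliers:
    def test_identical_predictions_all_average(self):
        out = classify_gap_outliers(_records([12.0] * 5))
        assert (out.group == "Average").all()

    def test_single_high_outlier(self):
        out = classify_gap_outliers(_records([10.0, 10.0, 10.0, 10.0, 20.0]))
        assert list(out.group) == ["Average"] * 4 + ["Older"]

    def test_order_invariance(self, rng):
        pred = rng.normal(12, 3, 40)
        base = _records(pred)
        shuffled = base.sample(frac=1.0, random_state=0)
        a = classify_gap_outliers(base).set_index("subject_id")["group"]
        b = classify_gap_outliers(shuffled).set_index("subject_id")["group"]
        assert a.sort_index().equals(b.sort_index())

    def test_small_stratum_warns_all_average(self):
        with pytest.warns(UserWarning, match="strata"):
            out = classify_gap_outliers(_records([5.0, 9.0]))
        assert (out.group == "Average").all()

    def test_gaussian_null_fraction_non_average(self, rng):
        pred = rng.normal(15, 2, 10_000)
        out = classify_gap_outliers(_records(pred))
        frac = (out.group != "Average").mean()
        expected = 2 * stats.norm.cdf(-1)      # ~ 0.3173
        assert abs(frac - expected) < 0.02

    def test_missing_values_rejected(self):
        df = _records([10.0, 11.0, 12.0])
        df.loc[1, "sex"] = np.nan
        with pytest.raises(ValueError):
            classify_gap_outliers(df)


class TestGroupCompare:
    def _table(self, rng, shift=0.0):
        rows = []
        for sex in (0, 1):
            for group, delta in (("Older", shift), ("Younger", 0.0),
                                 ("Average", 0.0)):
                for i in range(30):
                    rows.append({"sex": sex, "group": group,
                                 **{m: rng.normal(delta, 1.0)
                                    for m in VOLUMETRIC_MEASURES}})
        return pd.DataFrame(rows)

    def test_identical_groups_null(self, rng):
        df = self._table(rng)
        out = group_compare(df)
        assert len(out) == 16
        assert np.allclose(out.alpha_adj, 0.05 / 16)
        assert not out.significant.any()
        assert np.abs(out.cohens_d).max() < 0.6   # null-scale effects only

    def test_u_matches_exhaustive_enumeration(self, rng):
        for n1 in (2, 4, 8):
            for n2 in (3, 8):
                a = rng.integers(0, 6, n1).astype(float)   # include ties
                b = rng.integers(0, 6, n2).astype(float)
                U = stats.mannwhitneyu(a, b, alternative="two-sided")[0]
                assert U == pytest.approx(_u_oracle(a, b))

    def test_planted_shift_detected(self, rng):
        df = self._table(rng, shift=2.5)
        out = group_compare(df)
        hit = out[(out.group1 == "Older") & (out.group2 == "Average")]
        assert hit.significant.all()
        assert (hit.cohens_d > 1.5).all()

    def test_empty_group_reported_not_dropped(self, rng):
        df = self._table(rng)
        df = df[df.group != "Younger"]
        out = group_compare(df)
        younger = out[out.group1 == "Younger"]
        assert len(younger) == 8
        assert younger.U.isna().all()
        assert not younger.significant.any()


def test_cohens_d_agrees_with_pingouin(rng):
    pingouin = pytest.importorskip("pingouin")
    a, b = rng.normal(0.5, 1.2, 40), rng.normal(0.0, 0.9, 35)
    ours = cohens_d(a, b)
    ref = pingouin.compute_effsize(a, b, eftype="cohen")
    assert ours == pytest.approx(ref, abs=1e-10)


class TestCategorizeLongitudinal:
    def test_hand_built_rates(self):
        df = pd.DataFrame({
            "subject_id": ["a"] * 3, "age": [10.0, 12.0, 14.0],
            "predicted_age": [10.0, 12.0, 14.0],
            **{m: [100.0, 110.0, 126.0] for m in VOLUMETRIC_MEASURES}})
        subjects, _ = categorize_longitudinal(df)
        # per-interval rates [5, 8] -> mean 6.5
        assert subjects["WMV_rate"].iloc[0] == pytest.approx(6.5)

    def test_identical_rates_all_stable(self):
        rows = []
        for i in range(10):
            for v in range(3):
                rows.append({"subject_id": f"s{i}", "age": 10.0 + 2 * v,
                             "predicted_age": 10.0 + 2 * v,
                             **{m: 50.0 + 3.0 * v for m in VOLUMETRIC_MEASURES}})
        subjects, comps = categorize_longitudinal(pd.DataFrame(rows))
        assert (subjects.category == "Stable").all()
        assert comps.alpha_adj.iloc[0] == pytest.approx(0.05 / 8)

    def test_planted_acceleration_recovered_with_volumetric_associations(self):
        df = generate_longitudinal_cohort(300, seed=3, accelerated_fraction=0.12)
        subjects, comps = categorize_longitudinal(df)
        merged = subjects.merge(
            df.groupby("subject_id")["planted_category"].first(), on="subject_id")
        planted = merged[merged.planted_category == "Accelerated"]
        assert (planted.category == "Accelerated").mean() >= 0.9
        acc = comps[comps.comparison == "Stable-vs-Accelerated"]
        assert acc.significant.all()   # strong planted volumetric-rate coupling

    def test_single_visit_subject_rejected(self):
        df = pd.DataFrame({"subject_id": ["a"], "age": [10.0],
                           "predicted_age": [10.0],
                           **{m: [1.0] for m in VOLUMETRIC_MEASURES}})
        with pytest.raises(ValueError):
            categorize_longitudinal(df)


class TestCompareAgeModels:
    def test_exact_linear_dependence(self, rng):
        df = generate_volumetric_table(50, seed=0)
        y = (0.01 * df.WMV - 0.02 * df.GMV + 0.3 * df.sGMV + df.VV
             + 2.0 * df.sex + 5.0)
        out = compare_age_models(df, y, y)
        assert out["R2_chrono"] == pytest.approx(1.0, abs=1e-9)

    def test_independent_noise_near_zero(self, rng):
        df = generate_volumetric_table(334, seed=1)   # ~1000 rows
        noise = rng.normal(size=len(df))
        out = compare_age_models(df, noise, noise)
        assert out["R2_chrono"] < 0.02

    def test_matches_closed_form_r2(self, rng):
        df = generate_volumetric_table(40, seed=2)
        y = rng.normal(size=len(df))
        out = compare_age_models(df, y, df.age)
        X = np.column_stack([np.ones(len(df))]
                            + [df[m] for m in VOLUMETRIC_MEASURES] + [df.sex])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        ssr = np.sum((y - X @ beta) ** 2)
        sst = np.sum((y - y.mean()) ** 2)
        assert out["R2_chrono"] == pytest.approx(1 - ssr / sst, abs=1e-9)

    def test_too_few_rows_rejected(self):
        df = generate_volumetric_table(10, seed=0).head(5)
        with pytest.raises(ValueError):
            compare_age_models(df, df.age, df.age)


class TestAgeBiasCorrect:
    def test_zero_bias_recovers_near_zero_fit(self, rng):
        ages = rng.uniform(3, 30, 300)
        preds = ages + rng.normal(0, 0.5, 300)
        corrected, model = age_bias_correct(preds, ages, preds, ages)
        assert abs(model.slope) < 0.05
        assert abs(model.intercept) < 1.0

    def test_planted_slope_recovered(self, rng):
        ages = rng.uniform(3, 30, 500)
        preds = ages - 0.5 * (ages - 15.0) + rng.normal(0, 1.0, 500)
        fit_ages = rng.uniform(3, 30, 500)
        fit_preds = fit_ages - 0.5 * (fit_ages - 15.0) + rng.normal(0, 1.0, 500)
        _, model = age_bias_correct(preds, ages, fit_preds, fit_ages)
        assert model.slope == pytest.approx(-0.5, abs=0.05)

    def test_training_set_residual_mean_zero(self, rng):
        ages = rng.uniform(3, 30, 200)
        preds = ages + 0.3 * ages + rng.normal(0, 1, 200)
        corrected, _ = age_bias_correct(preds, ages, preds, ages)
        assert np.mean(corrected - ages) == pytest.approx(0.0, abs=1e-9)

    def test_constant_ages_rejected(self):
        with pytest.raises(ValueError):
            age_bias_correct([10.0] * 5, [10.0] * 5, [10.0] * 5, [10.0] * 5)
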