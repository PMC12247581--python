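"""Desk-scale end-to-end experiments on synthetic phantoms.

These runners wire the full pipeline together — phantom simulation,
preprocessing and slice selection, dual-guidance diffusion training per
slice percentile, reverse-diffusion prediction, and slice ensembling — at
sizes a single CPU handles in minutes (32^3 phantoms, 32x32 slices, T=100,
width-reduced encoders).  They are the basis of the package's
parameter-recovery and ensembling evaluations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .analysis import mae_iqr
from .ensemble import mean_ensemble, outlier_excluded_ensemble
from .model import ArchConfig, DualGuidanceRegressor, TrainingConfig, train
from .phantom import PhantomSpec, iter_cohort
from .preprocess import (DEFAULT_PERCENTILES, VolumeImage, extract_slice,
                         find_valid_slices, normalize_intensities,
                         select_percentile_slices)

__all__ = ["DeskProfile", "build_slice_dataset", "train_slice_model",
           "run_desk_experiment"]


@dataclass(frozen=True)
class DeskProfile:
    """Problem sizes and hyperparameters for the single-CPU profile."""

    n_train: int = 2000
    n_val: int = 200
    n_test: int = 200
    image_size: int = 32
    T: int = 100
    max_epochs: int = 10
    learning_rate: float = 3e-3
    batch_size: int = 64
    n_draws: int = 8
    percentiles: tuple[float, ...] = DEFAULT_PERCENTILES
    arch: ArchConfig = field(default_factory=ArchConfig)
    spec: PhantomSpec = field(default_factory=PhantomSpec)


def build_slice_dataset(n: int, seed: int, profile: DeskProfile):
    """Simulate ``n`` phantoms and return preprocessed percentile slices.

    Returns (slices, ages) where ``slices`` maps percentile -> (n, s, s)
    array.  Phantoms are preprocessed exactly as a real volume would be:
    intensity normalization, valid-slice detection, percentile selection.
    """
    size = profile.image_size
    slices = {p: np.empty((n, size, size)) for p in profile.percentiles}
    ages = np.empty(n)
    for i, (age, _sex, vol) in enumerate(iter_cohort(n, profile.spec, seed)):
        ages[i] = age
        vimg = normalize_intensities(VolumeImage(vol))
        valid = find_valid_slices(vimg)
        plan = select_percentile_slices(valid, profile.percentiles)
        for p, idx in zip(plan.percentiles, plan.selected_indices):
            slices[p][i] = extract_slice(vimg, idx, out_shape=(size, size))
    return slices, ages


def train_slice_model(train_data, val_data, seed: int,
                      profile: DeskProfile) -> DualGuidanceRegressor:
    """Train one percentile-slice model under the desk profile."""
    from .diffusion import build_schedule

    cfg = TrainingConfig(T=profile.T, learning_rate=profile.learning_rate,
                         batch_size=profile.batch_size,
                         max_epochs=profile.max_epochs,
                         seed=seed, age_bounds=profile.spec.age_range)
    model = DualGuidanceRegressor(profile.arch, cfg.age_bounds,
                                  build_schedule(cfg.T, cfg.beta_start, cfg.beta_end),
                                  seed=seed)
    train(model, train_data[0], train_data[1], val_data[0], val_data[1], cfg)
    return model


def run_desk_experiment(seed: int, profile: DeskProfile = DeskProfile(),
                        slice_percentiles: tuple[float, ...] | None = None) -> dict:
    """Full scaled-down study: train per-percentile models and evaluate.

    Trains one model per slice percentile on the training cohort, predicts
    the held-out test cohort per slice, and evaluates single-slice accuracy,
    the mean-predictor baseline, and the 5-slice outlier-excluded and plain
    mean ensembles.  All randomness derives from ``seed``.
    """
    percentiles = (profile.percentiles if slice_percentiles is None
                   else tuple(slice_percentiles))
    tr_slices, tr_ages = build_slice_dataset(profile.n_train, seed * 3 + 11, profile)
    va_slices, va_ages = build_slice_dataset(profile.n_val, seed * 3 + 12, profile)
    te_slices, te_ages = build_slice_dataset(profile.n_test, seed * 3 + 13, profile)

    per_slice_pred: dict[float, np.ndarray] = {}
    per_slice_mae: dict[float, float] = {}
    for j, p in enumerate(percentiles):
        model = train_slice_model((tr_slices[p], tr_ages), (va_slices[p], va_ages),
                                  seed * 100 + j, profile)
        pred = model.predict(te_slices[p], n_draws=profile.n_draws,
                             rng_seed=seed * 100 + 50 + j)
        per_slice_pred[p] = pred
        per_slice_mae[p] = mae_iqr(pred, te_ages)["MAE"]

    baseline = np.full_like(te_ages, tr_ages.mean())
    baseline_mae = mae_iqr(baseline, te_ages)["MAE"]
    median_p = 50.0 if 50.0 in per_slice_pred else percentiles[len(percentiles) // 2]
    median_pred = per_slice_pred[median_p]
    pearson_r = float(stats.pearsonr(median_pred, te_ages)[0])

    result = {
        "seed": seed,
        "test_ages": te_ages,
        "per_slice_pred": per_slice_pred,
        "per_slice_mae": per_slice_mae,
        "median_slice_mae": per_slice_mae[median_p],
        "baseline_mae": baseline_mae,
        "pearson_r": pearson_r,
    }
    if len(percentiles) >= 2:
        stacked = np.stack([per_slice_pred[p] for p in percentiles], axis=1)
        ens_out = np.array([outlier_excluded_ensemble(row).final_age for row in stacked])
        ens_mean = np.array([mean_ensemble(row).final_age for row in stacked])
        result["ensemble_outlier_mae"] = mae_iqr(ens_out, te_ages)["MAE"]
        result["ensemble_mean_mae"] = mae_iqr(ens_mean, te_ages)["MAE"]
        result["median_single_slice_mae"] = float(np.median(list(per_slice_mae.values())))
    return result
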