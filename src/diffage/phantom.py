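"""Synthetic phantoms and cohorts with known ground truth.

The image phantom encodes a scalar "age" geometrically in a nested-sphere
head model: a ventricle-like CSF core whose radius grows with age and a
cortical grey-matter band that thins with age, surrounding a white-matter
shell, all inside a fixed-radius "brain".  The mapping image -> age is thus
monotone and learnable at 32-64 voxel grids, analogous to ventricular
enlargement and cortical thinning over development.

Tabular generators emulate the statistical structure of volumetric
(WMV/GMV/sGMV/VV) cross-sections and short longitudinal series with planted,
recoverable effect sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "PhantomSpec", "SyntheticCohort", "generate_phantom", "generate_cohort",
    "generate_volumetric_table", "generate_longitudinal_cohort",
    "save_cohort_nifti", "VOLUMETRIC_MEASURES",
]

VOLUMETRIC_MEASURES = ("WMV", "GMV", "sGMV", "VV")


def _default_ventricle_radius(age: float) -> float:
    return 2.0 + 0.15 * (age - 3.0)


def _default_cortical_thickness(age: float) -> float:
    return 4.0 - 0.09 * (age - 3.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and noise model mapping age to a 3D phantom.

    Tissue intensities are T1w-like on a [0, 1] scale (CSF dark, WM bright);
    the outer brain radius is fixed so overall head size does not encode age.
    """

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    age_range: tuple[float, float] = (3.0, 30.0)
    ventricle_radius_fn: Callable[[float], float] = _default_ventricle_radius
    cortical_thickness_fn: Callable[[float], float] = _default_cortical_thickness
    brain_radius: float = 13.0
    tissue_intensities: Mapping[str, float] = field(default_factory=lambda: {
        "background": 0.0, "CSF": 0.25, "GM": 0.55, "WM": 0.9})
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if any(s < 16 for s in self.grid_shape):
            raise ValueError("grid_shape entries must be >= 16")
        if any(v < 0 for v in self.tissue_intensities.values()):
            raise ValueError("tissue intensities must be >= 0")
        ages = np.linspace(*self.age_range, 9)
        vr = [self.ventricle_radius_fn(a) for a in ages]
        ct = [self.cortical_thickness_fn(a) for a in ages]
        if not np.all(np.diff(vr) > 0):
            raise ValueError("ventricle_radius_fn must be strictly increasing")
        if not np.all(np.diff(ct) < 0):
            raise ValueError("cortical_thickness_fn must be strictly decreasing")


@dataclass(frozen=True)
class SyntheticCohort:
    volumes: list[np.ndarray]
    ages: np.ndarray
    sex: np.ndarray
    seed: int

    def __post_init__(self):
        if not (len(self.volumes) == len(self.ages) == len(self.sex)):
            raise ValueError("cohort fields must have equal length")


def _radius_grid(shape: tuple[int, int, int]) -> np.ndarray:
    axes = [np.arange(s) - (s - 1) / 2.0 for s in shape]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    return np.sqrt(zz ** 2 + yy ** 2 + xx ** 2)


def generate_phantom(age: float, spec: PhantomSpec, rng_seed: int) -> np.ndarray:
    """Render one 3D phantom volume for ``age``; deterministic per seed."""
    lo, hi = spec.age_range
    if not lo <= age <= hi:
        raise ValueError(f"age {age} outside spec.age_range {spec.age_range}")
    r = _radius_grid(spec.grid_shape)
    r_vent = spec.ventricle_radius_fn(age)
    thickness = spec.cortical_thickness_fn(age)
    r_wm = spec.brain_radius - thickness
    ti = spec.tissue_intensities
    vol = np.full(spec.grid_shape, ti["background"], dtype=np.float64)
    vol[r <= spec.brain_radius] = ti["GM"]
    vol[r <= r_wm] = ti["WM"]
    vol[r <= r_vent] = ti["CSF"]
    if spec.noise_sd > 0:
        rng = np.random.default_rng(rng_seed)
        vol = vol + rng.normal(0.0, spec.noise_sd, size=vol.shape)
        vol = np.clip(vol, 0.0, None)
    return vol


def generate_cohort(n: int, spec: PhantomSpec, seed: int) -> SyntheticCohort:
    """Cohort of phantoms with ages uniform over the spec age range."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    ages = rng.uniform(*spec.age_range, size=n)
    sex = rng.integers(0, 2, size=n)
    child_seeds = np.random.SeedSequence(seed).spawn(n)
    volumes = [generate_phantom(a, spec, s.generate_state(1)[0] % (2 ** 31))
               for a, s in zip(ages, child_seeds)]
    return SyntheticCohort(volumes=volumes, ages=ages, sex=sex, seed=seed)


def iter_cohort(n: int, spec: PhantomSpec, seed: int):
    """Stream (age, sex, volume) without holding all volumes in memory."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    ages = rng.uniform(*spec.age_range, size=n)
    sex = rng.integers(0, 2, size=n)
    child_seeds = np.random.SeedSequence(seed).spawn(n)
    for a, s, cs in zip(ages, sex, child_seeds):
        yield a, s, generate_phantom(a, spec, cs.generate_state(1)[0] % (2 ** 31))


def save_cohort_nifti(cohort: SyntheticCohort, out_dir) -> pd.DataFrame:
    """Write phantoms as 1 mm isotropic .nii.gz plus a metadata CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, vol in enumerate(cohort.volumes):
        path = out_dir / f"sub-{i:04d}.nii.gz"
        nib.save(nib.Nifti1Image(vol.astype(np.float32), affine=np.eye(4)), path)
        rows.append({"subject_id": f"sub-{i:04d}", "age": float(cohort.ages[i]),
                     "sex": int(cohort.sex[i]), "path": str(path)})
    meta = pd.DataFrame(rows)
    meta.to_csv(out_dir / "cohort.csv", index=False)
    return meta


# -- tabular generators -------------------------------------------------------

# Age trends and residual SDs per measure, loosely shaped on developmental
# volumetrics (GMV declines and VV grows over the simulated 5-25y range);
# units are arbitrary cm^3-like numbers, only trends and effect sizes matter.
_VOL_MODEL = {
    "WMV": (400.0, 8.0, 45.0),     # (intercept, slope per year, residual SD)
    "GMV": (760.0, -6.0, 55.0),
    "sGMV": (60.0, 0.4, 6.0),
    "VV": (12.0, 0.6, 4.0),
}
_GROUPS = ("Younger", "Average", "Older")


def generate_volumetric_table(n: int, effect=None, seed: int = 0,
                              age_range: tuple[float, float] = (5.0, 25.0)) -> pd.DataFrame:
    """Cross-sectional volumetric table with ``n`` subjects per planted group.

    ``effect`` maps measure -> {group -> Cohen's d} and plants a shift of
    ``d`` marginal standard deviations (residual plus age-trend spread) on
    that measure for that group, so pairwise group comparisons recover the
    planted standardized mean differences.
    """
    if n < 10:
        raise ValueError("need n >= 10 per group")
    effect = effect or {}
    rng = np.random.default_rng(seed)
    sd_age = (age_range[1] - age_range[0]) / np.sqrt(12.0)
    rows = []
    sid = 0
    for group in _GROUPS:
        ages = rng.uniform(*age_range, size=n)
        sexes = rng.integers(0, 2, size=n)
        cols = {}
        for measure, (b0, b1, sd) in _VOL_MODEL.items():
            sd_marginal = np.sqrt(sd ** 2 + (b1 * sd_age) ** 2)
            shift = effect.get(measure, {}).get(group, 0.0) * sd_marginal
            cols[measure] = b0 + b1 * ages + shift + rng.normal(0, sd, size=n)
        for i in range(n):
            rows.append({"subject_id": f"s{sid:05d}", "age": ages[i],
                         "sex": int(sexes[i]), "planted_group": group,
                         **{m: cols[m][i] for m in _VOL_MODEL}})
            sid += 1
    df = pd.DataFrame(rows)
    if df.isna().any().any():
        raise AssertionError("volumetric table contains missing cells")
    return df


# Longitudinal defaults: brain-age progresses ~1 y/y with between-subject
# slope SD 0.3; volumetric slopes follow the cross-sectional trends.  The
# accelerated/decelerated subgroups model a *common* pathological process:
# their slope mean shifts by shift_sd * slope SD while their residual
# between-subject slope spread shrinks to 0.25x (see docs/methods.md).
_LONG_SLOPES = {"WMV": 8.0, "GMV": -6.0, "sGMV": 0.4, "VV": 0.6}
_LONG_SLOPE_SD = {"WMV": 2.0, "GMV": 2.0, "sGMV": 0.3, "VV": 0.4}


def generate_longitudinal_cohort(n_subjects: int, n_visits: int = 3,
                                 interval: float = 2.0, seed: int = 0,
                                 baseline_age_range: tuple[float, float] = (8.0, 12.0),
                                 brainage_slope_sd: float = 0.3,
                                 value_noise_sd: float = 0.2,
                                 age_jitter_sd: float = 0.1,
                                 accelerated_fraction: float = 0.0,
                                 decelerated_fraction: float = 0.0,
                                 shift_sd: float = 2.0,
                                 subgroup_spread: float = 0.25,
                                 vol_slope_sd_scale: float = 1.0) -> pd.DataFrame:
    """Per-visit table of ages, predicted brain ages and volumetrics.

    Visit ages are baseline + k*interval with small jitter (strictly
    increasing).  Each subject has random volumetric and brain-age slopes;
    planted Accelerated/Decelerated subgroups shift the brain-age slope by
    ``+-shift_sd`` slope-SDs (with tighter within-subgroup spread) and move
    volumetric growth rates in the directions that accompany accelerated
    aging (faster VV growth, slower GMV/WMV/sGMV growth), and vice versa.
    """
    if n_visits < 2:
        raise ValueError("n_visits must be >= 2")
    if interval <= 0:
        raise ValueError("interval must be > 0")
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    n_acc = int(round(accelerated_fraction * n_subjects))
    n_dec = int(round(decelerated_fraction * n_subjects))
    labels = np.array(["Accelerated"] * n_acc + ["Decelerated"] * n_dec
                      + ["Stable"] * (n_subjects - n_acc - n_dec))
    rng.shuffle(labels)
    rows = []
    for i in range(n_subjects):
        label = labels[i]
        base_age = rng.uniform(*baseline_age_range)
        direction = {"Accelerated": 1.0, "Decelerated": -1.0, "Stable": 0.0}[label]
        spread = subgroup_spread if direction else 1.0
        ba_slope = (1.0 + direction * shift_sd * brainage_slope_sd
                    + rng.normal(0, spread * brainage_slope_sd))
        ba_intercept = base_age + rng.normal(0, 1.0)
        vol_slopes = {}
        vol_intercepts = {}
        for m in VOLUMETRIC_MEASURES:
            b0, b1, sd = _VOL_MODEL[m]
            sign = 1.0 if m == "VV" else -1.0
            slope_sd = vol_slope_sd_scale * _LONG_SLOPE_SD[m]
            vol_slopes[m] = (_LONG_SLOPES[m]
                             + direction * sign * shift_sd * slope_sd
                             + rng.normal(0, spread * slope_sd))
            vol_intercepts[m] = b0 + b1 * base_age + rng.normal(0, sd)
        ages = base_age + np.arange(n_visits) * interval
        if age_jitter_sd > 0:
            jitter = rng.normal(0, age_jitter_sd, size=n_visits)
            ages = np.sort(ages + jitter)
        for v in range(n_visits):
            dt = ages[v] - ages[0]
            row = {"subject_id": f"s{i:05d}", "visit": v, "age": ages[v],
                   "predicted_age": ba_intercept + ba_slope * dt
                   + rng.normal(0, value_noise_sd),
                   "planted_category": label}
            for m in VOLUMETRIC_MEASURES:
                row[m] = (vol_intercepts[m] + vol_slopes[m] * dt
                          + rng.normal(0, value_noise_sd * _LONG_SLOPE_SD[m]))
            rows.append(row)
    return pd.DataFrame(rows)
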