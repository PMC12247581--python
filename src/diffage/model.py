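"""Dual-guidance diffusion regression model for slice-based age prediction.

One model per axial slice percentile.  Architecture:

* an image encoder (residual CNN) producing the embedding rho(x);
* a global encoder + 1x1 convolution producing a saliency map whose mean is
  the global prior ``y_g``;
* a local encoder + gated attention over salient ROIs producing the local
  prior ``y_l``;
* a denoiser MLP taking ``[rho(x), y_t, y_g, y_l, t-embedding]`` and ending
  in a single-output fully connected layer that predicts the noise.

Training optimizes the noise-estimation loss plus condition-specific MMD
regularizers plus the MSE loss of the two priors against the true
(normalized) age; inference runs DDPM ancestral sampling conditioned on the
priors and averages several reverse chains.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .autograd import Tensor, concat
from .diffusion import (DiffusionSchedule, build_schedule, forward_noise,
                        normalize_age, denormalize_age, reverse_sample)
from .guidance import extract_rois, gated_attention_t
from .losses import LossBreakdown, mmd_t
from .nn import Adam, Conv2d, Linear, MLP, Module, ResNetEncoder, sinusoidal_embedding

__all__ = ["ArchConfig", "TrainingConfig", "DualGuidanceRegressor",
           "sample_prediction", "train"]


@dataclass(frozen=True)
class ArchConfig:
    """Network architecture; the defaults are the desk-scale profile."""

    image_size: int = 32
    encoder_widths: tuple[int, ...] = (8, 16)
    embed_dim: int = 32
    global_widths: tuple[int, ...] = (8, 16)
    local_widths: tuple[int, ...] = (8,)
    local_embed_dim: int = 16
    attention_dim: int = 16
    denoiser_hidden: tuple[int, ...] = (64, 64)
    time_embed_dim: int = 16
    k_rois: int = 4
    patch_size: int = 8
    stem_stride: int = 2
    local_stem_stride: int = 1


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization settings for one slice model."""

    T: int = 100
    learning_rate: float = 3e-3
    batch_size: int = 64
    max_epochs: int = 200
    patience: int = 50
    seed: int = 0
    age_bounds: tuple[float, float] = (3.0, 30.0)
    beta_start: float = 1e-4
    beta_end: float = 0.02
    dcg_loss_weight: float = 1.0

    def __post_init__(self):
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if not self.age_bounds[0] < self.age_bounds[1]:
            raise ValueError("age_bounds must satisfy min < max")


class _GatedAttention(Module):
    def __init__(self, d: int, d_att: int, rng: np.random.Generator):
        s = 1.0 / np.sqrt(d)
        self.V = Tensor(rng.normal(0, s, (d_att, d)), requires_grad=True)
        self.U = Tensor(rng.normal(0, s, (d_att, d)), requires_grad=True)
        self.w = Tensor(rng.normal(0, 1.0 / np.sqrt(d_att), d_att), requires_grad=True)


class DualGuidanceRegressor(Module):
    def __init__(self, arch: ArchConfig = ArchConfig(),
                 age_bounds: tuple[float, float] = (3.0, 30.0),
                 schedule: DiffusionSchedule | None = None, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.arch = arch
        self.age_bounds = tuple(age_bounds)
        self.schedule = schedule if schedule is not None else build_schedule(100)
        self.encoder = ResNetEncoder(arch.encoder_widths, arch.embed_dim, rng,
                                     stem_stride=arch.stem_stride)
        self.global_encoder = ResNetEncoder(arch.global_widths, arch.embed_dim, rng,
                                            stem_stride=arch.stem_stride)
        self.saliency_conv = Conv2d(arch.global_widths[-1], 1, 1, rng)
        self.local_encoder = ResNetEncoder(arch.local_widths, arch.local_embed_dim,
                                           rng, stem_stride=arch.local_stem_stride)
        self.attention = _GatedAttention(arch.local_embed_dim, arch.attention_dim, rng)
        self.local_head = Linear(arch.local_embed_dim, 1, rng)
        d_in = arch.embed_dim + 3 + arch.time_embed_dim
        self.denoiser = MLP((d_in, *arch.denoiser_hidden, 1), rng)

    # -- guidance -----------------------------------------------------------
    def priors(self, x: Tensor) -> tuple[Tensor, Tensor, np.ndarray]:
        """Batch global/local priors; returns (y_g, y_l, saliency maps)."""
        feats = self.global_encoder.feature_map(x)
        sal = self.saliency_conv(feats)                       # (B, h, w, 1)
        y_g = sal.mean(axis=(1, 2, 3))                        # (B,)
        patches = self._roi_patches(sal.data[..., 0], x.data[..., 0])
        b, k, p, _ = patches.shape
        h = self.local_encoder(Tensor(patches.reshape(b * k, p, p)[..., None]))
        h3 = h.reshape(b, k, self.arch.local_embed_dim)
        a = gated_attention_t(h3, self.attention.V, self.attention.U,
                              self.attention.w, axis=-1)       # (B, k)
        pooled = (h3 * a.reshape(b, k, 1)).sum(axis=1)         # (B, d)
        y_l = self.local_head(pooled).reshape(b)
        return y_g, y_l, sal.data[:, 0]

    def _roi_patches(self, sal_maps: np.ndarray, images: np.ndarray) -> np.ndarray:
        k, ps = self.arch.k_rois, self.arch.patch_size
        out = np.zeros((len(images), k, ps, ps))
        for i, (sal, img) in enumerate(zip(sal_maps, images)):
            rois = extract_rois(sal, img, k=k, patch_size=ps)
            for j in range(k):
                out[i, j] = rois[min(j, len(rois) - 1)].patch
        return out

    # -- denoiser -----------------------------------------------------------
    def predict_noise(self, rho: Tensor, y_t: np.ndarray, y_g: np.ndarray,
                      y_l: np.ndarray, t: np.ndarray) -> Tensor:
        """epsilon_hat(rho(x), y_t, y_g, y_l, t); one scalar per sample."""
        n = rho.shape[0]
        temb = sinusoidal_embedding(np.broadcast_to(np.asarray(t), (n,)),
                                    self.arch.time_embed_dim)
        cols = [rho,
                Tensor(np.broadcast_to(np.asarray(y_t, dtype=np.float64), (n,)).reshape(n, 1)),
                Tensor(np.broadcast_to(np.asarray(y_g, dtype=np.float64), (n,)).reshape(n, 1)),
                Tensor(np.broadcast_to(np.asarray(y_l, dtype=np.float64), (n,)).reshape(n, 1)),
                Tensor(temb)]
        return self.denoiser(concat(cols, axis=1)).reshape(n)

    # -- inference ----------------------------------------------------------
    def conditioning(self, images: np.ndarray):
        """Embedding and detached priors for a stack of slices (n, s, s)."""
        x = Tensor(np.asarray(images, dtype=np.float64)[..., None])
        rho = self.encoder(x).detach()
        y_g, y_l, _ = self.priors(x)
        return rho.data, y_g.data, y_l.data

    def predict(self, images: np.ndarray, n_draws: int = 8,
                rng_seed: int | None = 0) -> np.ndarray:
        """Predicted age in years for a stack of 2D slices."""
        images = np.asarray(images, dtype=np.float64)
        if images.ndim == 2:
            images = images[None]
        rho, y_g, y_l = self.conditioning(images)
        return sample_prediction(self, rho, y_g, y_l, self.schedule,
                                 n_draws=n_draws, rng_seed=rng_seed)

    # -- persistence --------------------------------------------------------
    def save(self, path) -> None:
        meta = {"arch": asdict(self.arch), "age_bounds": list(self.age_bounds),
                "T": int(self.schedule.T),
                "beta_start": float(self.schedule.beta[0]),
                "beta_end": float(self.schedule.beta[-1])}
        arrays = {f"p{i}": a for i, a in enumerate(self.state_dict())}
        np.savez(path, meta=np.array(json.dumps(meta)), **arrays)

    @classmethod
    def load(cls, path) -> "DualGuidanceRegressor":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            arrays = [z[f"p{i}"] for i in range(len(z.files) - 1)]
        arch_d = meta["arch"]
        for key in ("encoder_widths", "global_widths", "local_widths",
                    "denoiser_hidden"):
            arch_d[key] = tuple(arch_d[key])
        model = cls(ArchConfig(**arch_d), tuple(meta["age_bounds"]),
                    build_schedule(meta["T"], meta["beta_start"], meta["beta_end"]))
        model.load_state_dict(arrays)
        return model


def sample_prediction(model: DualGuidanceRegressor, rho_x: np.ndarray,
                      y_g: np.ndarray, y_l: np.ndarray,
                      schedule: DiffusionSchedule, n_draws: int = 8,
                      rng_seed: int | None = 0, inject_noise: bool = True,
                      y_T: np.ndarray | None = None) -> np.ndarray:
    """Average ``n_draws`` reverse chains per image and denormalize to years.

    ``rho_x``, ``y_g``, ``y_l`` are precomputed conditioning for n images;
    a seed is mandatory whenever the sampler draws randomness.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if rng_seed is None and (inject_noise or y_T is None):
        raise ValueError("sampling randomness requires rng_seed")
    rho_x = np.atleast_2d(np.asarray(rho_x, dtype=np.float64))
    n = rho_x.shape[0]
    y_g = np.broadcast_to(np.asarray(y_g, dtype=np.float64), (n,))
    y_l = np.broadcast_to(np.asarray(y_l, dtype=np.float64), (n,))
    rng = None if rng_seed is None else np.random.default_rng(rng_seed)

    # chains laid out as (n_draws, n) flattened; conditioning tiled to match
    rho_t = Tensor(np.tile(rho_x, (n_draws, 1)))
    yg_t = np.tile(y_g, n_draws)
    yl_t = np.tile(y_l, n_draws)

    def eps_fn(y, t):
        return model.predict_noise(rho_t, y, yg_t, yl_t, t).data

    y0 = reverse_sample(eps_fn, schedule, n_chains=n * n_draws, rng=rng,
                        inject_noise=inject_noise,
                        y_T=None if y_T is None else np.tile(np.asarray(y_T), n_draws))
    y0 = y0.reshape(n_draws, n).mean(axis=0)
    return denormalize_age(np.clip(y0, -1.0, 1.0), model.age_bounds)


@dataclass
class TrainResult:
    model: DualGuidanceRegressor
    history: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_val_loss: float = np.inf


def _epoch_loss(model: DualGuidanceRegressor, images, y0, t, eps, ref,
                dcg_weight: float, backprop: bool) -> tuple[Tensor, LossBreakdown, float]:
    x = Tensor(images[..., None])
    y_g, y_l, _ = model.priors(x)
    dcg = ((y_g - Tensor(y0)) ** 2 + (y_l - Tensor(y0)) ** 2).mean()
    rho = model.encoder(x)
    y_t = forward_noise(y0, t, eps, model.schedule)
    yg_d, yl_d = y_g.data, y_l.data
    eps_full = model.predict_noise(rho, y_t, yg_d, yl_d, t)
    eps_g = model.predict_noise(rho, y_t, yg_d, np.zeros_like(yl_d), t)
    eps_l = model.predict_noise(rho, y_t, np.zeros_like(yg_d), yl_d, t)
    L_e = ((Tensor(eps) - eps_full) ** 2).mean()
    L_g = mmd_t(eps_g, ref)
    L_l = mmd_t(eps_l, ref)
    loss = L_e + (L_g + L_l) * 0.5 + dcg * dcg_weight
    parts = LossBreakdown(float(L_e.data), float(max(L_g.data, 0.0)),
                          float(max(L_l.data, 0.0)))
    return loss, parts, float(dcg.data)


def train(model: DualGuidanceRegressor, train_slices: np.ndarray,
          train_ages: np.ndarray, val_slices: np.ndarray, val_ages: np.ndarray,
          config: TrainingConfig, verbose: bool = False) -> TrainResult:
    """Train one slice model with early stopping on the validation objective.

    Per step, timesteps are drawn uniformly from [1, T] and fresh Gaussian
    noise and MMD reference draws are taken from the training RNG stream.
    The validation objective reuses one fixed draw of (t, eps, reference) so
    epochs are comparable; the best-validation parameters are restored on
    return.  Raises on non-finite loss.
    """
    train_slices = np.asarray(train_slices, dtype=np.float64)
    val_slices = np.asarray(val_slices, dtype=np.float64)
    if len(train_slices) < 2 or len(val_slices) < 1:
        raise ValueError("need >= 2 training and >= 1 validation examples")
    rng = np.random.default_rng(config.seed)
    y_train = normalize_age(np.asarray(train_ages, dtype=np.float64), config.age_bounds)
    y_val = normalize_age(np.asarray(val_ages, dtype=np.float64), config.age_bounds)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    n = len(train_slices)
    T = model.schedule.T

    val_t = rng.integers(1, T + 1, size=len(val_slices))
    val_eps = rng.standard_normal(len(val_slices))
    val_ref = rng.standard_normal(len(val_slices))

    result = TrainResult(model=model)
    best_state = model.state_dict()
    stale = 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        tr_parts = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            if len(idx) < 2:
                continue
            t = rng.integers(1, T + 1, size=len(idx))
            eps = rng.standard_normal(len(idx))
            ref = rng.standard_normal(len(idx))
            loss, parts, _ = _epoch_loss(model, train_slices[idx], y_train[idx],
                                         t, eps, ref, config.dcg_loss_weight, True)
            if not np.isfinite(loss.data):
                raise RuntimeError(f"non-finite training loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            tr_parts.append((float(loss.data), parts))

        val_loss_t, val_parts, val_dcg = _epoch_loss(
            model, val_slices, y_val, val_t, val_eps, val_ref,
            config.dcg_loss_weight, False)
        val_loss = float(val_loss_t.data)
        if not np.isfinite(val_loss):
            raise RuntimeError(f"non-finite validation loss at epoch {epoch}")
        mean_train = float(np.mean([p[0] for p in tr_parts]))
        result.history.append({
            "epoch": epoch, "train_loss": mean_train, "val_loss": val_loss,
            "val_L_e": val_parts.L_e, "val_L_mmd_g": val_parts.L_mmd_g,
            "val_L_mmd_l": val_parts.L_mmd_l, "val_dcg": val_dcg})
        if verbose:
            print(f"epoch {epoch}: train {mean_train:.4f} val {val_loss:.4f}")
        if val_loss < result.best_val_loss - 1e-12:
            result.best_val_loss = val_loss
            result.best_epoch = epoch
            best_state = model.state_dict()
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    model.load_state_dict(best_state)
    return result
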