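"""Dual-granularity conditional guidance (DCG).

Two auxiliary predictions condition every diffusion step:

* the **global prior** ``y_g`` — a saliency map is produced from the whole
  slice by the global encoder followed by a 1x1 convolution, and its mean
  response is the prior;
* the **local prior** ``y_l`` — the top-k salient, non-overlapping locations
  are mapped back to image patches (ROIs), encoded by the local encoder,
  pooled by gated attention and passed through a linear head.

Both priors are trained against the normalized true age with an MSE loss.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .autograd import Tensor
from .nn import Linear, ResNetEncoder

__all__ = [
    "ROI", "compute_saliency", "global_prior", "extract_rois",
    "gated_attention", "local_prior", "dcg_loss", "gated_attention_t",
]


@dataclass(frozen=True)
class ROI:
    """A salient image patch: center (row, col) in image coordinates."""

    row: int
    col: int
    patch: np.ndarray


def compute_saliency(slice_image: np.ndarray, global_encoder: ResNetEncoder,
                     saliency_conv) -> np.ndarray:
    """Saliency map of one 2D slice: encoder feature grid -> 1x1 conv."""
    img = np.asarray(slice_image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a 2D slice")
    min_size = 2 ** len(global_encoder.blocks)
    if min(img.shape) < min_size:
        raise ValueError(f"slice smaller than encoder minimum size {min_size}")
    x = Tensor(img[None, :, :, None])
    feats = global_encoder.feature_map(x)
    sal = saliency_conv(feats)
    return sal.data[0, ..., 0]


def global_prior(saliency: np.ndarray) -> float:
    """Arithmetic mean of all saliency responses."""
    saliency = np.asarray(saliency, dtype=np.float64)
    if saliency.size == 0:
        raise ValueError("empty saliency map")
    return float(saliency.mean())


def extract_rois(saliency: np.ndarray, slice_image: np.ndarray, k: int = 4,
                 patch_size: int = 8) -> list[ROI]:
    """Greedy top-k salient locations with non-max suppression.

    Saliency grid locations are mapped to image coordinates by the grid ->
    image scale factor; locations closer (Chebyshev distance) than
    ``patch_size / 2`` in image coordinates to an already-selected ROI are
    suppressed.  Ties in saliency break in row-major scan order.  Patches are
    zero-padded at the image border.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    sal = np.asarray(saliency, dtype=np.float64)
    img = np.asarray(slice_image, dtype=np.float64)
    scale = (img.shape[0] / sal.shape[0], img.shape[1] / sal.shape[1])
    # row-major stable order on descending saliency
    flat = sal.ravel()
    order = np.argsort(-flat, kind="stable")
    radius = patch_size / 2.0
    centers: list[tuple[float, float]] = []
    rois: list[ROI] = []
    for idx in order:
        if len(rois) == k:
            break
        r, c = divmod(int(idx), sal.shape[1])
        ir = (r + 0.5) * scale[0]
        ic = (c + 0.5) * scale[1]
        if any(max(abs(ir - pr), abs(ic - pc)) < radius for pr, pc in centers):
            continue
        centers.append((ir, ic))
        rois.append(ROI(row=int(ir), col=int(ic),
                        patch=_crop_patch(img, int(ir), int(ic), patch_size)))
    if len(rois) < k:
        warnings.warn(f"only {len(rois)} ROIs available after suppression "
                      f"(requested {k})", stacklevel=2)
    return rois


def _crop_patch(img: np.ndarray, row: int, col: int, size: int) -> np.ndarray:
    half = size // 2
    patch = np.zeros((size, size))
    r0, c0 = row - half, col - half
    rs, cs = max(r0, 0), max(c0, 0)
    re, ce = min(r0 + size, img.shape[0]), min(c0 + size, img.shape[1])
    patch[rs - r0:re - r0, cs - c0:ce - c0] = img[rs:re, cs:ce]
    return patch


def gated_attention(features, V: np.ndarray, U: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Gated attention pooling weights.

    ``a_k = softmax_k( w^T (tanh(V h_k) * sigmoid(U h_k)) )`` over the
    instance features ``h_k``.  Weights are non-negative and sum to 1.
    """
    H = np.asarray(features, dtype=np.float64)
    if H.ndim != 2 or len(H) < 1:
        raise ValueError("expected a non-empty (k, d) feature matrix")
    if V.shape[1] != H.shape[1] or U.shape[1] != H.shape[1]:
        raise ValueError("attention parameter dimension mismatch")
    gate = np.tanh(H @ V.T) * (1.0 / (1.0 + np.exp(-(H @ U.T))))
    scores = gate @ w
    scores = scores - scores.max()
    e = np.exp(scores)
    return e / e.sum()


def gated_attention_t(H: Tensor, V: Tensor, U: Tensor, w: Tensor, axis: int = -1) -> Tensor:
    """Differentiable gated attention scores softmaxed along ``axis``.

    ``H`` is (..., k, d); returns weights of shape (..., k).
    """
    gate = (H @ V.transpose()).tanh() * (H @ U.transpose()).sigmoid()
    scores = (gate * w).sum(axis=-1)
    return scores.softmax(axis=axis)


def local_prior(rois: list[ROI], local_encoder: ResNetEncoder,
                attention: "object", head: Linear,
                fallback_y_g: float | None = None) -> float:
    """Attention-pooled ROI features through a linear head.

    With no ROIs the global prior is returned instead (with a warning).
    ``attention`` must expose Tensor parameters ``V``, ``U``, ``w``.
    """
    if not rois:
        warnings.warn("no ROIs; local prior falls back to global prior", stacklevel=2)
        if fallback_y_g is None:
            raise ValueError("empty ROI list and no fallback global prior")
        return float(fallback_y_g)
    patches = np.stack([r.patch for r in rois])[..., None]     # (k, p, p, 1)
    feats = local_encoder(Tensor(patches))                      # (k, d)
    weights = gated_attention(feats.data, attention.V.data, attention.U.data,
                              attention.w.data)
    pooled = weights @ feats.data                               # (d,)
    return float(head(Tensor(pooled[None])).data[0, 0])


def dcg_loss(y_g, y_l, y_true) -> float:
    """MSE of both priors against the normalized true age, batch-averaged."""
    y_g = np.atleast_1d(np.asarray(y_g, dtype=np.float64))
    y_l = np.atleast_1d(np.asarray(y_l, dtype=np.float64))
    y = np.atleast_1d(np.asarray(y_true, dtype=np.float64))
    if not (np.all(np.isfinite(y_g)) and np.all(np.isfinite(y_l)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite inputs to dcg_loss")
    return float(((y_g - y) ** 2 + (y_l - y) ** 2).mean())
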