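"""Soft Dice loss, planar projections, and the multi-task training objective.

The training objective combines a volumetric overlap term with silhouette
terms in the three anatomical planes:

    L = alpha * DL_vol + beta * (DL_axial + DL_coronal + DL_sagittal)

where every ``DL`` is a soft Dice loss and the planar maps are maximum
projections of the probability volume along one axis.  The projection terms
penalise breaks in the projected silhouette of the canal, which is how the
objective encodes global structural continuity.

All functions accept either numpy arrays or :class:`canalnet.nn.Tensor`
values; handing in tensors keeps the computation differentiable for
training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor, as_tensor

DEFAULT_SMOOTH = 1e-6


@dataclass(frozen=True)
class LossWeights:
    """Weights of the volumetric (alpha) and summed planar (beta) Dice terms."""

    alpha: float = 0.7
    beta: float = 0.3

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("loss weights must be nonnegative")


def _check_pair(pred, truth):
    p = pred.data if isinstance(pred, Tensor) else np.asarray(pred, dtype=float)
    t = truth.data if isinstance(truth, Tensor) else np.asarray(truth, dtype=float)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: prediction {p.shape} vs truth {t.shape}")


def soft_dice_loss(pred, truth, smooth: float = DEFAULT_SMOOTH) -> Tensor:
    """1 - (2*sum(p*t) + s) / (sum(p) + sum(t) + s); zero iff pred == truth."""
    if smooth < 0:
        raise ValueError("smoothing constant must be nonnegative")
    _check_pair(pred, truth)
    pred = as_tensor(pred)
    truth = as_tensor(truth)
    inter = (pred * truth).sum()
    denom = pred.sum() + truth.sum() + smooth
    return 1.0 - (2.0 * inter + smooth) / denom


def project(volume, axis: int, mode: str = "max"):
    """Project a probability volume to 2D along one axis.

    ``max`` (the default) is the silhouette operator — differentiable almost
    everywhere and [0,1]-preserving; ``mean`` is a softer alternative.
    """
    if axis not in (0, 1, 2):
        raise ValueError("axis must be 0, 1 or 2")
    if isinstance(volume, Tensor):
        if volume.ndim != 3:
            raise ValueError("projection expects a 3D volume")
        if mode == "max":
            return nn.amax(volume, axis)
        if mode == "mean":
            return _mean_tensor(volume, axis)
        raise ValueError(f"unknown projection mode {mode!r}")
    vol = np.asarray(volume, dtype=float)
    if vol.ndim != 3:
        raise ValueError("projection expects a 3D volume")
    if mode == "max":
        return vol.max(axis=axis)
    if mode == "mean":
        return vol.mean(axis=axis)
    raise ValueError(f"unknown projection mode {mode!r}")


def _mean_tensor(volume: Tensor, axis: int) -> Tensor:
    m = nn.mean_axes(volume, (axis,))
    # drop the kept axis to return a true 2D map
    out = Tensor(np.squeeze(m.data, axis=axis), parents=(m,))

    def bwd(g):
        if m.requires_grad:
            m._accum(np.expand_dims(g, axis))

    out._backward = bwd
    return out


def total_loss(pred, truth, weights: LossWeights = LossWeights(),
               smooth: float = DEFAULT_SMOOTH,
               projection_mode: str = "max") -> tuple[Tensor, dict[str, float]]:
    """Multi-task loss and its per-term breakdown.

    Returns the (differentiable) total together with a dict of the four
    component values: the volumetric Dice loss and the axial / coronal /
    sagittal projection Dice losses.
    """
    _check_pair(pred, truth)
    truth_arr = truth.data if isinstance(truth, Tensor) else np.asarray(truth, dtype=float)
    dl_vol = soft_dice_loss(pred, truth_arr, smooth)
    planes = {}
    planar_sum = None
    for name, axis in (("axial", 0), ("coronal", 1), ("sagittal", 2)):
        term = soft_dice_loss(project(pred, axis, projection_mode),
                              project(truth_arr, axis, projection_mode), smooth)
        planes[name] = term
        planar_sum = term if planar_sum is None else planar_sum + term
    total = weights.alpha * dl_vol + weights.beta * planar_sum
    breakdown = {
        "volume": dl_vol.item(),
        "axial": planes["axial"].item(),
        "coronal": planes["coronal"].item(),
        "sagittal": planes["sagittal"].item(),
    }
    return total, breakdown
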