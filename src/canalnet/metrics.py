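"""Segmentation evaluation: overlap metrics, curve distance, slice profiles.

Seven scalar metrics are computed between a binarised prediction and the
ground truth:

* overlap — DSC = 2TP/(2TP+FP+FN), JI = TP/(TP+FP+FN), PR = TP/(TP+FP),
  RC = TP/(TP+FN);
* volumetric — VOE = 1 - |gt ∩ pred| / |gt ∪ pred|, RVD = |V_gt - V_pred| / V_gt;
* geometric — MCD, the mean distance (mm) from each ground-truth centerline
  voxel to the nearest predicted centerline voxel, where centerlines come
  from 3D morphological thinning (skeletonization).

MCD is deliberately asymmetric: it asks "how far is the true canal course
from the predicted one", so a prediction that covers the whole true course
scores 0 even if it extends further.  Per-slice DSC/MCD profiles expose
where along the canal (from one foramen to the other) a model loses the
structure.

Conventions: probability maps are binarised at 0.5; when both masks are
empty the overlap metrics are 1 and VOE is 0 (identity of empties); an empty
prediction makes MCD infinite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from skimage.morphology import skeletonize

from .phantom import BinaryMask

DEFAULT_THRESHOLD = 0.5


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int | None = None


@dataclass(frozen=True)
class CenterCurve:
    """Skeleton voxel coordinates of a mask, with their grid spacing."""

    points: np.ndarray  # (N, 3) integer voxel coordinates
    spacing_mm: float


@dataclass(frozen=True)
class MetricsReport:
    dsc: float
    ji: float
    pr: float
    rc: float
    voe: float
    rvd: float
    mcd_mm: float

    COLUMNS = ("dsc", "ji", "pr", "rc", "rvd", "voe", "mcd_mm")

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in self.COLUMNS}


def _as_bool(mask) -> np.ndarray:
    if isinstance(mask, BinaryMask):
        return mask.values
    return np.asarray(mask).astype(bool)


def _spacing(mask, default: float = 1.0) -> float:
    return mask.spacing_mm if isinstance(mask, BinaryMask) else default


def binarize(prob, threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Threshold a probability volume into a boolean mask."""
    return np.asarray(prob) >= threshold


def confusion(pred, truth) -> ConfusionCounts:
    p, t = _as_bool(pred), _as_bool(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(p.size - tp - fp - fn)
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def overlap_metrics(c: ConfusionCounts) -> tuple[float, float, float, float]:
    """(DSC, JI, PR, RC); both-empty pairs score 1 by convention."""
    if min(c.tp, c.fp, c.fn) < 0:
        raise ValueError("confusion counts must be nonnegative")
    if c.tp == 0 and c.fp == 0 and c.fn == 0:
        return 1.0, 1.0, 1.0, 1.0
    dsc = 2 * c.tp / (2 * c.tp + c.fn + c.fp)
    ji = c.tp / (c.tp + c.fn + c.fp)
    pr = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else 0.0
    rc = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    return dsc, ji, pr, rc


def volume_metrics(pred, truth) -> tuple[float, float]:
    """(VOE, RVD) from voxel counts; RVD needs a nonempty ground truth."""
    p, t = _as_bool(pred), _as_bool(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    v_pred = int(np.count_nonzero(p))
    v_gt = int(np.count_nonzero(t))
    union = int(np.count_nonzero(p | t))
    inter = int(np.count_nonzero(p & t))
    voe = 0.0 if union == 0 else 1.0 - inter / union
    if v_gt == 0:
        raise ValueError("RVD is undefined for an empty ground truth")
    rvd = abs(v_gt - v_pred) / v_gt
    return voe, rvd


def centerline(mask) -> CenterCurve:
    """Extract the center curve of a mask by 3D morphological thinning."""
    m = _as_bool(mask)
    if not m.any():
        raise ValueError("cannot skeletonize an empty mask")
    skel = skeletonize(m)
    pts = np.argwhere(skel)
    if len(pts) == 0:  # thinning degenerately removed everything; keep 1 voxel
        pts = np.argwhere(m)[:1]
    return CenterCurve(points=pts, spacing_mm=_spacing(mask))


def mean_curve_distance(truth, pred, squared: bool = False) -> float:
    """Mean distance (mm) from truth-skeleton voxels to the pred skeleton.

    ``squared=True`` averages squared distances instead of Euclidean ones
    (an alternative literal reading of the distance kernel); the default is
    the Euclidean form, which carries millimetre units.
    """
    t_curve = centerline(truth)
    p_mask = _as_bool(pred)
    if not p_mask.any():
        return float("inf")
    p_curve = centerline(pred)
    spacing = t_curve.spacing_mm
    d, _ = cKDTree(p_curve.points * spacing).query(t_curve.points * spacing,
                                                   workers=-1)
    return float(np.mean(d ** 2) if squared else np.mean(d))


def evaluate_pair(pred, truth, threshold: float = DEFAULT_THRESHOLD) -> MetricsReport:
    """All seven metrics for one (prediction, truth) pair.

    ``pred`` may be a probability volume (binarised at ``threshold``), a
    boolean array, or a BinaryMask.
    """
    t = _as_bool(truth)
    if isinstance(pred, BinaryMask) or (hasattr(pred, "dtype") and
                                        np.asarray(pred).dtype == bool):
        p = _as_bool(pred)
        p_mask = BinaryMask(p, _spacing(pred, _spacing(truth)))
    else:
        p = binarize(pred, threshold)
        p_mask = BinaryMask(p, _spacing(truth))
    t_mask = truth if isinstance(truth, BinaryMask) else BinaryMask(t)
    c = confusion(p, t)
    dsc, ji, pr, rc = overlap_metrics(c)
    voe, rvd = volume_metrics(p, t)
    mcd = mean_curve_distance(t_mask, p_mask) if p.any() else float("inf")
    return MetricsReport(dsc=dsc, ji=ji, pr=pr, rc=rc, voe=voe, rvd=rvd,
                         mcd_mm=mcd)


def slice_profiles(pred, truth) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Along-canal per-slice (indices, DSC, MCD-mm) profiles.

    For every slice along axis 0 where the ground truth is nonempty, the 2D
    DSC of that slice pair and the mean distance from truth-skeleton voxels
    in the slice to the full predicted skeleton.  Slices where the prediction
    has no skeleton support report DSC accordingly and an infinite distance.
    """
    p, t = _as_bool(pred), _as_bool(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    spacing = _spacing(truth)
    occupied = np.flatnonzero(t.reshape(t.shape[0], -1).any(axis=1))
    t_skel = centerline(truth).points
    p_tree = None
    if p.any():
        p_tree = cKDTree(centerline(pred).points * spacing)
    dscs, mcds = [], []
    for z in occupied:
        c = confusion(p[z], t[z])
        dscs.append(overlap_metrics(c)[0] if (c.tp + c.fp + c.fn) else 1.0)
        pts = t_skel[t_skel[:, 0] == z]
        if len(pts) == 0:
            mcds.append(float("nan"))  # skeleton does not visit this slice
        elif p_tree is None:
            mcds.append(float("inf"))
        else:
            d, _ = p_tree.query(pts * spacing)
            mcds.append(float(np.mean(d)))
    return occupied, np.asarray(dscs), np.asarray(mcds)
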