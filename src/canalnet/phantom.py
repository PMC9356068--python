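"""Synthetic curved-tube phantoms emulating the mandibular canal in CBCT.

The mandibular canal appears in cone-beam CT as a dark lumen wrapped in a
bright cortical-bone rim on a noisy trabecular background, with stretches
where the rim all but disappears ("low visibility") and occasional bright
streaks from metal restorations.  This module renders a minimal analog of
that appearance: a smooth curved tube with a configurable rim, rim-gap
segments, Gaussian noise, and additive streak artifacts — together with the
exact ground-truth mask (canal *including* the cortical rim, matching the
annotation convention the evaluation assumes).  Everything is deterministic
given ``PhantomSpec.seed``.

Axis convention: axis 0 is the canal/slice axis (the "temporal" axis of the
recurrent network), axes 1-2 are in-plane rows/cols.  Intensities are
abstract floats, not Hounsfield units.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.spatial import cKDTree


class GeometryError(ValueError):
    """Raised when a phantom's tube or centerline leaves the volume."""


@dataclass(frozen=True)
class IntensityVolume:
    """A 3D scalar grid with isotropic voxel spacing in millimetres."""

    values: np.ndarray
    spacing_mm: float = 0.2

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 3 or min(v.shape) < 1:
            raise ValueError("volume must be 3D with all dimensions >= 1")
        if not np.isfinite(v).all():
            raise ValueError("volume contains non-finite values")
        if self.spacing_mm <= 0:
            raise ValueError("spacing must be strictly positive")
        object.__setattr__(self, "values", v)

    @property
    def shape(self):
        return self.values.shape


@dataclass(frozen=True)
class BinaryMask:
    """A boolean grid sharing geometry with its paired IntensityVolume."""

    values: np.ndarray
    spacing_mm: float = 0.2

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.dtype != bool:
            if not np.isin(v, (0, 1)).all():
                raise ValueError("mask values must be boolean or 0/1")
            v = v.astype(bool)
        if v.ndim != 3 or min(v.shape) < 1:
            raise ValueError("mask must be 3D with all dimensions >= 1")
        if self.spacing_mm <= 0:
            raise ValueError("spacing must be strictly positive")
        object.__setattr__(self, "values", v)

    @property
    def shape(self):
        return self.values.shape


@dataclass(frozen=True)
class PhantomSpec:
    """Full parameterisation of one synthetic canal phantom.

    ``gap_segments`` are (start_fraction, end_fraction, rim_attenuation)
    triples along the arc length of the centerline; attenuation 1 fades the
    cortical rim completely into the background, emulating the low-visibility
    stretches that make real canals hard to follow.
    """

    shape: tuple[int, int, int] = (16, 32, 32)
    spacing_mm: float = 0.2
    centerline_control_points: tuple = ((0.0, 16.0, 10.0),
                                        (7.5, 13.0, 16.0),
                                        (15.0, 16.0, 22.0))
    tube_radius_vox: float = 2.0
    rim_thickness_vox: float = 1.5
    lumen_intensity: float = 0.15
    rim_intensity: float = 0.75
    background_intensity: float = 0.35
    noise_sigma: float = 0.05
    gap_segments: tuple = ()
    streak_count: int = 0
    seed: int = 0

    def __post_init__(self):
        if len(self.shape) != 3 or min(self.shape) < 1:
            raise ValueError("shape must be a positive voxel triple")
        if self.spacing_mm <= 0:
            raise ValueError("spacing must be positive")
        pts = np.asarray(self.centerline_control_points, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 3:
            raise ValueError("need at least two 3D control points")
        for ax in range(3):
            if (pts[:, ax] < 0).any() or (pts[:, ax] > self.shape[ax] - 1).any():
                raise GeometryError("control points must lie inside the volume")
        if np.any(np.diff(pts[:, 0]) <= 0):
            raise GeometryError(
                "control points must be strictly increasing along axis 0 "
                "(the centerline is single-valued per slice)")
        if self.tube_radius_vox < 1 or self.rim_thickness_vox < 1:
            raise ValueError("tube radius and rim thickness must be >= 1 voxel")
        if not (self.rim_intensity > self.background_intensity > self.lumen_intensity):
            raise ValueError("intensities must satisfy rim > background > lumen")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be nonnegative")
        for seg in self.gap_segments:
            s, e, a = seg
            if not (0 <= s < e <= 1):
                raise ValueError("gap segment must satisfy 0 <= start < end <= 1")
            if not (0 <= a <= 1):
                raise ValueError("rim attenuation must lie in [0, 1]")
        if self.streak_count < 0:
            raise ValueError("streak count must be nonnegative")
        object.__setattr__(self, "centerline_control_points",
                           tuple(map(tuple, pts)))


# ---------------------------------------------------------------------------
# Centerline
# ---------------------------------------------------------------------------

def sample_centerline(spec: PhantomSpec) -> np.ndarray:
    """Discretise the phantom centerline at <= 1-voxel arc-length steps.

    A natural cubic spline is fit through the control points with the slice
    coordinate as the parameter, so the curve is single-valued (monotone) in
    axis 0; it is then resampled uniformly in arc length.  For a straight
    axis-aligned segment this degenerates to exactly one point per slice.
    """
    pts = np.asarray(spec.centerline_control_points, dtype=np.float64)
    z = pts[:, 0]
    if len(pts) == 2:
        # two points define a straight segment; CubicSpline would also give a
        # line but the explicit form keeps the endpoints exact
        def curve(zq):
            w = (zq - z[0]) / (z[-1] - z[0])
            return pts[0] + w[:, None] * (pts[1] - pts[0])
    else:
        cs = CubicSpline(z, pts[:, 1:], bc_type="natural")

        def curve(zq):
            rc = cs(zq)
            return np.column_stack([zq, rc])

    # dense parameter sweep -> cumulative arc length -> uniform resampling
    zfine = np.linspace(z[0], z[-1], max(64, 16 * len(np.arange(z[0], z[-1] + 1))))
    dense = curve(zfine)
    seglen = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seglen)])
    total = s[-1]
    n = int(np.ceil(total)) + 1  # step <= 1 voxel
    s_targets = np.linspace(0.0, total, n)
    z_targets = np.interp(s_targets, s, zfine)
    out = curve(z_targets)
    for ax in range(3):
        if (out[:, ax] < 0).any() or (out[:, ax] > spec.shape[ax] - 1).any():
            raise GeometryError("interpolated centerline leaves the volume")
    return out


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def render_phantom(spec: PhantomSpec) -> tuple[IntensityVolume, BinaryMask]:
    """Render one phantom and its exact ground-truth mask.

    The mask covers every voxel within ``tube_radius_vox + rim_thickness_vox``
    of the centerline — the canal *plus* its cortical rim.  The intensity
    volume is background, with the lumen and rim written over it, rim gaps
    attenuated linearly toward the background, optional streaks added, and
    Gaussian noise applied across the whole volume.
    """
    curve = sample_centerline(spec)
    outer = spec.tube_radius_vox + spec.rim_thickness_vox
    # the canal may run through the first/last slices (it crosses the volume),
    # but the tube must fit inside the in-plane field of view
    for ax in (1, 2):
        lo = curve[:, ax].min()
        hi = curve[:, ax].max()
        if lo < outer - 0.5 or hi > spec.shape[ax] - 1 - outer + 0.5:
            raise GeometryError(
                f"tube (outer radius {outer:.2f} vox) exceeds volume bounds "
                f"along axis {ax}")

    # nearest centerline sample for every voxel: distance + arc-length fraction
    grid = np.stack(np.meshgrid(*[np.arange(n) for n in spec.shape],
                                indexing="ij"), axis=-1).reshape(-1, 3)
    tree = cKDTree(curve)
    dist, idx = tree.query(grid, workers=-1)
    dist = dist.reshape(spec.shape)
    frac = (idx / max(len(curve) - 1, 1)).reshape(spec.shape)

    mask = dist <= outer
    lumen = dist <= spec.tube_radius_vox
    rim = mask & ~lumen

    # inside gap segments the whole tube cross-section fades toward the
    # background: the cortical rim loses contrast and the medulla pattern
    # becomes unclear, so the canal is genuinely hard to see there
    rim_value = np.full(spec.shape, spec.rim_intensity)
    lumen_value = np.full(spec.shape, spec.lumen_intensity)
    for start, end, atten in spec.gap_segments:
        in_gap = (frac >= start) & (frac <= end)
        rim_value[in_gap] = (spec.rim_intensity * (1 - atten)
                             + spec.background_intensity * atten)
        lumen_value[in_gap] = (spec.lumen_intensity * (1 - atten)
                               + spec.background_intensity * atten)
    intensity = np.full(spec.shape, spec.background_intensity)
    intensity[lumen] = lumen_value[lumen]
    intensity[rim] = rim_value[rim]

    rng = np.random.default_rng(spec.seed)
    for _ in range(spec.streak_count):
        intensity += _streak(spec, rng)
    if spec.noise_sigma > 0:
        intensity += rng.normal(0.0, spec.noise_sigma, size=spec.shape)

    return (IntensityVolume(intensity, spec.spacing_mm),
            BinaryMask(mask, spec.spacing_mm))


def _streak(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """One additive bright line with a Gaussian cross-profile (metal analog)."""
    point = np.array([rng.uniform(0, n - 1) for n in spec.shape])
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    grid = np.stack(np.meshgrid(*[np.arange(n) for n in spec.shape],
                                indexing="ij"), axis=-1).astype(float)
    rel = grid - point
    along = rel @ direction
    perp = rel - along[..., None] * direction
    d2 = np.sum(perp ** 2, axis=-1)
    amplitude = 1.5 * (spec.rim_intensity - spec.background_intensity)
    return amplitude * np.exp(-d2 / 2.0)  # cross-profile sigma = 1 voxel


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

def default_spec_sampler(rng: np.random.Generator,
                         shape: tuple[int, int, int] = (16, 32, 32),
                         with_gaps: bool = True,
                         gap_extent: tuple[float, float] = (0.15, 0.3),
                         gap_attenuation: tuple[float, float] = (0.8, 1.0),
                         streak_probability: float = 0.25) -> PhantomSpec:
    """Draw a randomised PhantomSpec with gentle anatomical-style variation.

    Curvature, radius, rim gaps and occasional streaks vary between draws the
    way canal shape and visibility vary between patients; intensity levels
    stay fixed so that contrast is comparable across a dataset.
    """
    T, H, W = shape
    # clearance for the widest sampled tube (outer radius <= 4.2 voxels),
    # shrunk on small grids so a sampling window remains
    margin = max(5.0, min(8.0, (min(H, W) - 1) / 2 - 2.0))
    if (min(H, W) - 1) / 2 <= margin:
        raise GeometryError(f"in-plane shape {(H, W)} too small for a phantom")
    r0, c0 = rng.uniform(margin, H - 1 - margin), rng.uniform(margin, W - 1 - margin)
    drift = rng.uniform(-4.0, 4.0, size=2)
    bow = rng.uniform(-3.0, 3.0, size=2)
    mid = np.clip([r0 + drift[0] / 2 + bow[0], c0 + drift[1] / 2 + bow[1]],
                  margin, [H - 1 - margin, W - 1 - margin])
    end = np.clip([r0 + drift[0], c0 + drift[1]],
                  margin, [H - 1 - margin, W - 1 - margin])
    control = ((0.0, r0, c0),
               ((T - 1) / 2, float(mid[0]), float(mid[1])),
               (float(T - 1), float(end[0]), float(end[1])))
    gaps = ()
    if with_gaps:
        extent = rng.uniform(*gap_extent)
        start = rng.uniform(0.15, 0.8 - extent)
        gaps = ((start, start + extent, rng.uniform(*gap_attenuation)),)
    return PhantomSpec(
        shape=shape,
        centerline_control_points=control,
        tube_radius_vox=rng.uniform(1.8, 2.4),
        rim_thickness_vox=rng.uniform(1.2, 1.8),
        gap_segments=gaps,
        streak_count=int(rng.random() < streak_probability),
        seed=int(rng.integers(2 ** 31)),
    )


def generate_dataset(
    n_left: int,
    n_right: int,
    spec_sampler: Callable[[np.random.Generator], PhantomSpec] | PhantomSpec | None = None,
    seed: int = 0,
) -> list[tuple[IntensityVolume, BinaryMask, str]]:
    """Generate a deterministic list of (volume, mask, side) phantoms.

    Right-side items are left-handed phantoms mirrored along axis 2, matching
    the convention that right-side scans are horizontally flipped so one model
    sees a single chirality.
    """
    if n_left + n_right < 1:
        raise ValueError("need at least one phantom")
    rng = np.random.default_rng(seed)
    items: list[tuple[IntensityVolume, BinaryMask, str]] = []
    for side, count in (("left", n_left), ("right", n_right)):
        for _ in range(count):
            if spec_sampler is None:
                spec = default_spec_sampler(rng)
            elif isinstance(spec_sampler, PhantomSpec):
                spec = spec_sampler
            else:
                spec = spec_sampler(rng)
            vol, mask = render_phantom(spec)
            if side == "right":
                vol = IntensityVolume(vol.values[:, :, ::-1].copy(), vol.spacing_mm)
                mask = BinaryMask(mask.values[:, :, ::-1].copy(), mask.spacing_mm)
            items.append((vol, mask, side))
    return items


def straight_spec(shape: tuple[int, int, int] = (16, 32, 32), **overrides) -> PhantomSpec:
    """A noiseless straight-tube spec centred in-plane; handy for oracles."""
    T, H, W = shape
    base = PhantomSpec(
        shape=shape,
        centerline_control_points=((0.0, (H - 1) / 2, (W - 1) / 2),
                                   (float(T - 1), (H - 1) / 2, (W - 1) / 2)),
        noise_sigma=0.0,
        gap_segments=(),
        streak_count=0,
    )
    return replace(base, **overrides) if overrides else base
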