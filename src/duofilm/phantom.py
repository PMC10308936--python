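"""Synthetic two-channel confocal phantoms with voxel-level ground truth.

The generator emulates the structures seen in young dual-species phototrophic
biofilms: a near-surface "seeding layer" of heterotrophic rod cells on the
attachment surface, filamentous cyanobacteria growing as curved tubes toward
the light-facing side, and a fraction of rods clustered around filament axes
(co-localization). Ground-truth boolean masks are recorded *before* optical
degradation, so every downstream stage (segmentation, biovolume, profiles)
can be validated against known volumes.

Image formation, in order: intensity assignment on the truth mask → depth
attenuation → Gaussian PSF convolution → Poisson resampling → additive
Gaussian read noise → clipping to the 8-bit range. The detector is taken to
sit at the high-z face (the light/objective side), so attenuation follows
``exp(-(z_max - z) / attenuation_length)`` and is strongest at the attachment
surface. Overlapping objects take the maximum intensity, not the sum (cells
are opaque): with constant per-channel emission this is simply the mask times
the channel intensity.

Conventions
-----------
* Arrays are (z, y, x); coordinates are physical µm with voxel index k along
  an axis of spacing d covering [k*d, (k+1)*d) and center (k+0.5)*d.
* A voxel belongs to an object iff its *center* lies within the object
  (capsule distance ≤ radius); no partial-volume weighting.
* Identical :class:`PhantomParams` (including ``seed``) regenerate a
  bit-identical stack; geometry draws precede noise draws via separate
  child generators, so truth masks are invariant to noise parameters.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from .stack_io import DEFAULT_SEGMENTS, DepthSegment, ImageStack, write_stack

__all__ = [
    "SEEDING_LAYER_UM",
    "PhantomParams",
    "Rod",
    "PhantomTruth",
    "generate_phantom",
    "generate_timeseries",
    "rasterize_capsule",
    "rasterize_tube",
    "render_channel",
    "matched_thresholds",
    "write_phantom",
]

#: Depth (µm from the attachment surface) of the rod seeding layer.
SEEDING_LAYER_UM = 10.0


def _as_sigma3(value) -> tuple[float, float, float]:
    if np.isscalar(value):
        v = float(value)
        return (v, v, v)
    t = tuple(float(v) for v in value)
    if len(t) != 3:
        raise ValueError(f"psf_sigma must be a scalar or 3 values, got {value!r}")
    return t


@dataclass(frozen=True)
class PhantomParams:
    """Generator parameters (all lengths in µm, intensities on the 8-bit scale).

    Defaults describe the study conditions the test-bed assumes: a
    0.5 µm-isotropic region of interest 30 µm deep, cyanobacterial filaments
    of radius 2 µm random-walking toward the light, Pseudomonas-like rods
    (3 µm capsules of radius 0.6 µm) mostly seeded below 10 µm, moderate
    optical blur and mixed Poisson–Gaussian noise at in-mask SNR ≈ 12.
    """

    grid_shape: tuple[int, int, int] = (60, 120, 120)
    voxel_spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)
    n_filaments: int = 5
    filament_radius: float = 2.0
    filament_length: float = 60.0
    filament_step: float = 1.0
    filament_step_sd: float = 0.35
    n_rods: int = 400
    rod_length: float = 3.0
    rod_radius: float = 0.6
    seeding_layer_fraction: float = 0.8
    coloc_fraction: float = 0.5
    coloc_radius: float = 1.5
    psf_sigma: tuple[float, float, float] | float = (0.5, 0.3, 0.3)
    attenuation_length: float = 100.0
    red_intensity: float = 200.0
    green_intensity: float = 180.0
    gauss_noise_sd: float = 6.0
    poisson_scale: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "grid_shape", tuple(int(n) for n in self.grid_shape))
        object.__setattr__(
            self, "voxel_spacing", tuple(float(s) for s in self.voxel_spacing)
        )
        object.__setattr__(self, "psf_sigma", _as_sigma3(self.psf_sigma))
        if len(self.grid_shape) != 3 or any(n <= 0 for n in self.grid_shape):
            raise ValueError(f"grid_shape must be 3 positive integers, got {self.grid_shape}")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel_spacing must be strictly positive")
        for name in (
            "filament_radius",
            "filament_length",
            "filament_step",
            "rod_length",
            "rod_radius",
            "coloc_radius",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("n_filaments", "n_rods"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("seeding_layer_fraction", "coloc_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("filament_step_sd", "gauss_noise_sd", "poisson_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.attenuation_length <= 0:
            raise ValueError("attenuation_length must be positive (use math.inf to disable)")
        if self.red_intensity < 0 or self.green_intensity < 0:
            raise ValueError("channel intensities must be non-negative")
        half_voxel = max(self.voxel_spacing) / 2.0
        for name in ("filament_radius", "rod_radius"):
            if getattr(self, name) < half_voxel:
                raise ValueError(
                    f"unresolvable geometry: {name}={getattr(self, name)} µm is smaller "
                    f"than half a voxel ({half_voxel} µm)"
                )
        for sigma, d in zip(self.psf_sigma, self.voxel_spacing):
            if 0.0 < sigma < d / 2.0:
                raise ValueError(
                    f"unresolvable geometry: psf_sigma {sigma} µm is smaller than half "
                    f"a voxel ({d / 2.0} µm); use 0 to disable the PSF"
                )

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical size (µm) of the grid along (z, y, x)."""
        return tuple(n * d for n, d in zip(self.grid_shape, self.voxel_spacing))


@dataclass(frozen=True)
class Rod:
    """One rod cell: a capsule with axis endpoints p0–p1 and cap radius."""

    p0: tuple[float, float, float]
    p1: tuple[float, float, float]
    radius: float
    centroid: tuple[float, float, float]
    colocalized: bool
    seeded: bool


@dataclass
class PhantomTruth:
    """Noise-free ground truth: species masks plus the generating geometry."""

    red_mask: np.ndarray
    green_mask: np.ndarray
    voxel_spacing: tuple[float, float, float]
    filaments: list[np.ndarray] = field(default_factory=list)
    rods: list[Rod] = field(default_factory=list)
    coloc_unsatisfied: int = 0

    def true_volume_per_segment(
        self, segments: Sequence[DepthSegment] = DEFAULT_SEGMENTS
    ) -> pd.DataFrame:
        """Exact per-segment truth volumes (µm³) by voxel-center counting."""
        dz, dy, dx = self.voxel_spacing
        vox = dz * dy * dx
        z_centers = (np.arange(self.red_mask.shape[0]) + 0.5) * dz
        rows = []
        for species, mask in (("red", self.red_mask), ("green", self.green_mask)):
            for seg in segments:
                sel = np.array([seg.contains(z) for z in z_centers])
                count = int(mask[sel].sum())
                rows.append(
                    {
                        "species": species,
                        "segment_lo_um": seg.z_lo,
                        "segment_hi_um": seg.z_hi,
                        "n_voxels": count,
                        "volume_um3": count * vox,
                    }
                )
        return pd.DataFrame(rows)


def _bbox_slices(
    lo: np.ndarray, hi: np.ndarray, grid_shape: Sequence[int], spacing: Sequence[float]
):
    """Index slices and voxel-center coordinate arrays covering [lo, hi] per axis."""
    slices, centers = [], []
    for a in range(3):
        d = spacing[a]
        k_lo = max(0, math.ceil(lo[a] / d - 0.5))
        k_hi = min(grid_shape[a] - 1, math.floor(hi[a] / d - 0.5))
        if k_hi < k_lo:
            return None, None
        slices.append(slice(k_lo, k_hi + 1))
        centers.append((np.arange(k_lo, k_hi + 1) + 0.5) * d)
    return tuple(slices), centers


def rasterize_capsule(
    p0: Sequence[float],
    p1: Sequence[float],
    radius: float,
    grid_shape: Sequence[int],
    spacing: Sequence[float],
    out: np.ndarray | None = None,
) -> np.ndarray:
    """Mark voxels whose centers lie within ``radius`` of the segment p0–p1.

    This is the capsule (cylinder + hemispherical caps) membership test used
    for both rods and single filament steps. Returns the boolean grid.
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    if out is None:
        out = np.zeros(tuple(grid_shape), dtype=bool)
    lo = np.minimum(p0, p1) - radius
    hi = np.maximum(p0, p1) + radius
    slices, centers = _bbox_slices(lo, hi, grid_shape, spacing)
    if slices is None:
        return out
    zc = centers[0][:, None, None]
    yc = centers[1][None, :, None]
    xc = centers[2][None, None, :]
    v = p1 - p0
    vv = float(v @ v)
    dz = zc - p0[0]
    dy = yc - p0[1]
    dx = xc - p0[2]
    if vv == 0.0:
        d2 = dz * dz + dy * dy + dx * dx
    else:
        t = (dz * v[0] + dy * v[1] + dx * v[2]) / vv
        t = np.clip(t, 0.0, 1.0)
        d2 = (dz - t * v[0]) ** 2 + (dy - t * v[1]) ** 2 + (dx - t * v[2]) ** 2
    out[slices] |= d2 <= radius * radius
    return out


def rasterize_tube(
    polyline: np.ndarray,
    radius: float,
    grid_shape: Sequence[int],
    spacing: Sequence[float],
    out: np.ndarray | None = None,
) -> np.ndarray:
    """Mark voxels within ``radius`` of a polyline (union of capsule segments)."""
    polyline = np.asarray(polyline, dtype=float)
    if out is None:
        out = np.zeros(tuple(grid_shape), dtype=bool)
    if len(polyline) == 1:
        return rasterize_capsule(polyline[0], polyline[0], radius, grid_shape, spacing, out)
    for p0, p1 in zip(polyline[:-1], polyline[1:]):
        rasterize_capsule(p0, p1, radius, grid_shape, spacing, out)
    return out


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0.0:
        return np.array([1.0, 0.0, 0.0])
    return v / n


def _random_filament(params: PhantomParams, rng: np.random.Generator) -> np.ndarray:
    """Random-walk tube axis: fixed step length, Gaussian heading jitter,
    reflected at the domain boundaries, biased toward the light-facing (+z) side."""
    ez, ey, ex = params.extent
    extent = np.array([ez, ey, ex])
    pos = np.array(
        [
            rng.uniform(0.0, min(0.25 * ez, SEEDING_LAYER_UM / 2.0)),
            rng.uniform(0.0, ey),
            rng.uniform(0.0, ex),
        ]
    )
    # initial heading: upward bias plus isotropic jitter
    direction = _unit(np.array([1.5, 0.0, 0.0]) + rng.normal(0.0, 1.0, 3))
    n_steps = max(1, int(round(params.filament_length / params.filament_step)))
    points = [pos.copy()]
    for _ in range(n_steps):
        step_vec = direction * params.filament_step + rng.normal(
            0.0, params.filament_step_sd, 3
        )
        direction = _unit(step_vec)
        pos = pos + direction * params.filament_step
        for a in range(3):  # reflect at boundaries
            if pos[a] < 0.0:
                pos[a] = -pos[a]
                direction[a] = -direction[a]
            elif pos[a] > extent[a]:
                pos[a] = 2.0 * extent[a] - pos[a]
                direction[a] = -direction[a]
        points.append(pos.copy())
    return np.array(points)


def _place_rods(
    params: PhantomParams,
    filaments: list[np.ndarray],
    rng: np.random.Generator,
) -> tuple[list[Rod], int]:
    ez, ey, ex = params.extent
    h = max(0.0, params.rod_length / 2.0 - params.rod_radius)  # axis half-length
    layer_hi = min(SEEDING_LAYER_UM, ez)
    vertices = np.concatenate(filaments) if filaments else np.empty((0, 3))
    rods: list[Rod] = []
    unsatisfied = 0
    for _ in range(params.n_rods):
        axis = _unit(rng.normal(0.0, 1.0, 3))
        z_extent = abs(axis[0]) * h + params.rod_radius  # half-extent along z
        seeded = rng.random() < params.seeding_layer_fraction
        want_coloc = len(vertices) > 0 and rng.random() < params.coloc_fraction

        def _fits_layer(cz: float) -> bool:
            return z_extent <= cz <= layer_hi - z_extent

        centroid = None
        colocalized = False
        if want_coloc:
            for _attempt in range(200):
                v = vertices[rng.integers(len(vertices))]
                offset = _unit(rng.normal(0.0, 1.0, 3)) * rng.uniform(0.0, params.coloc_radius)
                c = v + offset
                if not (0.0 <= c[0] <= ez and 0.0 <= c[1] <= ey and 0.0 <= c[2] <= ex):
                    continue
                if seeded and not _fits_layer(c[0]):
                    continue
                centroid = c
                colocalized = True
                break
            else:
                unsatisfied += 1
        if centroid is None:
            if seeded:
                if layer_hi - z_extent <= z_extent:  # degenerate thin layer
                    cz = layer_hi / 2.0
                else:
                    cz = rng.uniform(z_extent, layer_hi - z_extent)
            else:
                cz = rng.uniform(0.0, ez)
            centroid = np.array([cz, rng.uniform(0.0, ey), rng.uniform(0.0, ex)])
        p0 = centroid - axis * h
        p1 = centroid + axis * h
        rods.append(
            Rod(
                p0=tuple(p0),
                p1=tuple(p1),
                radius=params.rod_radius,
                centroid=tuple(centroid),
                colocalized=colocalized,
                seeded=seeded,
            )
        )
    return rods, unsatisfied


def render_channel(
    mask: np.ndarray,
    intensity: float,
    spacing: Sequence[float],
    psf_sigma: Sequence[float] | float,
    attenuation_length: float,
    gauss_noise_sd: float,
    poisson_scale: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Turn a truth mask into a noisy 8-bit channel.

    Steps: constant emission on the mask (max rule for overlaps), exponential
    depth attenuation toward low z (detector at the high-z face), Gaussian
    PSF (sigma in µm, 0 disables), Poisson resampling at ``poisson_scale``
    photons per intensity unit (0 disables), additive Gaussian noise
    (sd 0 disables), clip to [0, 255], round to uint8.
    """
    spacing = tuple(float(s) for s in spacing)
    sigma = _as_sigma3(psf_sigma)
    img = mask.astype(float) * float(intensity)
    nz = mask.shape[0]
    if math.isfinite(attenuation_length):
        z = (np.arange(nz) + 0.5) * spacing[0]
        z_max = nz * spacing[0]
        img *= np.exp(-(z_max - z) / attenuation_length)[:, None, None]
    if any(s > 0 for s in sigma):
        img = ndimage.gaussian_filter(img, sigma=[s / d for s, d in zip(sigma, spacing)])
    if poisson_scale > 0:
        img = rng.poisson(img * poisson_scale).astype(float) / poisson_scale
    if gauss_noise_sd > 0:
        img = img + rng.normal(0.0, gauss_noise_sd, img.shape)
    return np.rint(np.clip(img, 0.0, 255.0)).astype(np.uint8)


def generate_phantom(params: PhantomParams) -> tuple[ImageStack, PhantomTruth]:
    """Generate one two-channel phantom stack with its ground truth.

    Geometry and noise use independent child generators spawned from
    ``params.seed``, so the truth (geometry) is bit-identical across runs that
    differ only in noise parameters.
    """
    geo_rng, noise_rng = [
        np.random.default_rng(s) for s in np.random.SeedSequence(params.seed).spawn(2)
    ]
    red_mask = np.zeros(params.grid_shape, dtype=bool)
    filaments = [_random_filament(params, geo_rng) for _ in range(params.n_filaments)]
    for line in filaments:
        rasterize_tube(line, params.filament_radius, params.grid_shape, params.voxel_spacing, red_mask)
    rods, unsatisfied = _place_rods(params, filaments, geo_rng)
    green_mask = np.zeros(params.grid_shape, dtype=bool)
    for rod in rods:
        rasterize_capsule(
            rod.p0, rod.p1, rod.radius, params.grid_shape, params.voxel_spacing, green_mask
        )
    red = render_channel(
        red_mask,
        params.red_intensity,
        params.voxel_spacing,
        params.psf_sigma,
        params.attenuation_length,
        params.gauss_noise_sd,
        params.poisson_scale,
        noise_rng,
    )
    green = render_channel(
        green_mask,
        params.green_intensity,
        params.voxel_spacing,
        params.psf_sigma,
        params.attenuation_length,
        params.gauss_noise_sd,
        params.poisson_scale,
        noise_rng,
    )
    stack = ImageStack(red=red, green=green, voxel_spacing=params.voxel_spacing)
    truth = PhantomTruth(
        red_mask=red_mask,
        green_mask=green_mask,
        voxel_spacing=params.voxel_spacing,
        filaments=filaments,
        rods=rods,
        coloc_unsatisfied=unsatisfied,
    )
    return stack, truth


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


#: Per-day seed stride: seed_day = base_seed + 10007 * day (documented, fixed).
DAY_SEED_STRIDE = 10007


def generate_timeseries(
    base: PhantomParams,
    n_days: int,
    filament_multiplier: float = 1.0,
    rod_multiplier: float | None = None,
) -> list[tuple[ImageStack, PhantomTruth]]:
    """Generate a deterministic growth series of phantoms.

    Day d (d = 0 .. n_days-1) uses object counts round-half-up of
    ``base_count * multiplier**d`` and seed ``base.seed + 10007 * d``.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    if rod_multiplier is None:
        rod_multiplier = filament_multiplier
    if filament_multiplier < 0 or rod_multiplier < 0:
        raise ValueError("growth multipliers must be non-negative")
    series = []
    for day in range(n_days):
        p = replace(
            base,
            n_filaments=_round_half_up(base.n_filaments * filament_multiplier**day),
            n_rods=_round_half_up(base.n_rods * rod_multiplier**day),
            seed=base.seed + DAY_SEED_STRIDE * day,
        )
        series.append(generate_phantom(p))
    return series


def _volume_preserving_fraction(
    radius: float,
    axis_half_length: float,
    psf_sigma: tuple[float, float, float],
    spacing: tuple[float, float, float],
    n_objects: int = 16,
    calibration_seed: int = 99,
) -> float:
    """Threshold, as a fraction of plateau intensity, that preserves volume.

    Bead-calibration analog: render ``n_objects`` canonical capsules of the
    given geometry at unit intensity under the generator's PSF (no noise, no
    attenuation) and return the threshold fraction at which the number of
    voxels above threshold equals the number of truth voxels. For objects
    much larger than the PSF this converges to the half-maximum rule; for
    barely resolved objects it is substantially lower.
    """
    if all(s == 0 for s in psf_sigma):
        return 0.5
    rng = np.random.default_rng(calibration_seed)
    pad = 4.0 * max(psf_sigma) + radius + axis_half_length
    # one object per cell of a coarse lattice so halos never overlap
    cell = 2.0 * pad
    side = math.ceil(math.sqrt(n_objects))
    extent = (cell, side * cell, side * cell)
    shape = tuple(max(1, int(round(e / d))) for e, d in zip(extent, spacing))
    mask = np.zeros(shape, dtype=bool)
    k = 0
    for iy in range(side):
        for ix in range(side):
            if k >= n_objects:
                break
            center = np.array(
                [cell / 2.0, (iy + 0.5) * cell, (ix + 0.5) * cell]
            ) + rng.uniform(-0.5, 0.5, 3) * min(spacing)
            axis = _unit(rng.normal(0.0, 1.0, 3))
            rasterize_capsule(
                center - axis * axis_half_length,
                center + axis * axis_half_length,
                radius,
                shape,
                spacing,
                mask,
            )
            k += 1
    img = ndimage.gaussian_filter(
        mask.astype(float), sigma=[s / d for s, d in zip(psf_sigma, spacing)]
    )
    n_true = int(mask.sum())
    flat = np.sort(img.ravel())[::-1]
    if n_true >= flat.size:
        return 0.5
    return float(0.5 * (flat[n_true - 1] + flat[n_true]))


def matched_thresholds(
    params: PhantomParams, segments: Sequence[DepthSegment] = DEFAULT_SEGMENTS
) -> tuple[float, dict[DepthSegment, float]]:
    """Segmentation thresholds matched to the generator's imaging model.

    For each channel the threshold is the volume-preserving fraction of the
    plateau intensity for that channel's canonical object (filament tube or
    rod capsule) under the generator's PSF, scaled by the attenuated
    intensity: per depth segment (midpoint) for the green channel, and at
    the mean segment midpoint for the red channel's single threshold. This
    mirrors the single-threshold red / per-depth green scheme of the
    segmentation stage; the calibration depends only on generator
    parameters.
    """
    nz = params.grid_shape[0]
    z_max = nz * params.voxel_spacing[0]

    def atten(z: float) -> float:
        if not math.isfinite(params.attenuation_length):
            return 1.0
        return math.exp(-(z_max - z) / params.attenuation_length)

    sigma = _as_sigma3(params.psf_sigma)
    red_frac = _volume_preserving_fraction(
        params.filament_radius,
        max(params.filament_step, 2.0 * params.filament_radius),
        sigma,
        params.voxel_spacing,
    )
    green_frac = _volume_preserving_fraction(
        params.rod_radius,
        max(0.0, params.rod_length / 2.0 - params.rod_radius),
        sigma,
        params.voxel_spacing,
    )
    mids = [seg.midpoint for seg in segments]
    red_thr = red_frac * params.red_intensity * atten(float(np.mean(mids)))
    green_thr = {
        seg: green_frac * params.green_intensity * atten(seg.midpoint) for seg in segments
    }
    return red_thr, green_thr


def write_phantom(
    stack: ImageStack,
    truth: PhantomTruth,
    out_dir: str | Path,
    params: PhantomParams | None = None,
    segments: Sequence[DepthSegment] = DEFAULT_SEGMENTS,
) -> dict[str, Path]:
    """Write stack, truth masks (8-bit 0/255 TIFF) and true-volume CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    extra = {}
    if params is not None:
        extra = {"generator": "duofilm.phantom", "seed": params.seed,
                 "params": json.loads(json.dumps(_params_dict(params)))}
    paths = {"stack": write_stack(stack, out_dir / "stack.tif", extra_metadata=extra)}
    for name, mask in (("red", truth.red_mask), ("green", truth.green_mask)):
        p = out_dir / f"truth_{name}.tif"
        tifffile.imwrite(p, (mask.astype(np.uint8)) * 255)
        paths[f"truth_{name}"] = p
    vol = truth.true_volume_per_segment(segments)
    vol_path = out_dir / "truth_volumes.csv"
    vol.to_csv(vol_path, index=False)
    paths["truth_volumes"] = vol_path
    return paths


def _params_dict(params: PhantomParams) -> dict:
    d = {}
    for k, v in params.__dict__.items():
        d[k] = list(v) if isinstance(v, tuple) else v
    return d
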