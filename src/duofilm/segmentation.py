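"""Isosurface-style voxel segmentation with cross-channel masking.

The red channel (cyanobacterial autofluorescence) is segmented with a single
intensity threshold; the green channel (eGFP heterotroph) is first *masked*
by the red segmentation — every green voxel inside the red mask is set to
zero so autofluorescence bleed-through cannot inflate the heterotroph volume
— and then thresholded with a per-depth-segment threshold that compensates
for signal loss deeper in the biofilm.

"Isosurface quality" from the original GUI workflow is interpreted here as a
threshold on the (optionally Gaussian-smoothed) intensity on the 8-bit
scale; this is a documented interpretation, not a claim of equivalence to
the proprietary implementation. Thresholds are strict: a voxel is kept only
when its smoothed intensity is strictly greater than the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage
from skimage import morphology

from .stack_io import DEFAULT_SEGMENTS, DepthSegment, ImageStack, check_disjoint

__all__ = [
    "SegmentationParams",
    "SegmentationMask",
    "segment_red",
    "mask_green_by_red",
    "segment_green",
]


def _default_green_thresholds() -> dict[DepthSegment, float]:
    # deeper slabs get lower thresholds (signal attenuates away from the detector)
    return {
        DepthSegment(0.0, 10.0): 14.0,
        DepthSegment(10.0, 20.0): 12.0,
        DepthSegment(20.0, 30.0): 10.0,
    }


@dataclass
class SegmentationParams:
    """Thresholding parameters.

    smoothing_sigma is in µm (converted to voxels per axis via the stack
    spacing; 0 disables smoothing). min_object_voxels removes connected
    components (26-connectivity) smaller than the given voxel count, to
    suppress shot-noise speckle; set to 1 to disable.
    """

    red_threshold: float = 30.0
    green_thresholds: Mapping[DepthSegment, float] = field(
        default_factory=_default_green_thresholds
    )
    smoothing_sigma: float = 1.0
    min_object_voxels: int = 8

    def __post_init__(self) -> None:
        if self.red_threshold <= 0:
            raise ValueError("red_threshold must be > 0")
        for seg, thr in self.green_thresholds.items():
            if thr <= 0:
                raise ValueError(f"green threshold for {seg.label} must be > 0")
        if self.smoothing_sigma < 0:
            raise ValueError("smoothing_sigma must be >= 0")
        if self.min_object_voxels < 1:
            raise ValueError("min_object_voxels must be >= 1")


@dataclass
class SegmentationMask:
    """Boolean cell-voxel grid for one species/channel."""

    mask: np.ndarray
    species: str
    params_used: SegmentationParams
    unsegmented_voxels: int = 0

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def _as_bool_array(mask) -> np.ndarray:
    if isinstance(mask, SegmentationMask):
        return mask.mask
    return np.asarray(mask, dtype=bool)


def _smooth(channel: np.ndarray, sigma_um: float, spacing) -> np.ndarray:
    img = channel.astype(float)
    if sigma_um <= 0:
        return img
    return ndimage.gaussian_filter(img, sigma=[sigma_um / d for d in spacing])


def _remove_small(mask: np.ndarray, min_voxels: int) -> np.ndarray:
    if min_voxels <= 1:
        return mask
    # keep components of >= min_voxels voxels (removes those <= min_voxels - 1)
    return morphology.remove_small_objects(mask, max_size=min_voxels - 1, connectivity=3)


def segment_red(stack: ImageStack, params: SegmentationParams | None = None) -> SegmentationMask:
    """Threshold the red (cyanobacterium) channel.

    Voxels with smoothed red intensity strictly above ``red_threshold`` are
    kept, then components below ``min_object_voxels`` are removed.
    """
    params = params or SegmentationParams()
    smoothed = _smooth(stack.red, params.smoothing_sigma, stack.voxel_spacing)
    mask = smoothed > params.red_threshold
    mask = _remove_small(mask, params.min_object_voxels)
    return SegmentationMask(mask=mask, species="Tolypothrix-like (red)", params_used=params)


def mask_green_by_red(green_channel: np.ndarray, red_mask) -> np.ndarray:
    """Zero every green voxel inside the red mask (input left unmodified).

    This is the overestimation guard: autofluorescence of the cyanobacterium
    inside its own isosurface must not be counted as heterotroph signal.
    """
    red = _as_bool_array(red_mask)
    green = np.asarray(green_channel)
    if green.shape != red.shape:
        raise ValueError(
            f"shape mismatch: green {green.shape} vs red mask {red.shape}"
        )
    return np.where(red, np.zeros((), dtype=green.dtype), green)


def segment_green(
    stack: ImageStack,
    red_mask,
    params: SegmentationParams | None = None,
    segments: Sequence[DepthSegment] | None = None,
) -> SegmentationMask:
    """Segment the masked green (heterotroph) channel with per-depth thresholds.

    Pipeline: mask by red → smooth → per-segment strict threshold (a voxel
    uses the threshold of the depth segment containing its center) →
    re-intersect with the complement of the red mask (smoothing can leak
    masked intensity back across the red boundary; red voxels are by
    definition not green cells) → small-object removal.

    Voxels whose centers fall in no configured segment are excluded and
    counted in ``unsegmented_voxels``.
    """
    params = params or SegmentationParams()
    if segments is None:
        segments = tuple(params.green_thresholds.keys())
    check_disjoint(segments)
    for seg in segments:
        if seg not in params.green_thresholds:
            raise ValueError(f"no green threshold configured for segment {seg.label}")
    red = _as_bool_array(red_mask)
    if stack.green.shape != red.shape:
        raise ValueError(
            f"shape mismatch: stack {stack.green.shape} vs red mask {red.shape}"
        )
    masked = mask_green_by_red(stack.green, red)
    smoothed = _smooth(masked, params.smoothing_sigma, stack.voxel_spacing)

    nz, ny, nx = stack.shape
    mask = np.zeros(stack.shape, dtype=bool)
    unsegmented = 0
    for k, z in enumerate(stack.z_centers()):
        seg = next((s for s in segments if s.contains(z)), None)
        if seg is None:
            unsegmented += ny * nx
            continue
        mask[k] = smoothed[k] > params.green_thresholds[seg]
    mask &= ~red
    mask = _remove_small(mask, params.min_object_voxels)
    return SegmentationMask(
        mask=mask,
        species="Ps-like (green)",
        params_used=params,
        unsegmented_voxels=unsegmented,
    )
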