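"""Reading and writing of image stacks and tabular results.

A biofilm stack is a pair of aligned 3-D intensity grids — a red channel
carrying the chlorophyll-a / phycocyanin autofluorescence of the filamentous
cyanobacterium, and a green channel carrying the constitutive eGFP signal of
the heterotrophic partner — plus physical voxel spacing. The z axis is
anchored at the attachment surface (z = 0) and increases toward the bulk
medium / light-facing side.

Stacks are stored as multi-page TIFF with a JSON sidecar holding the voxel
spacing (µm), channel order, and any generator provenance. The sidecar is
authoritative for spacing; TIFF resolution tags are written for convenience.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "DepthSegment",
    "DEFAULT_SEGMENTS",
    "ImageStack",
    "read_stack",
    "write_stack",
    "write_quantification_csv",
    "read_quantification_csv",
]


@dataclass(frozen=True, order=True)
class DepthSegment:
    """Half-open z-slab [z_lo, z_hi) in µm measured from the attachment surface."""

    z_lo: float
    z_hi: float

    def __post_init__(self) -> None:
        if not self.z_lo < self.z_hi:
            raise ValueError(
                f"depth segment needs z_lo < z_hi, got [{self.z_lo}, {self.z_hi})"
            )

    def contains(self, z: float) -> bool:
        return self.z_lo <= z < self.z_hi

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.z_lo + self.z_hi)

    @property
    def label(self) -> str:
        return f"{self.z_lo:g}-{self.z_hi:g} um"


#: The depth stratification used throughout: 0–10, 10–20, 20–30 µm.
DEFAULT_SEGMENTS: tuple[DepthSegment, ...] = (
    DepthSegment(0.0, 10.0),
    DepthSegment(10.0, 20.0),
    DepthSegment(20.0, 30.0),
)


def check_disjoint(segments: Iterable[DepthSegment]) -> None:
    """Raise if any two depth segments overlap."""
    segs = sorted(segments)
    for a, b in zip(segs, segs[1:]):
        if b.z_lo < a.z_hi:
            raise ValueError(f"depth segments overlap: {a.label} and {b.label}")


@dataclass
class ImageStack:
    """Two aligned 3-D intensity grids with physical voxel spacing.

    Arrays are indexed (z, y, x); ``voxel_spacing`` is (dz, dy, dx) in µm.
    Index k along z spans the physical interval [k*dz, (k+1)*dz); a voxel is
    attributed to whichever depth segment contains its *center*.
    """

    red: np.ndarray
    green: np.ndarray
    voxel_spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.red = np.asarray(self.red)
        self.green = np.asarray(self.green)
        if self.red.ndim != 3 or self.green.ndim != 3:
            raise ValueError("channels must be 3-D (z, y, x) arrays")
        if self.red.shape != self.green.shape:
            raise ValueError(
                f"channel shapes differ: red {self.red.shape}, green {self.green.shape}"
            )
        self.voxel_spacing = tuple(float(s) for s in self.voxel_spacing)
        if len(self.voxel_spacing) != 3 or any(s <= 0 for s in self.voxel_spacing):
            raise ValueError(f"voxel spacing must be 3 positive values, got {self.voxel_spacing}")
        if self.red.min() < 0 or self.green.min() < 0:
            raise ValueError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.red.shape

    @property
    def voxel_volume(self) -> float:
        dz, dy, dx = self.voxel_spacing
        return dz * dy * dx

    def z_centers(self) -> np.ndarray:
        """Physical z coordinate (µm) of each slice's voxel centers."""
        dz = self.voxel_spacing[0]
        return (np.arange(self.shape[0]) + 0.5) * dz


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(stack: ImageStack, path: str | Path, extra_metadata: dict | None = None) -> Path:
    """Write a two-channel stack as multi-page TIFF plus a JSON sidecar.

    Page layout is z-major, channel-interleaved (z0/red, z0/green, z1/red, ...),
    recorded in the sidecar together with the voxel spacing in µm.
    """
    path = Path(path)
    arr = np.stack([stack.red, stack.green], axis=1)  # (z, c, y, x)
    dz, dy, dx = stack.voxel_spacing
    tifffile.imwrite(path, arr, resolution=(1.0 / dx, 1.0 / dy))
    sidecar = {
        "axes": "ZCYX",
        "channels": ["red", "green"],
        "voxel_spacing_um": [dz, dy, dx],
        "z_origin": "attachment_surface",
    }
    if extra_metadata:
        sidecar.update(extra_metadata)
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return path


def read_stack(path: str | Path, spacing_override: Sequence[float] | None = None) -> ImageStack:
    """Read a stack written by :func:`write_stack` (or any ZCYX two-channel TIFF).

    ``spacing_override`` (dz, dy, dx in µm) takes precedence over the sidecar.
    A missing channel or missing spacing raises ``ValueError`` naming the
    problem.
    """
    path = Path(path)
    arr = tifffile.imread(path)
    sidecar_file = _sidecar_path(path)
    meta = json.loads(sidecar_file.read_text()) if sidecar_file.exists() else {}

    if arr.ndim == 3:
        raise ValueError(f"green channel not found in {path} (single-channel stack)")
    if arr.ndim != 4:
        raise ValueError(f"unsupported stack layout with shape {arr.shape}")
    if meta.get("axes", "ZCYX") == "CZYX":
        arr = np.swapaxes(arr, 0, 1)
    channels = meta.get("channels", ["red", "green"])
    try:
        red = arr[:, channels.index("red")]
    except ValueError:
        raise ValueError(f"red channel not found in {path}") from None
    try:
        green = arr[:, channels.index("green")]
    except ValueError:
        raise ValueError(f"green channel not found in {path}") from None

    if spacing_override is not None:
        spacing = tuple(float(s) for s in spacing_override)
    elif "voxel_spacing_um" in meta:
        spacing = tuple(float(s) for s in meta["voxel_spacing_um"])
    else:
        raise ValueError(
            f"no voxel spacing for {path}: sidecar missing and no spacing_override given"
        )
    if meta.get("z_flipped", False):
        red = red[::-1]
        green = green[::-1]
    return ImageStack(red=red, green=green, voxel_spacing=spacing)


_QUANT_COLUMNS = [
    "condition",
    "day",
    "replicate",
    "species",
    "segment_lo_um",
    "segment_hi_um",
    "cell_volume_um3",
    "segment_volume_um3",
    "biovolume_percent",
]


def write_quantification_csv(records: Sequence, path: str | Path) -> Path:
    """Write biovolume records (one row each) as a deterministic CSV.

    Rows are ordered by (condition, day, replicate, species, segment_lo_um).
    ``records`` are any objects exposing the BiovolumeRecord attributes.
    """
    if not records:
        raise ValueError("no records to write")
    rows = [
        {
            "condition": r.condition,
            "day": r.day,
            "replicate": r.replicate,
            "species": r.species,
            "segment_lo_um": r.segment.z_lo,
            "segment_hi_um": r.segment.z_hi,
            "cell_volume_um3": r.cell_volume,
            "segment_volume_um3": r.segment_volume,
            "biovolume_percent": r.biovolume_percent,
        }
        for r in records
    ]
    frame = pd.DataFrame(rows, columns=_QUANT_COLUMNS)
    frame = frame.sort_values(
        ["condition", "day", "replicate", "species", "segment_lo_um"]
    ).reset_index(drop=True)
    path = Path(path)
    frame.to_csv(path, index=False)
    return path


def read_quantification_csv(path: str | Path) -> pd.DataFrame:
    """Read a quantification CSV back into a DataFrame (schema-checked)."""
    frame = pd.read_csv(path)
    missing = [c for c in _QUANT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"quantification CSV {path} missing columns: {missing}")
    return frame
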