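"""CFU accounting from track-dilution plating and resident:detached ratios."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CfuMeasurement",
    "cfu_per_liter",
    "read_cfu_csv",
    "summarize_cfu",
    "resident_detached_ratio",
    "ratio_with_error",
    "condition_fold",
]

_SOURCES = ("resident", "detached")


@dataclass(frozen=True)
class CfuMeasurement:
    """One plate count: colonies at a dilution, from a plated volume (L)."""

    colonies: int
    dilution_factor: float
    plated_volume_l: float
    source: str
    condition: str

    def __post_init__(self) -> None:
        if self.colonies < 0:
            raise ValueError("colonies must be >= 0")
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")
        if self.plated_volume_l <= 0:
            raise ValueError("plated_volume_l must be > 0")
        if self.source not in _SOURCES:
            raise ValueError(f"source must be one of {_SOURCES}, got {self.source!r}")


def cfu_per_liter(m: CfuMeasurement) -> float:
    """colonies × dilution_factor / plated_volume (CFU/L)."""
    if m.plated_volume_l <= 0:
        raise ValueError("plated volume must be > 0")
    return m.colonies * m.dilution_factor / m.plated_volume_l


def read_cfu_csv(path: str | Path) -> list[CfuMeasurement]:
    """Read plate rows: colonies, dilution_factor, plated_volume_l, source, condition."""
    frame = pd.read_csv(path)
    required = ["colonies", "dilution_factor", "plated_volume_l", "source", "condition"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"CFU CSV {path} missing columns: {missing}")
    return [
        CfuMeasurement(
            colonies=int(r.colonies),
            dilution_factor=float(r.dilution_factor),
            plated_volume_l=float(r.plated_volume_l),
            source=str(r.source),
            condition=str(r.condition),
        )
        for r in frame.itertuples(index=False)
    ]


def summarize_cfu(measurements: Sequence[CfuMeasurement]) -> pd.DataFrame:
    """Mean ± sample SD of CFU/L per (condition, source)."""
    if not measurements:
        raise ValueError("no measurements")
    rows = [
        {"condition": m.condition, "source": m.source, "cfu_per_l": cfu_per_liter(m)}
        for m in measurements
    ]
    frame = pd.DataFrame(rows)
    out = (
        frame.groupby(["condition", "source"])["cfu_per_l"]
        .agg(mean_cfu_per_l="mean", sd_cfu_per_l=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0, n="count")
        .reset_index()
    )
    return out


def resident_detached_ratio(resident: float, detached: float) -> float:
    """Resident biofilm CFU/L divided by detached (flow-through) CFU/L."""
    if detached <= 0:
        raise ValueError("detached CFU/L must be > 0")
    return resident / detached


def ratio_with_error(
    resident_mean: float,
    resident_sd: float,
    detached_mean: float,
    detached_sd: float,
) -> tuple[float, float]:
    """Ratio of means with first-order (delta-method) error propagation.

    sd(ratio) = ratio × sqrt((sd_r/r)² + (sd_d/d)²); inputs are means ± SD.
    """
    ratio = resident_detached_ratio(resident_mean, detached_mean)
    if resident_mean <= 0:
        raise ValueError("resident mean must be > 0 for relative-error propagation")
    rel = np.sqrt((resident_sd / resident_mean) ** 2 + (detached_sd / detached_mean) ** 2)
    return ratio, ratio * rel


def condition_fold(ratio_a: float, ratio_b: float) -> float:
    """ratio_a / ratio_b (e.g., N2-fixing over nitrate-fed retention ratio)."""
    if ratio_b == 0:
        raise ValueError("condition_fold denominator is zero")
    if ratio_b < 0:
        raise ValueError("condition_fold denominator must be positive")
    return ratio_a / ratio_b
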