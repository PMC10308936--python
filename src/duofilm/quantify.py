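"""Depth-stratified biovolume percentages, species ratios, and statistics.

Biovolume follows the "% cell isosurface / total segment volume" convention:
for each depth segment, the volume of all segmented cell voxels (voxel-center
membership × voxel volume) divided by the segment's total analyzed volume,
as a percent. Species ratios (heterotroph : cyanobacterium, "Ps : To") are
computed per replicate and then summarized, matching per-image box plots.

Statistics: Tukey box-plot summaries (type-7 linear-interpolation quartiles,
whiskers at the most extreme data within 1.5×IQR) and Welch's two-sided
unequal-variance t-test with Welch–Satterthwaite degrees of freedom. Welch
is preferred over the pooled-variance test because depth-stratified biofilm
biovolumes show strongly unequal spread between layers. No multiple-testing
correction is applied by default (raw p-values are reported); a
Benjamini–Hochberg column is available as a clearly labelled extra.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .stack_io import DEFAULT_SEGMENTS, DepthSegment

__all__ = [
    "SegmentVolume",
    "BiovolumeRecord",
    "RatioRecord",
    "BoxStats",
    "TTestResult",
    "biovolume_by_segment",
    "make_records",
    "records_from_frame",
    "ratio_ps_to",
    "box_stats",
    "welch_t_test",
    "fold_change",
    "pairwise_welch",
]


@dataclass(frozen=True)
class SegmentVolume:
    segment: DepthSegment
    cell_volume: float
    segment_volume: float
    biovolume_percent: float


@dataclass(frozen=True)
class BiovolumeRecord:
    """One (condition, day, replicate, species, depth segment) biovolume row."""

    condition: str
    day: int
    replicate: str
    species: str
    segment: DepthSegment
    cell_volume: float
    segment_volume: float
    biovolume_percent: float


@dataclass(frozen=True)
class RatioRecord:
    """Heterotroph:cyanobacterium biovolume ratio for one replicate/segment.

    ``undefined`` flags replicates whose red biovolume is zero; those carry
    ratio = nan and are excluded from summaries (with a logged count).
    """

    condition: str
    day: int
    replicate: str
    segment: DepthSegment
    ratio_ps_to: float
    undefined: bool = False


def _mask_array(mask) -> np.ndarray:
    m = getattr(mask, "mask", mask)
    return np.asarray(m, dtype=bool)


def biovolume_by_segment(
    mask,
    spacing: Sequence[float],
    segments: Sequence[DepthSegment] = DEFAULT_SEGMENTS,
) -> list[SegmentVolume]:
    """Per-segment cell volume, segment volume (both µm³) and biovolume %.

    A voxel belongs to the segment containing its center. A segment with no
    voxel centers inside the stack raises, naming the segment.
    """
    m = _mask_array(mask)
    dz, dy, dx = (float(s) for s in spacing)
    vox = dz * dy * dx
    nz, ny, nx = m.shape
    z_centers = (np.arange(nz) + 0.5) * dz
    out = []
    for seg in segments:
        sel = (z_centers >= seg.z_lo) & (z_centers < seg.z_hi)
        n_slices = int(sel.sum())
        if n_slices == 0:
            raise ValueError(f"segment {seg.label} lies entirely outside the stack")
        n_cell = int(m[sel].sum())
        n_total = n_slices * ny * nx
        out.append(
            SegmentVolume(
                segment=seg,
                cell_volume=n_cell * vox,
                segment_volume=n_total * vox,
                biovolume_percent=100.0 * n_cell / n_total,
            )
        )
    return out


def make_records(
    mask,
    spacing: Sequence[float],
    condition: str,
    day: int,
    replicate: str,
    species: str,
    segments: Sequence[DepthSegment] = DEFAULT_SEGMENTS,
) -> list[BiovolumeRecord]:
    """Biovolume records for one segmented image."""
    return [
        BiovolumeRecord(
            condition=condition,
            day=day,
            replicate=replicate,
            species=species,
            segment=sv.segment,
            cell_volume=sv.cell_volume,
            segment_volume=sv.segment_volume,
            biovolume_percent=sv.biovolume_percent,
        )
        for sv in biovolume_by_segment(mask, spacing, segments)
    ]


def records_from_frame(frame: pd.DataFrame) -> list[BiovolumeRecord]:
    """Rebuild records from a quantification CSV frame (see stack_io)."""
    return [
        BiovolumeRecord(
            condition=row.condition,
            day=int(row.day),
            replicate=str(row.replicate),
            species=row.species,
            segment=DepthSegment(row.segment_lo_um, row.segment_hi_um),
            cell_volume=float(row.cell_volume_um3),
            segment_volume=float(row.segment_volume_um3),
            biovolume_percent=float(row.biovolume_percent),
        )
        for row in frame.itertuples(index=False)
    ]


def _key(r: BiovolumeRecord):
    return (r.condition, r.day, r.replicate, r.segment)


def ratio_ps_to(
    green_records: Sequence[BiovolumeRecord],
    red_records: Sequence[BiovolumeRecord],
) -> list[RatioRecord]:
    """Pair green/red records on (condition, day, replicate, segment) and divide.

    Zero red biovolume yields an ``undefined`` record (nan ratio). Unpaired
    records raise with the missing keys listed.
    """
    green_by_key = {_key(r): r for r in green_records}
    red_by_key = {_key(r): r for r in red_records}
    missing_red = sorted(set(green_by_key) - set(red_by_key))
    missing_green = sorted(set(red_by_key) - set(green_by_key))
    if missing_red or missing_green:
        raise ValueError(
            "unpaired biovolume records; "
            f"missing red for {missing_red}, missing green for {missing_green}"
        )
    out = []
    for key in sorted(green_by_key):
        g = green_by_key[key]
        r = red_by_key[key]
        if r.biovolume_percent == 0:
            out.append(
                RatioRecord(*key[:3], segment=key[3], ratio_ps_to=float("nan"), undefined=True)
            )
        else:
            out.append(
                RatioRecord(
                    *key[:3],
                    segment=key[3],
                    ratio_ps_to=g.biovolume_percent / r.biovolume_percent,
                )
            )
    return out


@dataclass(frozen=True)
class BoxStats:
    n: int
    median: float
    q1: float
    q3: float
    whisker_lo: float
    whisker_hi: float
    mean: float
    sd: float
    outliers: tuple[float, ...]


def box_stats(values: Sequence[float]) -> BoxStats:
    """Tukey box-plot summary.

    Quartiles use linear interpolation (type 7); whiskers reach the most
    extreme data points within 1.5×IQR of the quartiles, but are clamped to
    the box (never inside [q1, q3], the standard drawing convention);
    anything beyond the whisker bounds is an outlier. sd is the sample
    standard deviation (0 for n = 1).
    """
    data = np.asarray(values, dtype=float)
    if data.size == 0:
        raise ValueError("box_stats requires at least one value")
    q1, med, q3 = np.percentile(data, [25.0, 50.0, 75.0])
    iqr = q3 - q1
    lo_bound = q1 - 1.5 * iqr
    hi_bound = q3 + 1.5 * iqr
    inside = data[(data >= lo_bound) & (data <= hi_bound)]
    whisker_lo = float(min(inside.min(), q1))
    whisker_hi = float(max(inside.max(), q3))
    outliers = tuple(sorted(data[(data < lo_bound) | (data > hi_bound)]))
    sd = float(data.std(ddof=1)) if data.size > 1 else 0.0
    return BoxStats(
        n=int(data.size),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_lo=whisker_lo,
        whisker_hi=whisker_hi,
        mean=float(data.mean()),
        sd=sd,
        outliers=outliers,
    )


@dataclass(frozen=True)
class TTestResult:
    t_statistic: float
    degrees_of_freedom: float
    p_value: float


def welch_t_test(sample_a: Sequence[float], sample_b: Sequence[float]) -> TTestResult:
    """Welch's two-sided unequal-variance t-test.

    t = (mean_a - mean_b) / sqrt(s²_a/n_a + s²_b/n_b), with
    Welch–Satterthwaite degrees of freedom. Requires n ≥ 2 per sample and
    nonzero pooled variance (two identical constant samples are degenerate).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_t_test requires n >= 2 in each sample")
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        raise ValueError("degenerate input: both samples have zero variance")
    sea = va / a.size
    seb = vb / b.size
    t = (a.mean() - b.mean()) / np.sqrt(sea + seb)
    df = (sea + seb) ** 2 / (sea**2 / (a.size - 1) + seb**2 / (b.size - 1))
    p = 2.0 * float(_sps.t.sf(abs(t), df))
    return TTestResult(t_statistic=float(t), degrees_of_freedom=float(df), p_value=p)


def fold_change(mean_a: float, mean_b: float) -> float:
    """mean_a / mean_b; the denominator must be strictly positive."""
    if mean_b == 0:
        raise ValueError("fold_change denominator is zero")
    if mean_b < 0:
        raise ValueError("fold_change denominator must be positive")
    return mean_a / mean_b


def pairwise_welch(
    groups: Mapping[str, Sequence[float]], benjamini_hochberg: bool = False
) -> pd.DataFrame:
    """All pairwise Welch tests between named groups of values.

    Returns a frame with group_a, group_b, t, df, p_value and optionally a
    ``p_bh`` Benjamini–Hochberg column (an extra beyond the raw-p reporting
    convention, computed via statsmodels).
    """
    names = list(groups)
    rows = []
    for i, na in enumerate(names):
        for nb in names[i + 1 :]:
            res = welch_t_test(groups[na], groups[nb])
            rows.append(
                {
                    "group_a": na,
                    "group_b": nb,
                    "t": res.t_statistic,
                    "df": res.degrees_of_freedom,
                    "p_value": res.p_value,
                }
            )
    frame = pd.DataFrame(rows, columns=["group_a", "group_b", "t", "df", "p_value"])
    if benjamini_hochberg and len(frame):
        from statsmodels.stats.multitest import multipletests

        frame["p_bh"] = multipletests(frame["p_value"], method="fdr_bh")[1]
    return frame
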