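"""Post-search label-free proteome comparison by within-sample abundance rank.

Works on abundance tables as exported after database search and label-free
quantification: one row per protein (locus tag), per-sample abundance, PSM
count, and FDR confidence category. The comparison statistic is the
*within-sample rank*: each protein is ranked among all proteins quantified
in that sample, most abundant = rank 1. Ranks are robust to between-sample
normalization (ranking is invariant under any strictly monotone transform),
which is why they are used instead of raw abundances.

ND semantics: a protein with no abundance value in a sample is "not
determined" in that sample; a zero abundance is invalid input, not ND. FDR
confidence categories are carried through as metadata only — no
re-estimation happens here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ProteinTable",
    "rank_within_sample",
    "rank_table",
    "summarize_ranks",
    "exclusive_proteins",
    "synthesize_protein_tables",
    "normalize_to_reference",
    "table1_report",
]

_TIE_METHODS = {"average": "average", "competition": "min"}


@dataclass
class ProteinTable:
    """Per-sample abundance / PSM / confidence rows keyed by locus tag.

    All three frames share the same index (unique locus tags) and the same
    sample columns; NaN marks ND. Abundances, where present, must be > 0.
    """

    abundance: pd.DataFrame
    psm: pd.DataFrame
    confidence: pd.DataFrame
    protein_name: pd.Series

    def __post_init__(self) -> None:
        if self.abundance.index.has_duplicates:
            dupes = self.abundance.index[self.abundance.index.duplicated()].tolist()
            raise ValueError(f"duplicate locus tags: {dupes}")
        for name, frame in (("psm", self.psm), ("confidence", self.confidence)):
            if not frame.index.equals(self.abundance.index) or list(frame.columns) != list(
                self.abundance.columns
            ):
                raise ValueError(f"{name} frame does not align with abundance frame")
        if not self.protein_name.index.equals(self.abundance.index):
            raise ValueError("protein_name does not align with abundance frame")
        values = self.abundance.to_numpy(dtype=float)
        if np.any(values[~np.isnan(values)] <= 0):
            raise ValueError("abundances must be strictly positive where present (ND = absent)")

    @property
    def samples(self) -> list[str]:
        return list(self.abundance.columns)

    @property
    def n_proteins(self) -> int:
        return len(self.abundance)

    def to_csv(self, path: str | Path) -> Path:
        frame = pd.DataFrame({"protein_name": self.protein_name})
        for s in self.samples:
            frame[f"abundance_{s}"] = self.abundance[s]
            frame[f"psm_{s}"] = self.psm[s]
            frame[f"confidence_{s}"] = self.confidence[s]
        path = Path(path)
        frame.to_csv(path, index_label="locus_tag")
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "ProteinTable":
        frame = pd.read_csv(path, index_col="locus_tag")
        samples = [c[len("abundance_") :] for c in frame.columns if c.startswith("abundance_")]
        if not samples:
            raise ValueError(f"no abundance_<sample> columns in {path}")
        return cls(
            abundance=frame[[f"abundance_{s}" for s in samples]].set_axis(samples, axis=1),
            psm=frame[[f"psm_{s}" for s in samples]].set_axis(samples, axis=1),
            confidence=frame[[f"confidence_{s}" for s in samples]].set_axis(samples, axis=1),
            protein_name=frame["protein_name"],
        )


def rank_within_sample(abundances, ties: str = "average") -> pd.Series:
    """Rank proteins by descending abundance within one sample.

    Most abundant protein gets rank 1. Ties receive the average of the tied
    rank positions (``ties="average"``) or the best tied position
    (``ties="competition"``). Input is a mapping/Series of present-only
    abundances (exclude ND beforehand); an empty input returns an empty
    Series. Over n proteins, average-tie ranks sum to n(n+1)/2.
    """
    if ties not in _TIE_METHODS:
        raise ValueError(f"ties must be one of {sorted(_TIE_METHODS)}, got {ties!r}")
    s = pd.Series(abundances, dtype=float)
    if s.isna().any():
        raise ValueError("rank_within_sample expects present-only abundances (no NaN)")
    return s.rank(ascending=False, method=_TIE_METHODS[ties])


def rank_table(table: ProteinTable, ties: str = "average") -> pd.DataFrame:
    """Per-sample within-sample ranks; NaN where the protein is ND."""
    out = {}
    for s in table.samples:
        col = table.abundance[s].dropna()
        out[s] = rank_within_sample(col, ties=ties)
    return pd.DataFrame(out).reindex(table.abundance.index)


def summarize_ranks(
    table: ProteinTable,
    condition_map: Mapping[str, str],
    ties: str = "average",
    spread: str = "sample_sd",
) -> pd.DataFrame:
    """Per-condition mean and spread of within-sample ranks over replicates.

    ``condition_map`` maps sample name → condition label. For each protein
    and condition: mean and spread of ranks over the replicates where the
    protein is detected; NaN (ND) when detected in none; the number of
    detected replicates is reported. ``spread`` is "sample_sd" (ddof-1 SD,
    0.0 for a single detected replicate) or "half_range" ((max-min)/2).
    Unknown samples in the map raise.
    """
    unknown = sorted(set(condition_map) - set(table.samples))
    if unknown:
        raise ValueError(f"condition_map names unknown samples: {unknown}")
    if spread not in ("sample_sd", "half_range"):
        raise ValueError(f"spread must be 'sample_sd' or 'half_range', got {spread!r}")
    ranks = rank_table(table, ties=ties)
    conditions: dict[str, list[str]] = {}
    for sample, cond in condition_map.items():
        conditions.setdefault(cond, []).append(sample)

    pieces = {}
    for cond, samples in conditions.items():
        sub = ranks[samples]
        detected = sub.notna().sum(axis=1)
        mean = sub.mean(axis=1)
        if spread == "sample_sd":
            sd = sub.std(axis=1, ddof=1)
            sd = sd.where(detected != 1, 0.0)
        else:
            sd = (sub.max(axis=1) - sub.min(axis=1)) / 2.0
        pieces[(cond, "mean_rank")] = mean
        pieces[(cond, "sd_rank")] = sd
        pieces[(cond, "detected_replicates")] = detected
    summary = pd.DataFrame(pieces)
    summary.columns = pd.MultiIndex.from_tuples(summary.columns, names=["condition", "stat"])
    summary.attrs["n_replicates"] = {c: len(s) for c, s in conditions.items()}
    return summary


def exclusive_proteins(
    summaries: pd.DataFrame,
    condition_a: str,
    condition_b: str,
    min_detected: int | None = None,
) -> list[str]:
    """Proteins detected in ``condition_a`` but in no ``condition_b`` replicate.

    ``min_detected`` (default: all of condition_a's replicates — strict)
    sets how many condition_a replicates must detect the protein.
    """
    conds = summaries.columns.get_level_values("condition")
    for cond in (condition_a, condition_b):
        if cond not in conds:
            raise ValueError(f"condition {cond!r} absent from summaries")
    if min_detected is None:
        min_detected = summaries.attrs.get("n_replicates", {}).get(condition_a)
        if min_detected is None:
            raise ValueError("min_detected not given and replicate counts unavailable")
    det_a = summaries[(condition_a, "detected_replicates")]
    det_b = summaries[(condition_b, "detected_replicates")]
    sel = (det_a >= min_detected) & (det_b == 0)
    return sorted(summaries.index[sel])


def synthesize_protein_tables(
    n_proteins: int = 2300,
    n_exclusive: int = 25,
    n_replicates: int = 2,
    log_abundance_mean: float = 14.0,
    log_abundance_sd: float = 2.0,
    replicate_log_sd: float = 0.25,
    seed: int = 0,
) -> tuple[ProteinTable, dict[str, str], list[str]]:
    """Generate a two-condition replicate table with planted exclusives.

    Emulates a shotgun-proteomics comparison of ~2,300 quantified proteins
    per sample in two conditions ("w/o N": N2-fixing; "w N": nitrate-fed)
    with ``n_replicates`` biological replicates each. Per-protein abundances
    are log-normal (natural-log mean/sd) with log-normal replicate scatter.
    ``n_exclusive`` proteins are planted as detected in every "w/o N"
    replicate and absent from every "w N" replicate; all other proteins are
    detected everywhere (noise-free detection), so the planted set is exactly
    recoverable. Returns (table, condition_map, planted locus tags).
    """
    if n_exclusive > n_proteins:
        raise ValueError("n_exclusive cannot exceed n_proteins")
    if n_proteins < 1 or n_replicates < 1 or n_exclusive < 0:
        raise ValueError("counts must be positive (n_exclusive >= 0)")
    rng = np.random.default_rng(seed)
    tags = [f"SYN_{i:05d}" for i in range(n_proteins)]
    exclusive = sorted(rng.choice(n_proteins, size=n_exclusive, replace=False).tolist())
    planted = [tags[i] for i in exclusive]
    samples = [f"M{r + 1} w/o N" for r in range(n_replicates)] + [
        f"M{r + 1} w N" for r in range(n_replicates)
    ]
    condition_map = {s: ("w/o N" if "w/o" in s else "w N") for s in samples}
    base = rng.normal(log_abundance_mean, log_abundance_sd, n_proteins)
    abundance = pd.DataFrame(
        {
            s: np.exp(base + rng.normal(0.0, replicate_log_sd, n_proteins))
            for s in samples
        },
        index=pd.Index(tags, name="locus_tag"),
    )
    for s in samples:
        if condition_map[s] == "w N":
            abundance.loc[planted, s] = np.nan
    detected = abundance.notna()
    psm = pd.DataFrame(
        rng.poisson(4, size=abundance.shape) + 1, index=abundance.index, columns=samples
    ).where(detected)
    confidence = pd.DataFrame("H", index=abundance.index, columns=samples).where(detected)
    names = pd.Series([f"synthetic protein {i}" for i in range(n_proteins)], index=abundance.index)
    table = ProteinTable(
        abundance=abundance, psm=psm, confidence=confidence, protein_name=names
    )
    return table, condition_map, planted


def normalize_to_reference(table: ProteinTable, reference_locus: str) -> ProteinTable:
    """Divide each sample's abundances by a reference protein's abundance.

    Mirrors internal-standard (e.g., GAPDH) normalization. Ranking is
    scale-invariant, so this affects exported abundances only. The reference
    must be detected in every sample.
    """
    if reference_locus not in table.abundance.index:
        raise ValueError(f"reference protein {reference_locus!r} not in table")
    ref = table.abundance.loc[reference_locus]
    if ref.isna().any():
        missing = ref.index[ref.isna()].tolist()
        raise ValueError(f"reference {reference_locus!r} is ND in samples: {missing}")
    return ProteinTable(
        abundance=table.abundance / ref,
        psm=table.psm.copy(),
        confidence=table.confidence.copy(),
        protein_name=table.protein_name.copy(),
    )


def table1_report(
    table: ProteinTable,
    condition_map: Mapping[str, str],
    loci: Sequence[str] | None = None,
    ties: str = "average",
    spread: str = "sample_sd",
) -> pd.DataFrame:
    """Flat report: locus tag, name, mean ± sd rank per condition, per-sample
    PSM counts and confidence categories (ND where not detected)."""
    summary = summarize_ranks(table, condition_map, ties=ties, spread=spread)
    if loci is None:
        loci = list(table.abundance.index)
    conds = list(dict.fromkeys(condition_map.values()))
    out = pd.DataFrame(index=pd.Index(loci, name="locus_tag"))
    out["protein_name"] = table.protein_name.loc[loci]
    for cond in conds:
        out[f"mean_rank [{cond}]"] = summary.loc[loci, (cond, "mean_rank")].round(1)
        out[f"sd_rank [{cond}]"] = summary.loc[loci, (cond, "sd_rank")].round(1)
    for s in condition_map:
        out[f"PSM [{s}]"] = table.psm.loc[loci, s]
        out[f"confidence [{s}]"] = table.confidence.loc[loci, s].fillna("ND")
    return out
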