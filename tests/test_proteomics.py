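import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from duofilm.proteomics import (
    ProteinTable,
    exclusive_proteins,
    normalize_to_reference,
    rank_table,
    rank_within_sample,
    summarize_ranks,
    synthesize_protein_tables,
    table1_report,
)


class TestRankWithinSample:
    def test_simple_descending(self):
        ranks = rank_within_sample({"A": 10.0, "B": 5.0, "C": 1.0})
        assert ranks.to_dict() == {"A": 1.0, "B": 2.0, "C": 3.0}

    def test_ties_average_of_positions(self):
        ranks = rank_within_sample({"A": 5.0, "B": 5.0, "C": 2.0})
        assert ranks.to_dict() == {"A": 1.5, "B": 1.5, "C": 3.0}

    def test_ties_competition_policy(self):
        ranks = rank_within_sample({"A": 5.0, "B": 5.0, "C": 2.0}, ties="competition")
        assert ranks.to_dict() == {"A": 1.0, "B": 1.0, "C": 3.0}

    def test_single_protein(self):
        assert rank_within_sample({"only": 3.3}).to_dict() == {"only": 1.0}

    def test_empty_input(self):
        assert rank_within_sample({}).empty

    def test_distinct_abundances_give_exact_permutation(self, rng):
        """Sort-based brute-force oracle: with all-distinct abundances the
        ranks are exactly the permutation 1..n."""
        for n in (2, 17, 500):
            values = rng.permutation(n) + rng.random(n) * 0.5 + 1.0
            tags = [f"P{i}" for i in range(n)]
            ranks = rank_within_sample(dict(zip(tags, values)))
            order = sorted(tags, key=lambda t: -values[tags.index(t)])
            expected = {t: float(i + 1) for i, t in enumerate(order)}
            assert ranks.to_dict() == expected
            assert ranks.sum() == n * (n + 1) / 2

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        values=st.lists(
            st.floats(min_value=0.01, max_value=1e6, allow_nan=False), min_size=1, max_size=40
        ),
        scale=st.floats(min_value=0.1, max_value=100.0),
    )
    def test_invariant_under_monotone_transform(self, values, scale):
        tags = [f"P{i}" for i in range(len(values))]
        base = rank_within_sample(dict(zip(tags, values)))
        squeezed = rank_within_sample(dict(zip(tags, [np.log1p(v) * scale for v in values])))
        pd.testing.assert_series_equal(base, squeezed)


def toy_table():
    """Two conditions x two replicates with known detection patterns."""
    samples = ["M1 w/o N", "M2 w/o N", "M1 w N", "M2 w N"]
    abundance = pd.DataFrame(
        {
            "M1 w/o N": [100.0, 50.0, 10.0, 5.0],
            "M2 w/o N": [90.0, 60.0, 12.0, 4.0],
            "M1 w N": [80.0, np.nan, 11.0, np.nan],
            "M2 w N": [85.0, np.nan, 13.0, 6.0],
        },
        index=pd.Index(["P_house", "P_excl", "P_mid", "P_partial"], name="locus_tag"),
    )
    detected = abundance.notna()
    psm = pd.DataFrame(3, index=abundance.index, columns=samples).where(detected)
    conf = pd.DataFrame("H", index=abundance.index, columns=samples).where(detected)
    names = pd.Series(["housekeeping", "exclusive", "middle", "partial"], index=abundance.index)
    table = ProteinTable(abundance=abundance, psm=psm, confidence=conf, protein_name=names)
    cmap = {s: ("w/o N" if "w/o" in s else "w N") for s in samples}
    return table, cmap


class TestProteinTable:
    def test_duplicate_locus_rejected(self):
        table, _ = toy_table()
        dup = table.abundance.copy()
        dup.index = ["A", "A", "B", "C"]
        with pytest.raises(ValueError, match="duplicate"):
            ProteinTable(dup, table.psm.set_axis(dup.index), table.confidence.set_axis(dup.index),
                         table.protein_name.set_axis(dup.index))

    def test_nonpositive_abundance_rejected(self):
        table, _ = toy_table()
        bad = table.abundance.copy()
        bad.iloc[0, 0] = 0.0
        with pytest.raises(ValueError, match="positive"):
            ProteinTable(bad, table.psm, table.confidence, table.protein_name)

    def test_csv_round_trip(self, tmp_path):
        table, _ = toy_table()
        path = table.to_csv(tmp_path / "prot.csv")
        back = ProteinTable.from_csv(path)
        pd.testing.assert_frame_equal(back.abundance, table.abundance)
        assert back.samples == table.samples


class TestSummarizeRanks:
    def test_mean_and_sample_sd_two_replicates(self):
        """Ranks 10 and 14 in two replicates -> 12 ± |10-14|/sqrt(2) = 2.83."""
        samples = ["M1", "M2"]
        n = 20
        abundance = pd.DataFrame(
            {"M1": np.arange(n, 0, -1, dtype=float), "M2": np.arange(n, 0, -1, dtype=float)},
            index=[f"P{i}" for i in range(n)],
        )
        # protein P9 has rank 10 in M1; swap to rank 14 in M2
        abundance.loc["P9", "M2"], abundance.loc["P13", "M2"] = (
            abundance.loc["P13", "M2"],
            abundance.loc["P9", "M2"],
        )
        detected = abundance.notna()
        table = ProteinTable(
            abundance,
            pd.DataFrame(1, index=abundance.index, columns=samples).where(detected),
            pd.DataFrame("H", index=abundance.index, columns=samples).where(detected),
            pd.Series("x", index=abundance.index),
        )
        summary = summarize_ranks(table, {"M1": "c", "M2": "c"})
        assert summary.loc["P9", ("c", "mean_rank")] == pytest.approx(12.0)
        assert summary.loc["P9", ("c", "sd_rank")] == pytest.approx(4 / np.sqrt(2), abs=1e-12)

    def test_half_range_spread_option(self):
        table, cmap = toy_table()
        summary = summarize_ranks(table, cmap, spread="half_range")
        ranks = rank_table(table)
        got = summary.loc["P_house", ("w/o N", "sd_rank")]
        r1, r2 = ranks.loc["P_house", ["M1 w/o N", "M2 w/o N"]]
        assert got == pytest.approx(abs(r1 - r2) / 2)

    def test_single_replicate_detection(self):
        table, cmap = toy_table()
        summary = summarize_ranks(table, cmap)
        assert summary.loc["P_partial", ("w N", "detected_replicates")] == 1
        assert summary.loc["P_partial", ("w N", "sd_rank")] == 0.0

    def test_nd_when_absent_everywhere_in_condition(self):
        table, cmap = toy_table()
        summary = summarize_ranks(table, cmap)
        assert summary.loc["P_excl", ("w N", "detected_replicates")] == 0
        assert np.isnan(summary.loc["P_excl", ("w N", "mean_rank")])
        assert summary.loc["P_excl", ("w/o N", "mean_rank")] == pytest.approx(2.0)

    def test_unknown_sample_rejected(self):
        table, cmap = toy_table()
        with pytest.raises(ValueError, match="unknown"):
            summarize_ranks(table, {**cmap, "M9 w N": "w N"})


class TestExclusiveProteins:
    def test_strict_exclusive_detected(self):
        table, cmap = toy_table()
        summary = summarize_ranks(table, cmap)
        assert exclusive_proteins(summary, "w/o N", "w N") == ["P_excl"]

    def test_partial_detection_not_exclusive(self):
        table, cmap = toy_table()
        summary = summarize_ranks(table, cmap)
        # P_partial is detected in one w N replicate -> not w/o-N-exclusive
        assert "P_partial" not in exclusive_proteins(summary, "w/o N", "w N")

    def test_disjoint_between_directions(self):
        table, cmap = toy_table()
        summary = summarize_ranks(table, cmap)
        a = set(exclusive_proteins(summary, "w/o N", "w N"))
        b = set(exclusive_proteins(summary, "w N", "w/o N"))
        assert not a & b

    def test_missing_condition_rejected(self):
        table, cmap = toy_table()
        summary = summarize_ranks(table, cmap)
        with pytest.raises(ValueError, match="absent"):
            exclusive_proteins(summary, "w/o N", "nope")


class TestSynthesizer:
    def test_planted_exclusives_recovered_exactly(self):
        table, cmap, planted = synthesize_protein_tables(
            n_proteins=400, n_exclusive=25, seed=7
        )
        summary = summarize_ranks(table, cmap)
        assert exclusive_proteins(summary, "w/o N", "w N") == planted
        assert exclusive_proteins(summary, "w N", "w/o N") == []

    def test_no_exclusives_when_none_planted(self):
        table, cmap, planted = synthesize_protein_tables(n_proteins=100, n_exclusive=0, seed=1)
        assert planted == []
        summary = summarize_ranks(table, cmap)
        assert exclusive_proteins(summary, "w/o N", "w N") == []

    def test_reproducible_by_seed(self):
        t1, _, p1 = synthesize_protein_tables(n_proteins=50, n_exclusive=5, seed=3)
        t2, _, p2 = synthesize_protein_tables(n_proteins=50, n_exclusive=5, seed=3)
        pd.testing.assert_frame_equal(t1.abundance, t2.abundance)
        assert p1 == p2

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            synthesize_protein_tables(n_proteins=10, n_exclusive=11)


class TestNormalization:
    def test_reference_division_preserves_ranks(self):
        table, cmap = toy_table()
        normed = normalize_to_reference(table, "P_house")
        pd.testing.assert_frame_equal(rank_table(normed), rank_table(table))
        assert (normed.abundance.loc["P_house"].dropna() == 1.0).all()

    def test_reference_must_be_detected_everywhere(self):
        table, _ = toy_table()
        with pytest.raises(ValueError, match="ND in samples"):
            normalize_to_reference(table, "P_excl")


def test_table1_report_layout():
    table, cmap = toy_table()
    report = table1_report(table, cmap)
    assert "mean_rank [w/o N]" in report.columns
    assert report.loc["P_excl", "confidence [M1 w N]"] == "ND"
    assert np.isnan(report.loc["P_excl", "mean_rank [w N]"])
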