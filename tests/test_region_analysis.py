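"""Region calling, merging, annotation, scan correlation, and the QTL
overlap permutation test."""

import numpy as np
import pandas as pd
import pytest

from sweepscan.containers import RegionSet
from sweepscan.region_analysis import (
    annotate_regions,
    correlate_scans,
    merge_windows,
    percentile_select,
    qtl_overlap_permutation,
    region_qtl_overlap_bp,
)


def window_frame(values, chrom="1", step=10_000, window=20_000, qualifies=None):
    n = len(values)
    starts = 1 + step * np.arange(n)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": starts + window - 1,
            "n_markers": 50,
            "weighted_fst": values,
            "mean_fst": values,
            "qualifies": True if qualifies is None else qualifies,
        }
    )


class TestPercentileSelect:
    def test_top_one_percent_of_hundred(self):
        w = window_frame([0.01 * k for k in range(1, 101)])
        res = percentile_select(w, 0.99)
        assert res.cutoff == pytest.approx(1.0)
        assert len(res.windows) == 1

    def test_ties_at_cutoff_are_included(self):
        values = list(np.linspace(0.01, 0.5, 985)) + [0.9] * 5 + [0.91] * 10
        w = window_frame(values)
        res = percentile_select(w, 0.99)  # ceil(0.01*1000) = 10 -> cutoff 0.91
        assert res.cutoff == pytest.approx(0.91)
        assert len(res.windows) == 10
        res2 = percentile_select(w, 0.985)  # k=15 -> cutoff 0.9, ties pull all 5
        assert len(res2.windows) == 15

    def test_non_qualifying_windows_ignored(self):
        w = window_frame([0.1, 0.2, 0.9, 0.95], qualifies=[True, True, True, False])
        res = percentile_select(w, 0.5)
        assert res.windows["weighted_fst"].max() == 0.9

    def test_no_qualifying_windows_errors(self):
        w = window_frame([0.5], qualifies=[False])
        with pytest.raises(ValueError):
            percentile_select(w, 0.99)


class TestMergeWindows:
    def test_overlapping_and_disjoint(self):
        sel = pd.DataFrame(
            {
                "chrom": ["1", "1", "1"],
                "start": [10_001, 20_001, 50_001],
                "end": [30_000, 40_000, 70_000],
            }
        )
        merged = merge_windows(sel)
        assert [tuple(r) for r in merged.regions[["start", "end"]].to_numpy()] == [
            (10_001, 40_000),
            (50_001, 70_000),
        ]

    def test_single_window_identity(self):
        sel = pd.DataFrame({"chrom": ["1"], "start": [1], "end": [20_000]})
        merged = merge_windows(sel)
        assert len(merged) == 1
        assert tuple(merged.regions.iloc[0][["start", "end"]]) == (1, 20_000)

    def test_bookended_windows_merge(self):
        sel = pd.DataFrame(
            {"chrom": ["1", "1"], "start": [1, 20_001], "end": [20_000, 40_000]}
        )
        assert len(merge_windows(sel)) == 1

    def test_two_runs_of_consecutive_windows(self):
        """32 step-consecutive windows in two separated runs -> 2 envelope regions."""
        starts = [1 + 10_000 * k for k in range(30)] + [4_000_001, 4_010_001]
        sel = pd.DataFrame(
            {"chrom": "26", "start": starts, "end": [s + 19_999 for s in starts]}
        )
        merged = merge_windows(sel)
        assert len(merged) == 2
        assert tuple(merged.regions.iloc[0][["start", "end"]]) == (1, 310_000)
        assert tuple(merged.regions.iloc[1][["start", "end"]]) == (4_000_001, 4_030_000)

    def test_against_brute_force_union(self):
        """Merged output equals a base-set union on random window sets."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = rng.integers(1, 30)
            starts = rng.integers(1, 500, size=n) * 10 + 1
            ends = starts + rng.integers(1, 40, size=n) * 10 - 1
            sel = pd.DataFrame(
                {"chrom": rng.choice(["1", "2"], size=n), "start": starts, "end": ends}
            )
            merged = merge_windows(sel)
            covered = set()
            for c, s, e in sel[["chrom", "start", "end"]].itertuples(index=False):
                covered.update((c, x) for x in range(s, e + 1))
            merged_covered = set()
            for c, s, e in merged.regions[["chrom", "start", "end"]].itertuples(
                index=False
            ):
                merged_covered.update((c, x) for x in range(s, e + 1))
            assert merged_covered == covered
            # maximal: pairwise disjoint and not book-ended
            regs = merged.regions
            for chrom, grp in regs.groupby("chrom"):
                starts_g = grp["start"].to_numpy()
                ends_g = grp["end"].to_numpy()
                assert (starts_g[1:] > ends_g[:-1] + 1).all()


class TestCorrelateScans:
    def test_identical_scans_give_r_one(self):
        values = np.linspace(0.1, 0.9, 30)
        r, p, n = correlate_scans(window_frame(values), window_frame(values), 0.8)
        assert r == pytest.approx(1.0)
        assert n >= 3

    def test_anti_correlated_scans(self):
        values = np.linspace(0.1, 0.9, 30)
        r, _, _ = correlate_scans(
            window_frame(values), window_frame(1.0 - values), 0.8
        )
        assert r == pytest.approx(-1.0)

    def test_too_few_windows_errors(self):
        w = window_frame([0.5, 0.6])
        with pytest.raises(ValueError, match=">= 3"):
            correlate_scans(w, w, 0.5)


class TestAnnotateRegions:
    def test_inclusive_boundary(self):
        genes = RegionSet.from_records([("1", 100, 200, "geneA")])
        overlapping = RegionSet.from_records([("1", 150, 300, "r1")])
        adjacent = RegionSet.from_records([("1", 201, 300, "r2")])
        table, n = annotate_regions(overlapping, genes)
        assert n == 1 and table.iloc[0]["genes"] == "geneA"
        table, n = annotate_regions(adjacent, genes)
        assert n == 0 and table.iloc[0]["n_genes"] == 0

    def test_matches_quadratic_oracle(self):
        rng = np.random.default_rng(1)
        genes = RegionSet.from_records(
            [
                ("1", int(s), int(s + rng.integers(1, 5000)), f"g{i}")
                for i, s in enumerate(rng.integers(1, 10**6, size=1000))
            ]
        )
        regions = RegionSet.from_records(
            [
                ("1", int(s), int(s + rng.integers(1, 50_000)), f"r{i}")
                for i, s in enumerate(rng.integers(1, 10**6, size=50))
            ]
        )
        table, n_unique = annotate_regions(regions, genes)
        brute_unique = set()
        for _, reg in regions.regions.iterrows():
            hits = set()
            for _, g in genes.regions.iterrows():
                if g["start"] <= reg["end"] and reg["start"] <= g["end"]:
                    hits.add(g["label"])
            brute_unique |= hits
            row = table[
                (table["start"] == reg["start"]) & (table["end"] == reg["end"])
            ].iloc[0]
            assert row["n_genes"] == len(hits)
        assert n_unique == len(brute_unique)


class TestQtlOverlapPermutation:
    lengths = {"1": 10_000_000, "2": 10_000_000}

    def test_saturating_qtls_give_p_one(self):
        qtls = RegionSet.from_records(
            [(c, 1, length, "q") for c, length in self.lengths.items()]
        )
        regions = RegionSet.from_records([("1", 100, 50_099, "r")])
        test = qtl_overlap_permutation(regions, qtls, self.lengths, n_perm=200, seed=0)
        assert test.observed_overlap_mb == pytest.approx(0.05)
        assert test.p_value == 1.0
        assert test.null_sd == 0.0

    def test_null_mean_matches_coverage_expectation(self):
        """Uniform placement: E[overlap] = q * total region Mb."""
        rng = np.random.default_rng(2)
        qtls = RegionSet.from_records(
            [("1", s, s + 499_999, f"q{i}") for i, s in enumerate(range(1, 10**7, 10**6))]
        )  # covers 5 Mb of 20 Mb -> q = 0.25
        regions = RegionSet.from_records(
            [("2", 1 + k * 200_000, k * 200_000 + 40_000, f"r{k}") for k in range(10)]
        )
        test = qtl_overlap_permutation(regions, qtls, self.lengths, n_perm=1000, seed=3)
        expected = 0.25 * regions.total_length() / 1e6
        assert abs(test.null_mean - expected) < 3 * test.null_sd

    def test_engineered_containment_is_significant(self):
        qtls = RegionSet.from_records(
            [("1", 1, 1_000_000, "q1"), ("2", 1, 1_000_000, "q2")]
        )  # 10% of genome
        regions = RegionSet.from_records(
            [("1", 1000 + k * 60_000, 50_999 + k * 60_000, f"r{k}") for k in range(10)]
        )
        test = qtl_overlap_permutation(regions, qtls, self.lengths, n_perm=1000, seed=4)
        assert test.p_value <= 0.01

    def test_seeded_reproducibility_and_p_bounds(self):
        qtls = RegionSet.from_records([("1", 1, 2_000_000, "q")])
        regions = RegionSet.from_records([("1", 5_000_000, 5_050_000, "r")])
        a = qtl_overlap_permutation(regions, qtls, self.lengths, n_perm=500, seed=7)
        b = qtl_overlap_permutation(regions, qtls, self.lengths, n_perm=500, seed=7)
        assert a.to_dict() == b.to_dict()
        assert 1 / 501 <= a.p_value <= 1.0

    def test_per_chromosome_mode_stays_on_chromosome(self):
        qtls = RegionSet.from_records([("2", 1, 10_000_000, "q")])
        regions = RegionSet.from_records([("1", 1, 100_000, "r")])
        test = qtl_overlap_permutation(
            regions, qtls, self.lengths, n_perm=100, seed=5, per_chromosome=True
        )
        # region never leaves chromosome 1, which holds no QTL
        assert test.null_mean == 0.0 and test.observed_overlap_mb == 0.0

    def test_oversized_region_rejected(self):
        qtls = RegionSet.from_records([("1", 1, 100, "q")])
        regions = RegionSet.from_records([("1", 1, 10_000_001, "r")])
        with pytest.raises(ValueError, match="longer"):
            qtl_overlap_permutation(
                regions, qtls, {"1": 10_000_000}, n_perm=10, seed=0
            )

    def test_overlap_statistic_counts_bases_once(self):
        # two QTLs double-covering the same region: still 0.01 Mb
        qtls = RegionSet.from_records([("1", 1, 20_000, "a"), ("1", 5_000, 15_000, "b")])
        regions = RegionSet.from_records([("1", 1, 10_000, "r")])
        assert region_qtl_overlap_bp(regions, qtls, self.lengths) == 10_000
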