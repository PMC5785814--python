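"""Weir-Cockerham components, weighted Fst, and the sliding-window machinery.

The independent oracle used throughout is straight-line scalar arithmetic
written directly from the two-population diploid estimator definitions,
kept deliberately separate from the vectorized implementation.
"""

import numpy as np
import pandas as pd
import pytest

from sweepscan.containers import PopulationAssignment
from sweepscan.fst_scan import (
    SiteCounts,
    compute_site_components,
    compute_site_counts,
    genome_weighted_fst,
    site_components_table,
    sliding_window_fst,
    weighted_fst,
)
from sweepscan.synthetic_data import SimulationConfig, simulate_cohort

from .conftest import two_pop_assignment


def oracle_components(n1, n2, p1, p2, h1, h2):
    """Independent scalar evaluation of the two-population diploid estimator."""
    r = 2
    nbar = (n1 + n2) / 2
    nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (1.0 / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
    )
    c = hbar / 2
    return a, b, c


class TestSiteCounts:
    def test_fixed_difference_counts(self):
        samples = [f"s{i}" for i in range(28)]
        geno = np.array([2] * 14 + [0] * 14, dtype=np.int8)
        counts = compute_site_counts(geno, samples, two_pop_assignment(samples))
        assert (counts.n1, counts.n2) == (14, 14)
        assert (counts.p1, counts.p2, counts.h1, counts.h2) == (1.0, 0.0, 0.0, 0.0)

    def test_het_hom_mix(self):
        samples = [f"s{i}" for i in range(28)]
        geno = np.array([1] * 7 + [0] * 7 + [0] * 14, dtype=np.int8)
        counts = compute_site_counts(geno, samples, two_pop_assignment(samples))
        assert counts.p1 == 0.25 and counts.h1 == 0.5

    def test_population_below_minimum_is_skipped(self):
        samples = [f"s{i}" for i in range(4)]
        geno = np.array([1, 1, -1, -1], dtype=np.int8)
        with pytest.raises(ValueError, match="skipped"):
            compute_site_counts(geno, samples, two_pop_assignment(samples))


class TestComponents:
    @pytest.mark.parametrize("n", [2, 5, 14, 50])
    def test_fixed_difference_gives_fst_one(self, n):
        comp = compute_site_components(
            SiteCounts(n1=n, n2=n, p1=1.0, p2=0.0, h1=0.0, h2=0.0)
        )
        assert comp.fst == pytest.approx(1.0, abs=1e-14)

    @pytest.mark.parametrize("n,p", [(14, 0.3), (14, 0.5), (10, 0.1), (3, 0.7)])
    def test_identical_hwe_populations_closed_form(self, n, p):
        """Equal-n identical populations at HWE: Fst = -1/(2(n-1)) exactly."""
        h = 2 * p * (1 - p)
        comp = compute_site_components(SiteCounts(n1=n, n2=n, p1=p, p2=p, h1=h, h2=h))
        assert comp.fst == pytest.approx(-1 / (2 * (n - 1)), abs=1e-12)

    def test_hand_arithmetic_example(self):
        comp = compute_site_components(
            SiteCounts(n1=10, n2=4, p1=0.8, p2=0.25, h1=0.2, h2=0.3)
        )
        a, b, c = oracle_components(10, 4, 0.8, 0.25, 0.2, 0.3)
        assert comp.a == pytest.approx(a, abs=1e-14)
        assert comp.b == pytest.approx(b, abs=1e-14)
        assert comp.c == pytest.approx(c, abs=1e-14)

    def test_agreement_with_oracle_on_random_sites(self):
        """<= 1e-10 absolute agreement on 1000 random admissible sites."""
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n1, n2 = rng.integers(2, 15, size=2)
            p1, p2 = rng.uniform(0, 1, size=2)
            h1 = rng.uniform(0, 2 * min(p1, 1 - p1))
            h2 = rng.uniform(0, 2 * min(p2, 1 - p2))
            comp = compute_site_components(
                SiteCounts(n1=int(n1), n2=int(n2), p1=p1, p2=p2, h1=h1, h2=h2)
            )
            a, b, c = oracle_components(n1, n2, p1, p2, h1, h2)
            assert abs(comp.a - a) <= 1e-10
            assert abs(comp.b - b) <= 1e-10
            assert abs(comp.c - c) <= 1e-10

    def test_monomorphic_site_components_are_zero(self):
        comp = compute_site_components(
            SiteCounts(n1=14, n2=14, p1=0.0, p2=0.0, h1=0.0, h2=0.0)
        )
        assert comp.a == 0 and comp.b == 0 and comp.c == 0

    def test_population_label_symmetry(self):
        comp = compute_site_components(
            SiteCounts(n1=9, n2=13, p1=0.4, p2=0.9, h1=0.3, h2=0.1)
        )
        swapped = compute_site_components(
            SiteCounts(n1=13, n2=9, p1=0.9, p2=0.4, h1=0.1, h2=0.3)
        )
        assert comp.a == pytest.approx(swapped.a, abs=1e-14)
        assert comp.b == pytest.approx(swapped.b, abs=1e-14)
        assert comp.c == pytest.approx(swapped.c, abs=1e-14)

    def test_per_site_fst_never_exceeds_one(self):
        rng = np.random.default_rng(1)
        for _ in range(500):
            n1, n2 = rng.integers(2, 20, size=2)
            p1, p2 = rng.uniform(0, 1, size=2)
            h1 = rng.uniform(0, 2 * min(p1, 1 - p1))
            h2 = rng.uniform(0, 2 * min(p2, 1 - p2))
            comp = compute_site_components(
                SiteCounts(n1=int(n1), n2=int(n2), p1=p1, p2=p2, h1=h1, h2=h2)
            )
            if comp.a + comp.b + comp.c != 0:
                assert comp.fst <= 1 + 1e-12


class TestWeightedFst:
    def test_single_fixed_difference(self):
        assert weighted_fst(np.array([0.5]), np.array([0.0]), np.array([0.0])) == 1.0

    def test_cancellation(self):
        a = np.array([0.3, -0.3])
        b = np.zeros(2)
        c = np.array([0.0, 0.6])
        assert weighted_fst(a, b, c) == 0.0

    def test_all_monomorphic_undefined(self):
        with pytest.raises(ValueError):
            weighted_fst(np.zeros(3), np.zeros(3), np.zeros(3))

    def test_recovery_of_simulated_f(self):
        """200 BN sites at F=0.25, n=14+14: within 0.05 of truth over 20 seeds."""
        for seed in range(20):
            rng = np.random.default_rng(seed)
            p_anc = rng.uniform(0.1, 0.9, size=200)
            shape = 0.25
            a_par = p_anc * (1 - shape) / shape
            b_par = (1 - p_anc) * (1 - shape) / shape
            p1 = rng.beta(a_par, b_par)
            p2 = rng.beta(a_par, b_par)
            g1 = rng.binomial(2, p1[:, None], size=(200, 14))
            g2 = rng.binomial(2, p2[:, None], size=(200, 14))
            from sweepscan.fst_scan import wc_components

            def pop_counts(g):
                n = np.full(200, 14)
                p = g.sum(axis=1) / 28
                h = (g == 1).mean(axis=1)
                return n, p, h

            n1, pp1, h1 = pop_counts(g1)
            n2, pp2, h2 = pop_counts(g2)
            a, b, c = wc_components(n1, n2, pp1, pp2, h1, h2)
            assert weighted_fst(a, b, c) == pytest.approx(0.25, abs=0.05)

    def test_random_split_of_one_population_is_unbiased_at_zero(self):
        """Random halves of one HWE population estimate theta = 0 on average.

        (The -1/(2(n-1)) closed form is the plug-in value when the two
        samples have *identical* observed frequencies; over random splits
        the estimator is unbiased for zero.)
        """
        rng = np.random.default_rng(3)
        estimates = []
        for _ in range(20):
            p = rng.uniform(0.2, 0.8, size=300)
            g = rng.binomial(2, p[:, None], size=(300, 28)).astype(np.int8)
            perm = rng.permutation(28)
            g1, g2 = g[:, perm[:14]], g[:, perm[14:]]
            from sweepscan.fst_scan import wc_components

            def pc(gm):
                return (
                    np.full(300, 14),
                    gm.sum(axis=1) / 28,
                    (gm == 1).mean(axis=1),
                )

            n1, p1, h1 = pc(g1)
            n2, p2, h2 = pc(g2)
            a, b, c = wc_components(n1, n2, p1, p2, h1, h2)
            estimates.append(weighted_fst(a, b, c))
        assert np.mean(estimates) == pytest.approx(0.0, abs=0.01)


class TestSlidingWindows:
    def _components(self, positions, chrom="1"):
        n = len(positions)
        return pd.DataFrame(
            {
                "chrom": chrom,
                "pos": positions,
                "var_class": "SNP",
                "a": np.full(n, 0.1),
                "b": np.zeros(n),
                "c": np.full(n, 0.1),
                "fst": np.full(n, 0.5),
                "polymorphic": True,
            }
        )

    def test_leading_sites_fall_in_first_window_only(self):
        comp = self._components(list(range(1, 11)))
        w = sliding_window_fst(comp, {"1": 30_000}, 20_000, 10_000, min_markers=1)
        assert list(w["start"]) == [1, 10_001, 20_001]
        assert list(w["n_markers"]) == [10, 0, 0]
        assert w.loc[0, "weighted_fst"] == pytest.approx(0.5)

    def test_interior_site_in_exactly_two_windows(self):
        comp = self._components([15_000])
        w = sliding_window_fst(comp, {"1": 30_000}, 20_000, 10_000, min_markers=1)
        member = w[w["n_markers"] > 0]
        assert list(member["start"]) == [1, 10_001]

    def test_marker_count_conservation(self):
        """Sum of window marker counts equals a brute-force membership recount."""
        rng = np.random.default_rng(4)
        positions = np.sort(rng.choice(np.arange(1, 100_001), size=400, replace=False))
        comp = self._components(positions)
        w = sliding_window_fst(comp, {"1": 100_000}, 20_000, 10_000, min_markers=1)
        brute = 0
        for start, end in zip(w["start"], w["end"]):
            brute += ((positions >= start) & (positions <= end)).sum()
        assert w["n_markers"].sum() == brute

    def test_terminal_window_truncated(self):
        comp = self._components([5])
        w = sliding_window_fst(comp, {"1": 25_000}, 20_000, 10_000, min_markers=1)
        assert list(w["end"]) == [20_000, 25_000, 25_000]

    def test_min_marker_gating(self):
        comp = self._components(list(range(1000, 1000 + 9)))
        w = sliding_window_fst(comp, {"1": 20_000}, 20_000, 10_000, min_markers=10)
        assert not w["qualifies"].any()
        assert w["weighted_fst"].isna().all()

    def test_bad_geometry_rejected(self):
        comp = self._components([100])
        with pytest.raises(ValueError):
            sliding_window_fst(comp, {"1": 10_000}, 5_000, 10_000, 1)
        with pytest.raises(ValueError, match="without a length"):
            sliding_window_fst(comp, {"2": 10_000}, 20_000, 10_000, 1)


class TestEndToEndEstimation:
    def test_genome_weighted_fst_tracks_truth(self):
        config = SimulationConfig(
            seed=21,
            chrom_lengths={"1": 400_000},
            snp_density=8,
            indel_density=1,
            background_fst=0.25,
            missing_rate=0.0,
            fail_fraction=0.0,
        )
        table, pops, *_ = simulate_cohort(config)
        comp = site_components_table(table, pops)
        assert genome_weighted_fst(comp) == pytest.approx(0.25, abs=0.03)

    def test_sites_with_missing_population_skipped(self):
        samples = [f"s{i}" for i in range(4)]
        geno = np.array([[1, 1, -1, -1], [1, 0, 1, 2]], dtype=np.int8)
        from .conftest import make_variants

        vt = make_variants([{"pos": 10}, {"pos": 20}], genotypes=geno, samples=samples)
        comp = site_components_table(vt, two_pop_assignment(samples))
        assert len(comp) == 1 and comp.iloc[0]["pos"] == 20
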