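"""Synthetic two-population cohorts with known differentiation structure.

The generator emulates a joint variant call on two selected lines of 14
diploid individuals each.  Population allele frequencies follow the
Balding-Nichols model: given an ancestral frequency ``p`` and a
differentiation parameter ``F``, each population's frequency is an
independent draw from ``Beta(p(1-F)/F, (1-p)(1-F)/F)``, which has mean ``p``
and variance ``F p (1-p)`` — exactly the quantity the Weir-Cockerham
estimator targets.  Injected sweep intervals carry a higher ``F`` than the
genomic background, producing localized differentiation peaks.

Per-site nuisance fields (QUAL, aggregate depth, DP4 strand counts) are
drawn so that every non-engineered site passes the default filtration
criteria; a configurable fraction of sites is engineered to violate exactly
one named filter rule each, recorded in the :class:`TruthTable` so the
filtration stage can be checked for exactness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    HET,
    INDEL,
    SITE_COLUMNS,
    SNP,
    PopulationAssignment,
    RegionSet,
    VariantTable,
)
from .filtration import (
    RULE_ALT_READS,
    RULE_INDEL_CLUSTER,
    RULE_MAX_DEPTH,
    RULE_MIN_DEPTH,
    RULE_QUALITY,
    RULE_SNP_CLUSTER,
    RULE_STRAND,
)

_BASES = np.array(["A", "C", "G", "T"])
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


@dataclass
class SimulationConfig:
    """Parameters of the two-population cohort simulation.

    Defaults reflect the study system the package models: two chicken lines
    (a paternal broiler line and a white-egg layer line) of 14 diploid
    individuals each, genome-wide densities of 16.84 SNPs/kb and 1.72
    INDELs/kb, aggregate (28-sample) site depth around 314x, a transition
    fraction giving TS/TV near 2.3, and background differentiation near the
    genome-wide mean weighted Fst of ~0.28 observed between such lines.  The
    genome itself is scaled down to a few megabases so that a full simulation
    runs in seconds.
    """

    seed: int = 0
    n_per_pop: int = 14
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"1": 2_000_000, "2": 1_000_000}
    )
    snp_density: float = 16.84  # expected SNPs per kb
    indel_density: float = 1.72  # expected INDELs per kb
    background_fst: float = 0.28
    sweep_intervals: tuple = ()  # (chrom, start, end, sweep_fst), 1-based inclusive
    ancestral_freq_law: tuple = ("uniform", 0.05, 0.95)  # or ("beta", a, b)
    depth_mean: float = 313.6  # aggregate depth over 28 samples at ~11.2x each
    depth_sd: float = 60.0
    qual_mean: float = 150.0
    qual_sd: float = 60.0
    ts_fraction: float = 0.7  # transition probability per SNP (TS/TV ~ 2.33)
    missing_rate: float = 0.02
    fail_fraction: float = 0.01  # per filter rule
    gene_density_per_mb: float = 10.0
    gene_length_range: tuple[int, int] = (5_000, 50_000)
    n_qtls: int = 30
    qtl_length_range: tuple[int, int] = (100_000, 1_000_000)
    qtl_sweep_enrichment: float = 0.0  # fraction of QTLs forced to overlap a sweep
    pop_labels: tuple[str, str] = ("broiler", "layer")

    def validate(self) -> None:
        if not 0 < self.background_fst < 1:
            raise ValueError("background_fst must lie in (0, 1)")
        if self.snp_density <= 0 or self.indel_density <= 0:
            raise ValueError("densities must be positive")
        for chrom, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"zero/negative length for chromosome {chrom}")
        for chrom, start, end, fst in self.sweep_intervals:
            if chrom not in self.chrom_lengths:
                raise ValueError(f"sweep on unknown chromosome {chrom}")
            if not 1 <= start <= end <= self.chrom_lengths[chrom]:
                raise ValueError(f"sweep {chrom}:{start}-{end} outside chromosome")
            if not self.background_fst < fst < 1:
                raise ValueError("sweep_fst must satisfy background_fst < fst < 1")
        if not 0 <= self.missing_rate < 1 or not 0 <= self.fail_fraction < 1:
            raise ValueError("missing_rate and fail_fraction must lie in [0, 1)")


@dataclass
class TruthTable:
    """Ground truth for every emitted variant plus the sweep layout.

    ``sites`` columns: chrom, pos, var_class, p_anc, p_pop1, p_pop2, F_used,
    fail_rule ("" for clean sites).  ``F_used`` equals the background Fst
    outside sweeps and the sweep Fst inside.
    """

    sites: pd.DataFrame
    sweep_intervals: tuple

    def write(self, path: str) -> None:
        self.sites.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str, sweep_intervals: tuple = ()) -> "TruthTable":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        df["fail_rule"] = df["fail_rule"].fillna("")
        return cls(sites=df, sweep_intervals=sweep_intervals)


def draw_population_freqs(
    p_anc: float, F: float, rng: np.random.Generator
) -> tuple[float, float]:
    """Draw the two population allele frequencies under Balding-Nichols.

    Both frequencies are independent ``Beta(p(1-F)/F, (1-p)(1-F)/F)`` draws
    with mean ``p_anc`` and variance ``F * p_anc * (1 - p_anc)``.
    """
    if not 0 < F < 1:
        raise ValueError(f"F must lie in (0, 1), got {F}")
    if not 0 < p_anc < 1:
        raise ValueError(f"p_anc must lie in (0, 1), got {p_anc}")
    a = p_anc * (1 - F) / F
    b = (1 - p_anc) * (1 - F) / F
    return float(rng.beta(a, b)), float(rng.beta(a, b))


def _draw_freqs(
    p_anc: np.ndarray, F: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    a = p_anc * (1 - F) / F
    b = (1 - p_anc) * (1 - F) / F
    return rng.beta(a, b)


def make_sweep_intervals(
    chrom_lengths: Mapping[str, int],
    coverage: float = 0.01,
    sweep_fst: float = 0.8,
    sweep_length: int = 100_000,
    rng: np.random.Generator | None = None,
) -> tuple:
    """Lay out non-overlapping sweep intervals covering ~``coverage`` of the genome."""
    rng = rng or np.random.default_rng(0)
    total = sum(chrom_lengths.values())
    n_sweeps = max(1, int(round(coverage * total / sweep_length)))
    chroms = list(chrom_lengths)
    weights = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    out: list[tuple] = []
    for _ in range(n_sweeps):
        for _attempt in range(200):
            chrom = chroms[rng.choice(len(chroms), p=weights)]
            L = chrom_lengths[chrom]
            if L < sweep_length:
                continue
            start = int(rng.integers(1, L - sweep_length + 2))
            end = start + sweep_length - 1
            if all(
                c != chrom or end < s - sweep_length or start > e + sweep_length
                for c, s, e, _f in out
            ):
                out.append((chrom, start, end, sweep_fst))
                break
    return tuple(out)


def _sample_positions(rng: np.random.Generator, length: int, n: int) -> np.ndarray:
    """Approximately-Poisson unique sorted positions in [1, length]."""
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    return np.unique(rng.integers(1, length + 1, size=n))


def _thin_min_gap(pos: np.ndarray, min_gap: int) -> np.ndarray:
    """Greedy thinning so consecutive positions differ by at least min_gap."""
    if len(pos) == 0:
        return pos
    keep = [pos[0]]
    for p in pos[1:]:
        if p - keep[-1] >= min_gap:
            keep.append(p)
    return np.asarray(keep, dtype=np.int64)


def _find_free_spot(
    rng: np.random.Generator,
    length: int,
    occupied: np.ndarray,
    span: int,
    clearance: int,
) -> int | None:
    """Random start q such that [q-clearance, q+span+clearance] holds no occupied position."""
    lo, hi = clearance + 1, length - span - clearance
    if hi <= lo:
        return None
    for _ in range(200):
        q = int(rng.integers(lo, hi + 1))
        left = np.searchsorted(occupied, q - clearance)
        right = np.searchsorted(occupied, q + span + clearance, side="right")
        if left == right:
            return q
    return None


def _random_snp_alleles(
    rng: np.random.Generator, n: int, ts_fraction: float
) -> tuple[np.ndarray, np.ndarray]:
    ref = _BASES[rng.integers(0, 4, size=n)]
    is_ts = rng.random(n) < ts_fraction
    alt = np.empty(n, dtype=object)
    for i in range(n):
        r = ref[i]
        if is_ts[i]:
            alt[i] = _TRANSITION[r]
        else:
            choices = [b for b in "ACGT" if b != r and b != _TRANSITION[r]]
            alt[i] = choices[int(rng.integers(0, 2))]
    return ref.astype(object), alt


def _random_indel_alleles(
    rng: np.random.Generator, n: int
) -> tuple[np.ndarray, np.ndarray]:
    ref = np.empty(n, dtype=object)
    alt = np.empty(n, dtype=object)
    lengths = rng.geometric(0.5, size=n).clip(max=6)
    is_ins = rng.random(n) < 0.5
    for i in range(n):
        anchor = str(_BASES[rng.integers(0, 4)])
        tail = "".join(_BASES[rng.integers(0, 4, size=int(lengths[i]))])
        if is_ins[i]:
            ref[i], alt[i] = anchor, anchor + tail
        else:
            ref[i], alt[i] = anchor + tail, anchor
    return ref, alt


def _place_sites(
    config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Choose positions, classes and engineered fail labels for every site."""
    frames = []
    for chrom, length in config.chrom_lengths.items():
        n_snp = rng.poisson(length / 1000 * config.snp_density)
        n_indel = rng.poisson(length / 1000 * config.indel_density)
        snp_pos = _sample_positions(rng, length, n_snp)
        indel_pos = _thin_min_gap(_sample_positions(rng, length, n_indel), 5)
        indel_pos = indel_pos[~np.isin(indel_pos, snp_pos)]

        labels_snp = np.full(len(snp_pos), "", dtype=object)
        labels_indel = np.full(len(indel_pos), "", dtype=object)

        extra_pos: list[int] = []
        extra_class: list[str] = []
        extra_label: list[str] = []
        if config.fail_fraction > 0:
            occupied = np.sort(np.concatenate([snp_pos, indel_pos]))
            # SNP clusters: 11 SNPs at consecutive positions (span 11 bp <= 50)
            target_snp = int(round(config.fail_fraction * len(snp_pos)))
            n_clusters = max(1, target_snp // 11) if target_snp >= 1 else 0
            for _ in range(n_clusters):
                q = _find_free_spot(rng, length, occupied, span=11, clearance=60)
                if q is None:
                    continue
                cluster = list(range(q, q + 11))
                extra_pos += cluster
                extra_class += [SNP] * 11
                extra_label += [RULE_SNP_CLUSTER] * 11
                occupied = np.sort(np.concatenate([occupied, cluster]))
            # INDEL cluster pairs: starts 2 bp apart (one intervening base)
            target_ind = int(round(config.fail_fraction * len(indel_pos)))
            n_pairs = max(1, target_ind // 2) if target_ind >= 1 else 0
            for _ in range(n_pairs):
                q = _find_free_spot(rng, length, occupied, span=3, clearance=12)
                if q is None:
                    continue
                extra_pos += [q, q + 2]
                extra_class += [INDEL] * 2
                extra_label += [RULE_INDEL_CLUSTER] * 2
                occupied = np.sort(np.concatenate([occupied, [q, q + 2]]))

        df = pd.DataFrame(
            {
                "chrom": chrom,
                "pos": np.concatenate(
                    [snp_pos, indel_pos, np.asarray(extra_pos, dtype=np.int64)]
                ),
                "var_class": (
                    [SNP] * len(snp_pos) + [INDEL] * len(indel_pos) + extra_class
                ),
                "fail_rule": np.concatenate(
                    [labels_snp, labels_indel, np.asarray(extra_label, dtype=object)]
                ),
            }
        )
        frames.append(df.sort_values("pos"))
    sites = pd.concat(frames, ignore_index=True)
    # engineered single-field failures among currently-clean sites
    if config.fail_fraction > 0 and len(sites):
        k = max(1, int(round(config.fail_fraction * len(sites))))
        clean = np.flatnonzero((sites["fail_rule"] == "").to_numpy())
        rules = [RULE_QUALITY, RULE_MIN_DEPTH, RULE_MAX_DEPTH, RULE_STRAND, RULE_ALT_READS]
        picks = rng.choice(clean, size=min(len(clean), k * len(rules)), replace=False)
        col = sites.columns.get_loc("fail_rule")
        for j, idx in enumerate(picks):
            sites.iloc[idx, col] = rules[j % len(rules)]
    return sites.reset_index(drop=True)


def _truncnorm_int(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int
) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    draws = stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)
    return np.round(draws).astype(np.int64)


def _interval_tracks(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[RegionSet, RegionSet]:
    chroms = list(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    weights = lengths / lengths.sum()

    def _uniform_intervals(n: int, len_range: tuple[int, int], prefix: str):
        rows = []
        for i in range(n):
            ci = rng.choice(len(chroms), p=weights)
            L = int(lengths[ci])
            ln = int(rng.integers(len_range[0], len_range[1] + 1))
            ln = min(ln, L)
            start = int(rng.integers(1, L - ln + 2))
            rows.append((chroms[ci], start, start + ln - 1, f"{prefix}_{i:04d}"))
        return rows

    n_genes = int(round(config.gene_density_per_mb * lengths.sum() / 1e6))
    genes = RegionSet.from_records(
        _uniform_intervals(n_genes, config.gene_length_range, "gene")
    )

    n_enriched = (
        int(round(config.qtl_sweep_enrichment * config.n_qtls))
        if config.sweep_intervals
        else 0
    )
    rows = _uniform_intervals(config.n_qtls - n_enriched, config.qtl_length_range, "qtl")
    for i in range(n_enriched):
        chrom, s, e, _f = config.sweep_intervals[
            int(rng.integers(0, len(config.sweep_intervals)))
        ]
        L = config.chrom_lengths[chrom]
        ln = int(rng.integers(*config.qtl_length_range))
        ln = min(ln, L)
        lo = max(1, s - ln + 1)
        hi = min(e, L - ln + 1)
        start = int(rng.integers(lo, max(lo, hi) + 1))
        rows.append((chrom, start, start + ln - 1, f"qtl_sweep_{i:04d}"))
    qtls = RegionSet.from_records(rows)
    return genes, qtls


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[VariantTable, PopulationAssignment, TruthTable, RegionSet, RegionSet]:
    """Generate a full synthetic cohort.

    Returns the variant table (sorted by chrom, pos), the two-population
    sample assignment, the per-site truth table, and gene/QTL interval
    tracks.  Sites at which no alternate allele was drawn in any individual
    are not emitted (a joint caller only reports sites with variant
    evidence).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    sites = _place_sites(config, rng)
    n = len(sites)
    samples = [
        f"{config.pop_labels[0]}_{i + 1:02d}" for i in range(config.n_per_pop)
    ] + [f"{config.pop_labels[1]}_{i + 1:02d}" for i in range(config.n_per_pop)]
    assignment = PopulationAssignment(
        {s: config.pop_labels[0] for s in samples[: config.n_per_pop]}
        | {s: config.pop_labels[1] for s in samples[config.n_per_pop :]}
    )
    if n == 0:
        warnings.warn("configured densities produced zero sites", stacklevel=2)
        empty = pd.DataFrame(columns=SITE_COLUMNS)
        return (
            VariantTable(empty, np.empty((0, len(samples)), dtype=np.int8), samples),
            assignment,
            TruthTable(
                pd.DataFrame(
                    columns=[
                        "chrom", "pos", "var_class", "p_anc",
                        "p_pop1", "p_pop2", "F_used", "fail_rule",
                    ]
                ),
                config.sweep_intervals,
            ),
            *_interval_tracks(config, rng),
        )

    # ancestral frequencies and per-site F
    law = config.ancestral_freq_law
    if law[0] == "uniform":
        p_anc = rng.uniform(law[1], law[2], size=n)
    elif law[0] == "beta":
        p_anc = rng.beta(law[1], law[2], size=n).clip(1e-6, 1 - 1e-6)
    else:
        raise ValueError(f"unknown ancestral_freq_law {law[0]!r}")
    F = np.full(n, config.background_fst)
    chrom_arr = sites["chrom"].to_numpy()
    pos_arr = sites["pos"].to_numpy()
    for chrom, s, e, fst in config.sweep_intervals:
        F[(chrom_arr == chrom) & (pos_arr >= s) & (pos_arr <= e)] = fst
    p1 = _draw_freqs(p_anc, F, rng)
    p2 = _draw_freqs(p_anc, F, rng)

    # Hardy-Weinberg genotypes within each population
    npp = config.n_per_pop
    geno = np.empty((n, 2 * npp), dtype=np.int8)
    geno[:, :npp] = rng.binomial(2, p1[:, None], size=(n, npp))
    geno[:, npp:] = rng.binomial(2, p2[:, None], size=(n, npp))
    if config.missing_rate > 0:
        geno[rng.random(geno.shape) < config.missing_rate] = -1

    # engineered-fail sites must stay polymorphic so their truth label is testable
    fail = sites["fail_rule"].to_numpy()
    engineered = np.flatnonzero(fail != "")
    alt_count = ((geno == 1).sum(axis=1) + 2 * (geno == 2).sum(axis=1)).astype(np.int64)
    for i in engineered[alt_count[engineered] == 0]:
        geno[i, 0] = HET
    alt_count = (geno == 1).sum(axis=1) + 2 * (geno == 2).sum(axis=1)

    keep = alt_count > 0
    sites = sites.loc[keep].reset_index(drop=True)
    geno = geno[keep]
    p_anc, F, p1, p2 = p_anc[keep], F[keep], p1[keep], p2[keep]
    fail = fail[keep]
    alt_count = alt_count[keep]
    n = len(sites)

    # nuisance fields: clean sites are guaranteed to pass the default filters
    qual = stats.truncnorm.rvs(
        (40.0 - config.qual_mean) / config.qual_sd,
        np.inf,
        loc=config.qual_mean,
        scale=config.qual_sd,
        size=n,
        random_state=rng,
    )
    depth_lo = max(8.0, config.depth_mean - 2.5 * config.depth_sd)
    depth = _truncnorm_int(
        rng, config.depth_mean, config.depth_sd, depth_lo,
        config.depth_mean + 2.5 * config.depth_sd, n,
    )
    non_missing = (geno >= 0).sum(axis=1)
    aaf = alt_count / np.maximum(1, 2 * non_missing)
    alt_total = np.clip(rng.binomial(depth, aaf.clip(0.08, 0.92)), 3, depth)
    alt_fwd = 1 + rng.binomial(alt_total - 2, 0.5)
    alt_rev = alt_total - alt_fwd
    ref_total = depth - alt_total
    ref_fwd = rng.binomial(ref_total, 0.5)
    ref_rev = ref_total - ref_fwd

    # per-rule field overrides (each engineered site violates exactly one rule)
    def _idx(rule: str) -> np.ndarray:
        return np.flatnonzero(fail == rule)

    i = _idx(RULE_QUALITY)
    qual[i] = rng.uniform(5.0, 39.5, size=len(i))
    i = _idx(RULE_MIN_DEPTH)
    depth[i] = rng.integers(3, 5, size=len(i))
    alt_total[i], alt_fwd[i], alt_rev[i] = 3, 1, 2
    ref_fwd[i], ref_rev[i] = depth[i] - 3, 0
    i = _idx(RULE_MAX_DEPTH)
    depth[i] = np.round(
        config.depth_mean + rng.uniform(8, 12, size=len(i)) * config.depth_sd
    ).astype(np.int64)
    alt_total[i] = depth[i] // 2
    alt_fwd[i] = 1 + rng.binomial(alt_total[i] - 2, 0.5)
    alt_rev[i] = alt_total[i] - alt_fwd[i]
    ref_fwd[i], ref_rev[i] = depth[i] - alt_total[i], 0
    i = _idx(RULE_STRAND)
    alt_rev[i] = alt_fwd[i] + alt_rev[i]
    alt_fwd[i] = 0
    i = _idx(RULE_ALT_READS)
    alt_fwd[i], alt_rev[i] = 1, 1
    ref_fwd[i], ref_rev[i] = depth[i] - 2, 0

    is_snp = (sites["var_class"] == SNP).to_numpy()
    ref = np.empty(n, dtype=object)
    alt = np.empty(n, dtype=object)
    ref[is_snp], alt[is_snp] = _random_snp_alleles(
        rng, int(is_snp.sum()), config.ts_fraction
    )
    ref[~is_snp], alt[~is_snp] = _random_indel_alleles(rng, int((~is_snp).sum()))

    site_df = pd.DataFrame(
        {
            "chrom": sites["chrom"],
            "pos": sites["pos"].astype(np.int64),
            "ref": ref,
            "alt": alt,
            "var_class": sites["var_class"],
            "qual": np.round(qual, 2),
            "total_depth": depth,
            "ref_fwd": ref_fwd,
            "ref_rev": ref_rev,
            "alt_fwd": alt_fwd,
            "alt_rev": alt_rev,
        }
    )
    table = VariantTable(site_df, geno, samples).sort()
    order = (
        sites.assign(_i=np.arange(n))
        .sort_values(["chrom", "pos"], kind="mergesort")["_i"]
        .to_numpy()
    )
    truth = TruthTable(
        pd.DataFrame(
            {
                "chrom": sites["chrom"].to_numpy()[order],
                "pos": sites["pos"].to_numpy()[order],
                "var_class": sites["var_class"].to_numpy()[order],
                "p_anc": p_anc[order],
                "p_pop1": p1[order],
                "p_pop2": p2[order],
                "F_used": F[order],
                "fail_rule": fail[order],
            }
        ),
        config.sweep_intervals,
    )
    genes, qtls = _interval_tracks(config, rng)
    return table, assignment, truth, genes, qtls
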