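"""Candidate-region calling and downstream region statistics.

Covers: top-percentile window selection (ties included at the cutoff),
union of adjacent/overlapping selected windows into candidate regions,
correlation of SNP- and INDEL-based window scans, gene annotation of
regions, and a permutation test for QTL overlap.

The permutation test fixes the QTL annotation and re-places each candidate
region uniformly at random (length preserved; chromosome drawn with
probability proportional to its length among chromosomes that can hold the
region; placed regions may overlap each other).  The statistic is the
total genomic size (Mb) of the regions covered by the union of QTL
intervals, counting each region base once.  The p-value uses the add-one
empirical formula (1 + #{null >= observed}) / (1 + n_perm), which cannot
be zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .containers import RegionSet


@dataclass
class ThresholdResult:
    level: float  # quantile level, e.g. 0.99
    cutoff: float  # smallest weighted Fst among the selected windows
    windows: pd.DataFrame  # selected rows of the window table


@dataclass
class OverlapTest:
    observed_overlap_mb: float
    null_mean: float
    null_sd: float
    n_permutations: int
    p_value: float

    def to_dict(self) -> dict:
        return {
            "observed_overlap_mb": self.observed_overlap_mb,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "n_permutations": self.n_permutations,
            "p_value": self.p_value,
        }


def percentile_select(windows: pd.DataFrame, level: float) -> ThresholdResult:
    """Select the top (1 - level) fraction of qualifying windows, ties included.

    The cutoff is the smallest weighted Fst among the top
    ``ceil((1 - level) * N)`` qualifying windows; every window at or above
    the cutoff is selected, so the result never depends on sort order.
    """
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    qual = windows[windows["qualifies"] & windows["weighted_fst"].notna()]
    if not len(qual):
        raise ValueError("no qualifying windows")
    k = int(np.ceil((1 - level) * len(qual) - 1e-9))
    k = max(k, 1)
    top_values = np.sort(qual["weighted_fst"].to_numpy())[::-1]
    cutoff = float(top_values[k - 1])
    selected = qual[qual["weighted_fst"] >= cutoff]
    return ThresholdResult(level=level, cutoff=cutoff, windows=selected.copy())


def merge_windows(selected: pd.DataFrame) -> RegionSet:
    """Union overlapping or book-ended selected windows into maximal regions."""
    if not len(selected):
        return RegionSet(pd.DataFrame(columns=["chrom", "start", "end", "label"]))
    rows = []
    ordered = selected.sort_values(["chrom", "start", "end"])
    cur = None
    for chrom, start, end in ordered[["chrom", "start", "end"]].itertuples(index=False):
        if cur is not None and chrom == cur[0] and start <= cur[2] + 1:
            cur[2] = max(cur[2], end)
        else:
            if cur is not None:
                rows.append(tuple(cur))
            cur = [chrom, int(start), int(end)]
    rows.append(tuple(cur))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["label"] = [f"region_{i:04d}" for i in range(len(df))]
    return RegionSet(df)


def correlate_scans(
    snp_windows: pd.DataFrame,
    indel_windows: pd.DataFrame,
    level: float = 0.99,
) -> tuple[float, float, int]:
    """Pearson r between SNP and INDEL window Fst over putative-sweep windows.

    Windows are aligned by identical (chrom, start, end); the comparison set
    is windows that qualify in both scans and belong to the top-level
    selection of at least one of them.  Returns (r, two-sided p, n).
    """
    top_snp = percentile_select(snp_windows, level).windows
    top_indel = percentile_select(indel_windows, level).windows
    key = ["chrom", "start", "end"]
    merged = snp_windows.merge(
        indel_windows, on=key, suffixes=("_snp", "_indel"), how="inner"
    )
    merged = merged[merged["qualifies_snp"] & merged["qualifies_indel"]]
    in_top = pd.MultiIndex.from_frame(merged[key]).isin(
        pd.MultiIndex.from_frame(pd.concat([top_snp[key], top_indel[key]]))
    )
    sub = merged[in_top]
    if len(sub) < 3:
        raise ValueError(f"only {len(sub)} comparable windows; need >= 3")
    r, p = stats.pearsonr(sub["weighted_fst_snp"], sub["weighted_fst_indel"])
    return float(r), float(p), int(len(sub))


def annotate_regions(
    regions: RegionSet, genes: RegionSet
) -> tuple[pd.DataFrame, int]:
    """Genes intersecting (>= 1 bp, inclusive bounds) each region.

    Returns a per-region table (chrom, start, end, label, genes, n_genes)
    and the number of unique genes across all regions.
    """
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in genes.regions.groupby("chrom", sort=False):
        # intervaltree is half-open; +1 on end makes queries inclusive
        trees[chrom] = IntervalTree.from_tuples(
            (s, e + 1, lab) for s, e, lab in grp[["start", "end", "label"]].itertuples(index=False)
        )
    rows = []
    all_genes: set[str] = set()
    for chrom, start, end, label in regions.regions[
        ["chrom", "start", "end", "label"]
    ].itertuples(index=False):
        hits = sorted(iv.data for iv in trees.get(chrom, IntervalTree()).overlap(start, end + 1))
        all_genes.update(hits)
        rows.append((chrom, start, end, label, ",".join(hits), len(hits)))
    table = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "label", "genes", "n_genes"]
    )
    return table, len(all_genes)


def _merged_global_intervals(
    regions: RegionSet, offsets: Mapping[str, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Union of intervals in concatenated-genome coordinates (1-based inclusive)."""
    ivs = []
    for chrom, start, end in regions.regions[["chrom", "start", "end"]].itertuples(
        index=False
    ):
        if chrom in offsets:
            off = offsets[chrom]
            ivs.append((off + start, off + end))
    if not ivs:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    ivs.sort()
    starts, ends = [ivs[0][0]], [ivs[0][1]]
    for s, e in ivs[1:]:
        if s <= ends[-1] + 1:
            ends[-1] = max(ends[-1], e)
        else:
            starts.append(s)
            ends.append(e)
    return np.asarray(starts, dtype=np.int64), np.asarray(ends, dtype=np.int64)


def _covered_upto(
    x: np.ndarray, starts: np.ndarray, ends: np.ndarray, cum: np.ndarray
) -> np.ndarray:
    """Total bp of the sorted disjoint intervals lying within [1, x]."""
    i = np.searchsorted(starts, x, side="right")
    im = np.maximum(i - 1, 0)
    return np.where(i > 0, cum[im] - np.maximum(ends[im] - x, 0), 0)


def _coverage_overlap(
    q_start: np.ndarray, q_end: np.ndarray, starts: np.ndarray, ends: np.ndarray,
    cum: np.ndarray,
) -> np.ndarray:
    """bp of the fixed union intervals covered inside each query interval."""
    return _covered_upto(q_end, starts, ends, cum) - _covered_upto(
        np.asarray(q_start) - 1, starts, ends, cum
    )


def region_qtl_overlap_bp(regions: RegionSet, qtls: RegionSet,
                          chrom_lengths: Mapping[str, int]) -> int:
    """Total bp of the regions covered by the union of QTL intervals."""
    offsets = _chrom_offsets(chrom_lengths)
    qs, qe = _merged_global_intervals(qtls, offsets)
    if not len(qs):
        return 0
    cum = np.cumsum(qe - qs + 1)
    rs, re = _merged_global_intervals(regions, offsets)
    return int(_coverage_overlap(rs, re, qs, qe, cum).sum())


def _chrom_offsets(chrom_lengths: Mapping[str, int]) -> dict[str, int]:
    offsets = {}
    off = 0
    for chrom, length in chrom_lengths.items():
        offsets[chrom] = off
        off += int(length)
    return offsets


def qtl_overlap_permutation(
    regions: RegionSet,
    qtls: RegionSet,
    chrom_lengths: Mapping[str, int],
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    per_chromosome: bool = False,
) -> OverlapTest:
    """Permutation test of region/QTL overlap.

    Each permutation re-places every region uniformly at random with its
    length preserved; by default anywhere in the genome (chromosome chosen
    with probability proportional to length among chromosomes that fit the
    region), or on its own chromosome with ``per_chromosome=True``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    offsets = _chrom_offsets(chrom_lengths)
    chroms = list(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in chroms], dtype=np.int64)

    reg = regions.regions
    for chrom, start, end in reg[["chrom", "start", "end"]].itertuples(index=False):
        if chrom not in chrom_lengths:
            raise ValueError(f"region on unknown chromosome {chrom}")
        if end - start + 1 > lengths.max():
            raise ValueError("a region is longer than every chromosome")

    qs, qe = _merged_global_intervals(qtls, offsets)
    if not len(qs):
        observed = 0.0
        return OverlapTest(0.0, 0.0, 0.0, n_perm, 1.0)
    cum = np.cumsum(qe - qs + 1)

    rs, re = _merged_global_intervals(regions, offsets)
    observed_bp = int(_coverage_overlap(rs, re, qs, qe, cum).sum())

    region_len = (reg["end"] - reg["start"] + 1).to_numpy(dtype=np.int64)
    n_reg = len(region_len)
    null_bp = np.zeros(n_perm, dtype=np.int64)
    off_arr = np.array([offsets[c] for c in chroms], dtype=np.int64)

    if per_chromosome:
        reg_chrom_len = np.array(
            [chrom_lengths[c] for c in reg["chrom"]], dtype=np.int64
        )
        reg_off = np.array([offsets[c] for c in reg["chrom"]], dtype=np.int64)
        starts_local = (
            rng.random((n_perm, n_reg)) * (reg_chrom_len - region_len + 1)
        ).astype(np.int64) + 1
        g_start = reg_off[None, :] + starts_local
    else:
        g_start = np.empty((n_perm, n_reg), dtype=np.int64)
        for j in range(n_reg):
            fits = lengths >= region_len[j]
            w = np.where(fits, lengths, 0).astype(float)
            w /= w.sum()
            ci = rng.choice(len(chroms), size=n_perm, p=w)
            n_valid = lengths[ci] - region_len[j] + 1
            g_start[:, j] = off_arr[ci] + (rng.random(n_perm) * n_valid).astype(np.int64) + 1
    g_end = g_start + region_len[None, :] - 1
    ov = _coverage_overlap(g_start.ravel(), g_end.ravel(), qs, qe, cum)
    null_bp = ov.reshape(n_perm, n_reg).sum(axis=1)

    observed = observed_bp / 1e6
    null = null_bp / 1e6
    p = (1 + int((null >= observed).sum())) / (1 + n_perm)
    return OverlapTest(
        observed_overlap_mb=float(observed),
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)) if n_perm > 1 else 0.0,
        n_permutations=n_perm,
        p_value=float(p),
    )
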