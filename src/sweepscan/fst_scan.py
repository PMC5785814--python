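"""Weir-Cockerham Fst variance components and windowed scans.

Per biallelic site, with r = 2 populations, n_i non-missing diploids,
sample alternate-allele frequencies p_i and observed heterozygote
proportions h_i, define

    nbar = (n1 + n2) / r
    n_c  = (r*nbar - sum(n_i^2)/(r*nbar)) / (r - 1)
    pbar = sum(n_i * p_i) / (r * nbar)
    s2   = sum(n_i * (p_i - pbar)^2) / ((r - 1) * nbar)
    hbar = sum(n_i * h_i) / (r * nbar)

and the three variance components

    a = (nbar / n_c) * [s2 - (pbar*(1-pbar) - s2*(r-1)/r - hbar/4) / (nbar - 1)]
    b = (nbar / (nbar - 1)) * [pbar*(1-pbar) - s2*(r-1)/r - hbar*(2*nbar-1)/(4*nbar)]
    c = hbar / 2

The per-site estimate is a/(a+b+c); a window's "weighted" Fst is the
ratio of sums sum(a)/sum(a+b+c) over its sites (not the mean of per-site
ratios).  Components are reported unclamped — a, and hence both window
statistics, may be negative.  Sites monomorphic in the pooled sample have
a = b = c = 0 exactly and are excluded from window marker counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import PopulationAssignment, VariantTable

log = logging.getLogger(__name__)

_R = 2  # populations


@dataclass
class SiteCounts:
    """Marshalled per-site inputs to the estimator (two populations)."""

    n1: int
    n2: int
    p1: float
    p2: float
    h1: float
    h2: float


@dataclass
class SiteFstComponents:
    a: float  # between-population component
    b: float  # between-individual, within-population
    c: float  # within-individual

    @property
    def fst(self) -> float:
        denom = self.a + self.b + self.c
        return self.a / denom if denom != 0 else float("nan")


def compute_site_counts(
    genotypes: np.ndarray,
    samples: list[str],
    assignment: PopulationAssignment,
    min_individuals: int = 2,
) -> SiteCounts:
    """Counts for a single site; raises if either population has too few calls."""
    idx = assignment.indices(samples)
    pop1, pop2 = assignment.require_two()
    out = []
    for pop in (pop1, pop2):
        g = np.asarray(genotypes)[idx[pop]]
        g = g[g >= 0]
        n = len(g)
        if n < min_individuals:
            raise ValueError(
                f"population {pop} has {n} non-missing individuals "
                f"(minimum {min_individuals}); site skipped"
            )
        p = float((2 * (g == 2).sum() + (g == 1).sum()) / (2 * n))
        h = float((g == 1).sum() / n)
        out.append((n, p, h))
    (n1, p1, h1), (n2, p2, h2) = out
    return SiteCounts(n1=n1, n2=n2, p1=p1, p2=p2, h1=h1, h2=h2)


def wc_components(
    n1: np.ndarray,
    n2: np.ndarray,
    p1: np.ndarray,
    p2: np.ndarray,
    h1: np.ndarray,
    h2: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Weir-Cockerham (a, b, c) for arrays of site counts."""
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    nbar = (n1 + n2) / _R
    nc = (_R * nbar - (n1**2 + n2**2) / (_R * nbar)) / (_R - 1)
    pbar = (n1 * p1 + n2 * p2) / (_R * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((_R - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (_R * nbar)
    pq = pbar * (1 - pbar)
    inner = pq - s2 * (_R - 1) / _R - hbar / 4
    a = (nbar / nc) * (s2 - inner / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pq - s2 * (_R - 1) / _R - hbar * (2 * nbar - 1) / (4 * nbar))
    c = hbar / 2
    return a, b, c


def compute_site_components(counts: SiteCounts) -> SiteFstComponents:
    a, b, c = wc_components(
        np.array([counts.n1]),
        np.array([counts.n2]),
        np.array([counts.p1]),
        np.array([counts.p2]),
        np.array([counts.h1]),
        np.array([counts.h2]),
    )
    return SiteFstComponents(a=float(a[0]), b=float(b[0]), c=float(c[0]))


def weighted_fst(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Ratio-of-sums estimate sum(a)/sum(a+b+c) over a set of sites."""
    a = np.asarray(a, dtype=float)
    denom = float(a.sum() + np.sum(b) + np.sum(c))
    if denom == 0:
        raise ValueError("all sites monomorphic: weighted Fst undefined")
    return float(a.sum() / denom)


def site_components_table(
    variants: VariantTable,
    assignment: PopulationAssignment,
    min_individuals: int = 2,
) -> pd.DataFrame:
    """Per-site components for a whole table.

    Returns columns (chrom, pos, var_class, a, b, c, fst, polymorphic).
    Sites with fewer than ``min_individuals`` non-missing diploids in either
    population are dropped (count logged).
    """
    pop1, pop2 = assignment.require_two()
    idx = assignment.indices(variants.samples)
    g1 = variants.genotypes[:, idx[pop1]]
    g2 = variants.genotypes[:, idx[pop2]]

    def _pop_counts(g: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        n = (g >= 0).sum(axis=1)
        het = (g == 1).sum(axis=1)
        alt = 2 * (g == 2).sum(axis=1) + het
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(n > 0, alt / np.maximum(1, 2 * n), 0.0)
            h = np.where(n > 0, het / np.maximum(1, n), 0.0)
        return n, p, h

    n1, p1, h1 = _pop_counts(g1)
    n2, p2, h2 = _pop_counts(g2)
    ok = (n1 >= min_individuals) & (n2 >= min_individuals)
    n_skipped = int((~ok).sum())
    if n_skipped:
        log.info(
            "site_components_table: %d sites skipped (<%d non-missing in a population)",
            n_skipped,
            min_individuals,
        )
    a, b, c = wc_components(n1[ok], n2[ok], p1[ok], p2[ok], h1[ok], h2[ok])
    denom = a + b + c
    with np.errstate(divide="ignore", invalid="ignore"):
        fst = np.where(denom != 0, a / np.where(denom != 0, denom, 1.0), np.nan)
    sites = variants.sites.loc[ok, ["chrom", "pos", "var_class"]].reset_index(drop=True)
    return sites.assign(a=a, b=b, c=c, fst=fst, polymorphic=denom != 0)


def genome_weighted_fst(components: pd.DataFrame) -> float:
    """Genome-wide ratio-of-sums Fst over a components table."""
    return weighted_fst(
        components["a"].to_numpy(), components["b"].to_numpy(), components["c"].to_numpy()
    )


def sliding_window_fst(
    components: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    window_bp: int = 20_000,
    step_bp: int = 10_000,
    min_markers: int = 10,
) -> pd.DataFrame:
    """Overlapping sliding-window weighted Fst.

    Windows are anchored at position 1 on every chromosome: starts 1,
    1+step, 1+2*step, ...; a site at position p belongs to every window
    whose interval [start, start+window_bp-1] covers p (two windows for the
    default 20 kb / 10 kb geometry, away from chromosome ends).  Terminal
    windows are truncated at the chromosome end.  Monomorphic sites do not
    count as markers.  Windows below ``min_markers`` are retained with
    ``qualifies=False`` and NaN statistics.

    Returns columns (chrom, start, end, n_markers, weighted_fst, mean_fst,
    qualifies).
    """
    if window_bp < step_bp:
        raise ValueError("window_bp must be >= step_bp")
    if min_markers < 1:
        raise ValueError("min_markers must be >= 1")
    unknown = set(components["chrom"]) - set(chrom_lengths)
    if unknown:
        raise ValueError(f"sites on chromosomes without a length: {sorted(unknown)}")

    rows = []
    by_chrom = {c: g for c, g in components.groupby("chrom", sort=False)}
    for chrom, length in chrom_lengths.items():
        n_windows = (length - 1) // step_bp + 1
        starts = 1 + step_bp * np.arange(n_windows)
        ends = np.minimum(starts + window_bp - 1, length)
        nmark = np.zeros(n_windows, dtype=np.int64)
        suma = np.zeros(n_windows)
        sumd = np.zeros(n_windows)
        sum_ratio = np.zeros(n_windows)
        n_ratio = np.zeros(n_windows, dtype=np.int64)
        grp = by_chrom.get(chrom)
        if grp is not None:
            poly = grp[grp["polymorphic"]]
            pos = poly["pos"].to_numpy()
            a = poly["a"].to_numpy()
            d = (poly["a"] + poly["b"] + poly["c"]).to_numpy()
            ratio = poly["fst"].to_numpy()
            # window index k covers p iff k in [ceil((p - window)/step), (p-1)//step]
            k_hi = (pos - 1) // step_bp
            k_lo = np.maximum(0, np.ceil((pos - window_bp) / step_bp).astype(np.int64))
            max_multiplicity = window_bp // step_bp + 1
            for m in range(max_multiplicity):
                k = k_hi - m
                sel = (k >= k_lo) & (k < n_windows)
                ks = k[sel]
                np.add.at(nmark, ks, 1)
                np.add.at(suma, ks, a[sel])
                np.add.at(sumd, ks, d[sel])
                np.add.at(sum_ratio, ks, ratio[sel])
                np.add.at(n_ratio, ks, 1)
        qualifies = nmark >= min_markers
        with np.errstate(divide="ignore", invalid="ignore"):
            wfst = np.where(qualifies & (sumd != 0), suma / np.where(sumd != 0, sumd, 1), np.nan)
            mfst = np.where(
                qualifies & (n_ratio > 0), sum_ratio / np.maximum(n_ratio, 1), np.nan
            )
        n_dropped = int((qualifies & (sumd == 0)).sum())
        if n_dropped:
            log.info(
                "sliding_window_fst: %d windows on %s dropped as all-monomorphic",
                n_dropped,
                chrom,
            )
        qualifies = qualifies & (sumd != 0)
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": ends,
                    "n_markers": nmark,
                    "weighted_fst": wfst,
                    "mean_fst": mfst,
                    "qualifies": qualifies,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
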