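"""Descriptive statistics over a variant table.

Conventions follow standard resequencing-study reporting: the alternate
allele frequency (AAF) of a site is the number of alternate alleles over
all non-missing alleles in the chosen sample subset; a variant is "near
fixation" at AAF >= 0.9 and "low frequency" at AAF <= 0.3 (thresholds
configurable); the per-individual heterozygous fraction counts only
genotypes at which the individual actually carries the variant
(#het / (#het + #hom_alt)); the substitution spectrum is directional
(ref->alt, 12 categories); TS/TV counts A<->G and C<->T as transitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import SNP, PopulationAssignment, VariantTable

log = logging.getLogger(__name__)

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
SUBSTITUTION_TYPES = [
    f"{r}>{a}" for r in "ACGT" for a in "ACGT" if r != a
]  # 12 directional categories


@dataclass
class AafSpectrum:
    aafs: np.ndarray
    hist: np.ndarray
    bin_edges: np.ndarray
    fraction_fixed: float
    fraction_low: float

    @property
    def n_sites(self) -> int:
        return len(self.aafs)


def alternate_allele_frequency(
    genotypes: np.ndarray, subset: np.ndarray | None = None
) -> float:
    """AAF of one site: (2*#hom_alt + #het) / (2 * #non-missing)."""
    g = np.asarray(genotypes)
    if subset is not None:
        g = g[np.asarray(subset)]
    g = g[g >= 0]
    if len(g) == 0:
        raise ValueError("all genotypes missing: AAF undefined")
    return float((2 * (g == 2).sum() + (g == 1).sum()) / (2 * len(g)))


def aaf_by_site(
    variants: VariantTable, sample_idx: np.ndarray | None = None
) -> np.ndarray:
    """Vectorized per-site AAF; NaN where every genotype is missing (logged)."""
    g = variants.genotypes if sample_idx is None else variants.genotypes[:, sample_idx]
    n = (g >= 0).sum(axis=1)
    alt = 2 * (g == 2).sum(axis=1) + (g == 1).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        aaf = np.where(n > 0, alt / np.maximum(1, 2 * n), np.nan)
    n_undef = int((n == 0).sum())
    if n_undef:
        log.info("aaf_by_site: %d sites with all genotypes missing excluded", n_undef)
    return aaf


def aaf_spectrum(
    aafs: Sequence[float],
    bins: int = 10,
    fixed_threshold: float = 0.9,
    low_threshold: float = 0.3,
) -> AafSpectrum:
    """Histogram plus the near-fixation (>= 0.9) and low-frequency (<= 0.3) fractions."""
    aafs = np.asarray(aafs, dtype=float)
    aafs = aafs[~np.isnan(aafs)]
    if len(aafs) == 0:
        raise ValueError("no defined AAF values")
    if aafs.min() < 0 or aafs.max() > 1:
        raise ValueError("AAF values must lie in [0, 1]")
    hist, edges = np.histogram(aafs, bins=bins, range=(0.0, 1.0))
    return AafSpectrum(
        aafs=aafs,
        hist=hist,
        bin_edges=edges,
        fraction_fixed=float((aafs >= fixed_threshold).mean()),
        fraction_low=float((aafs <= low_threshold).mean()),
    )


def per_individual_het_fraction(variants: VariantTable) -> pd.Series:
    """#het / (#het + #hom_alt) per sample; NaN for samples carrying no variant."""
    g = variants.genotypes
    het = (g == 1).sum(axis=0).astype(float)
    hom_alt = (g == 2).sum(axis=0).astype(float)
    carrier = het + hom_alt
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(carrier > 0, het / np.maximum(carrier, 1), np.nan)
    return pd.Series(frac, index=variants.samples, name="het_fraction")


def _substitution_pairs(variants: VariantTable) -> list[tuple[str, str]]:
    snps = variants.sites
    if (snps["var_class"] != SNP).any():
        raise ValueError("substitution statistics are defined for SNPs only")
    return list(zip(snps["ref"], snps["alt"]))


def tstv_ratio(snps: VariantTable) -> float:
    """Transitions (A<->G, C<->T) over transversions; error if no transversions."""
    pairs = _substitution_pairs(snps)
    ts = sum(1 for p in pairs if p in TRANSITIONS)
    tv = len(pairs) - ts
    if tv == 0:
        raise ValueError("zero transversions: TS/TV ratio undefined")
    return ts / tv


def substitution_spectrum(snps: VariantTable) -> pd.Series:
    """Directional ref->alt proportions over the 12 substitution types (sum 1)."""
    pairs = _substitution_pairs(snps)
    if not pairs:
        raise ValueError("no SNPs")
    counts = pd.Series(0, index=SUBSTITUTION_TYPES, dtype=float)
    observed = pd.Series([f"{r}>{a}" for r, a in pairs]).value_counts()
    counts.loc[observed.index] = observed.to_numpy(dtype=float)
    return counts / counts.sum()


@dataclass
class LinePartition:
    shared: int
    pop1_only: int
    pop2_only: int
    pop1: str
    pop2: str

    @property
    def total_detected(self) -> int:
        return self.shared + self.pop1_only + self.pop2_only


def line_partition(
    variants: VariantTable, assignment: PopulationAssignment
) -> LinePartition:
    """Venn partition of variants detected (>=1 alt allele carried) per line."""
    pop1, pop2 = assignment.require_two()
    idx = assignment.indices(variants.samples)
    in1 = (variants.genotypes[:, idx[pop1]] > 0).any(axis=1)
    in2 = (variants.genotypes[:, idx[pop2]] > 0).any(axis=1)
    return LinePartition(
        shared=int((in1 & in2).sum()),
        pop1_only=int((in1 & ~in2).sum()),
        pop2_only=int((~in1 & in2).sum()),
        pop1=pop1,
        pop2=pop2,
    )


def variant_density(
    variants: VariantTable, chrom_lengths: Mapping[str, int]
) -> pd.DataFrame:
    """Variants per kb, per chromosome and genome-wide, split by class."""
    rows = []
    counts = variants.sites.groupby(["chrom", "var_class"]).size()
    for chrom, length in chrom_lengths.items():
        for var_class in ("SNP", "INDEL"):
            c = int(counts.get((chrom, var_class), 0))
            rows.append((chrom, var_class, c, 1000 * c / length))
    total_len = sum(chrom_lengths.values())
    for var_class in ("SNP", "INDEL"):
        c = int((variants.sites["var_class"] == var_class).sum())
        rows.append(("genome", var_class, c, 1000 * c / total_len))
    return pd.DataFrame(rows, columns=["chrom", "var_class", "count", "per_kb"])
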