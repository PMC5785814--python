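"""Six-rule variant filtration with per-rule removal accounting.

The rules, applied in a fixed order for report attribution:

1. ``quality``          — Phred variant quality >= 40 (default)
2. ``min_depth``        — aggregate site depth >= 5
3. ``max_depth``        — depth <= mean + 3 SD over all called sites
4. ``strand_support``   — at least one alt-supporting read on each strand
5. ``alt_read_support`` — at least 3 alt-supporting reads
6. ``snp_cluster`` / ``indel_cluster`` — >10 SNPs in any 50 bp span; two
   INDELs with <= 1 intervening base between their start positions

A site failing several rules is counted once, under the first failing rule.
Sites with an unknown field (missing QUAL/DP/DP4 in the input) are removed
by the rule that needs the field, with a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import INDEL, SNP, VariantTable

log = logging.getLogger(__name__)

RULE_QUALITY = "quality"
RULE_MIN_DEPTH = "min_depth"
RULE_MAX_DEPTH = "max_depth"
RULE_STRAND = "strand_support"
RULE_ALT_READS = "alt_read_support"
RULE_SNP_CLUSTER = "snp_cluster"
RULE_INDEL_CLUSTER = "indel_cluster"

#: Attribution order (rule 6 covers both cluster flavours).
RULE_ORDER = [
    RULE_QUALITY,
    RULE_MIN_DEPTH,
    RULE_MAX_DEPTH,
    RULE_STRAND,
    RULE_ALT_READS,
    RULE_SNP_CLUSTER,
    RULE_INDEL_CLUSTER,
]


@dataclass
class FilterConfig:
    min_qual: float = 40.0
    min_depth: int = 5
    max_depth_sd_mult: float = 3.0
    min_alt_reads: int = 3
    require_both_strands: bool = True
    snp_cluster_count: int = 10  # removal triggers at > this many SNPs...
    snp_cluster_span_bp: int = 50  # ...within any span of this many bases
    indel_cluster_gap_bp: int = 1  # <= this many intervening bases between starts
    depth_ceiling_override: float | None = None

    def validate(self) -> None:
        if min(self.min_qual, self.min_depth, self.min_alt_reads) < 0:
            raise ValueError("thresholds must be non-negative")
        if self.snp_cluster_span_bp < 1:
            raise ValueError("snp_cluster_span_bp must be >= 1")


@dataclass
class FilterReport:
    input_count: int
    output_count: int
    removed: dict[str, int] = field(default_factory=dict)
    depth_ceiling: float = float("nan")
    unknown_field_removals: int = 0

    def validate(self) -> None:
        if self.input_count - sum(self.removed.values()) != self.output_count:
            raise AssertionError("removal bookkeeping does not balance")

    def to_frame(self) -> pd.DataFrame:
        rows = [("input", self.input_count)]
        rows += [(f"removed_{r}", self.removed.get(r, 0)) for r in RULE_ORDER]
        rows += [("output", self.output_count), ("depth_ceiling", self.depth_ceiling)]
        return pd.DataFrame(rows, columns=["metric", "value"])


def depth_ceiling(variants: VariantTable, mult: float = 3.0) -> float:
    """Dataset-wide depth ceiling: mean + mult * SD (sample SD, N-1 denominator)."""
    depths = variants.sites["total_depth"].to_numpy()
    depths = depths[depths >= 0].astype(float)
    if len(depths) == 0:
        raise ValueError("all site depths unknown; cannot compute depth ceiling")
    if len(depths) == 1:
        return float(depths[0])
    return float(depths.mean() + mult * depths.std(ddof=1))


def _snp_cluster_mask(
    pos: np.ndarray, count_threshold: int, span_bp: int
) -> np.ndarray:
    """Mark SNPs inside any span of ``span_bp`` bases holding > count_threshold SNPs.

    Sorted positions of one chromosome.  Any offending window can be shifted
    left until its first base is a SNP, so anchoring candidate windows at
    each SNP position is exhaustive.
    """
    mask = np.zeros(len(pos), dtype=bool)
    j = 0
    for i in range(len(pos)):
        if j < i:
            j = i
        while j + 1 < len(pos) and pos[j + 1] <= pos[i] + span_bp - 1:
            j += 1
        if j - i + 1 > count_threshold:
            mask[i : j + 1] = True
    return mask


def _indel_cluster_mask(pos: np.ndarray, gap_bp: int) -> np.ndarray:
    """Mark INDEL pairs whose start positions differ by <= gap_bp + 1."""
    mask = np.zeros(len(pos), dtype=bool)
    if len(pos) < 2:
        return mask
    close = np.diff(pos) <= gap_bp + 1
    mask[:-1] |= close
    mask[1:] |= close
    return mask


def apply_filters(
    variants: VariantTable, config: FilterConfig | None = None
) -> tuple[VariantTable, FilterReport]:
    """Apply the six filtration rules; return survivors and a removal report."""
    config = config or FilterConfig()
    config.validate()
    if not variants.is_sorted():
        raise ValueError("variants must be sorted by (chrom, pos)")
    s = variants.sites
    n = len(s)
    qual = s["qual"].to_numpy(dtype=float)
    depth = s["total_depth"].to_numpy(dtype=float)
    alt_fwd = s["alt_fwd"].to_numpy(dtype=float)
    alt_rev = s["alt_rev"].to_numpy(dtype=float)

    unknown_qual = np.isnan(qual)
    unknown_depth = depth < 0
    unknown_strand = (alt_fwd < 0) | (alt_rev < 0)

    ceiling = (
        config.depth_ceiling_override
        if config.depth_ceiling_override is not None
        else depth_ceiling(variants, config.max_depth_sd_mult)
    )

    fail = {}
    fail[RULE_QUALITY] = unknown_qual | (qual < config.min_qual)
    fail[RULE_MIN_DEPTH] = unknown_depth | (depth < config.min_depth)
    fail[RULE_MAX_DEPTH] = unknown_depth | (depth > ceiling)
    if config.require_both_strands:
        fail[RULE_STRAND] = unknown_strand | (alt_fwd < 1) | (alt_rev < 1)
    else:
        fail[RULE_STRAND] = np.zeros(n, dtype=bool)
    fail[RULE_ALT_READS] = unknown_strand | (alt_fwd + alt_rev < config.min_alt_reads)

    snp_cluster = np.zeros(n, dtype=bool)
    indel_cluster = np.zeros(n, dtype=bool)
    is_snp = (s["var_class"] == SNP).to_numpy()
    is_indel = (s["var_class"] == INDEL).to_numpy()
    for _, grp in s.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        snp_idx = idx[is_snp[idx]]
        if len(snp_idx):
            snp_cluster[snp_idx] = _snp_cluster_mask(
                s["pos"].to_numpy()[snp_idx],
                config.snp_cluster_count,
                config.snp_cluster_span_bp,
            )
        ind_idx = idx[is_indel[idx]]
        if len(ind_idx):
            indel_cluster[ind_idx] = _indel_cluster_mask(
                s["pos"].to_numpy()[ind_idx], config.indel_cluster_gap_bp
            )
    fail[RULE_SNP_CLUSTER] = snp_cluster
    fail[RULE_INDEL_CLUSTER] = indel_cluster

    # first-failing-rule attribution
    attributed = np.zeros(n, dtype=bool)
    removed_counts: dict[str, int] = {}
    any_fail = np.zeros(n, dtype=bool)
    for rule in RULE_ORDER:
        newly = fail[rule] & ~attributed
        removed_counts[rule] = int(newly.sum())
        attributed |= newly
        any_fail |= fail[rule]

    n_unknown = int(((unknown_qual | unknown_depth | unknown_strand) & any_fail).sum())
    if n_unknown:
        log.info("apply_filters: %d sites removed due to unknown fields", n_unknown)

    survivors = variants.subset(~any_fail)
    report = FilterReport(
        input_count=n,
        output_count=survivors.n_sites,
        removed=removed_counts,
        depth_ceiling=float(ceiling),
        unknown_field_removals=n_unknown,
    )
    report.validate()
    return survivors, report
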