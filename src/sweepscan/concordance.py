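"""Cross-platform genotype validation between a sequencing call set and an array.

Two metrics, per standard NGS-vs-array comparison practice:

* POS-CONC — sites matched between the two call sets by genomic key,
  either position-only ``(chrom, pos)`` or allele-aware
  ``(chrom, pos, ref, alt)``;
* GEN-CONC — the subset of POS-CONC sites with identical genotype calls,
  reported overall and stratified by array zygosity.

Error rate (%) = 100 - 100 * GEN-CONC / POS-CONC.  Genotypes missing on
either side are excluded from both numerator and denominator (logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping

import pandas as pd

from .containers import GT_CODES, MISSING, VariantTable

log = logging.getLogger(__name__)

SiteKey = tuple


@dataclass
class ConcordanceReport:
    n_seq: int
    n_array: int
    pos_conc: int
    gen_conc: int
    n_compared: int  # POS-CONC sites with genotypes defined on both sides
    n_missing_excluded: int
    hom_compared: int
    hom_concordant: int
    het_compared: int
    het_concordant: int

    @property
    def pos_conc_pct(self) -> float:
        return 100.0 * self.pos_conc / self.n_array if self.n_array else 0.0

    @property
    def gen_conc_pct(self) -> float:
        return 100.0 * self.gen_conc / self.n_compared if self.n_compared else 0.0

    @property
    def error_rate_pct(self) -> float:
        return 100.0 - self.gen_conc_pct

    def to_dict(self) -> dict:
        return {
            "n_seq": self.n_seq,
            "n_array": self.n_array,
            "pos_conc": self.pos_conc,
            "pos_conc_pct": self.pos_conc_pct,
            "gen_conc": self.gen_conc,
            "gen_conc_pct": self.gen_conc_pct,
            "error_rate_pct": self.error_rate_pct,
            "n_compared": self.n_compared,
            "n_missing_excluded": self.n_missing_excluded,
            "hom_gen_conc_pct": (
                100.0 * self.hom_concordant / self.hom_compared
                if self.hom_compared
                else float("nan")
            ),
            "het_gen_conc_pct": (
                100.0 * self.het_concordant / self.het_compared
                if self.het_compared
                else float("nan")
            ),
        }


def site_keys(
    variants: VariantTable, mode: str = "pos"
) -> list[SiteKey]:
    """Site keys for matching: ``pos`` -> (chrom, pos); ``allele`` -> + (ref, alt)."""
    s = variants.sites
    if mode == "pos":
        return list(zip(s["chrom"], s["pos"]))
    if mode == "allele":
        return list(zip(s["chrom"], s["pos"], s["ref"], s["alt"]))
    raise ValueError(f"unknown mode {mode!r}")


def position_concordance(
    set_a: Iterable[SiteKey], set_b: Iterable[SiteKey]
) -> set[SiteKey]:
    """Matched keys (set intersection); duplicate keys within a set are an error."""
    out = []
    for name, keys in (("A", set_a), ("B", set_b)):
        keys = list(keys)
        s = set(keys)
        if len(s) != len(keys):
            seen: set = set()
            dups = [k for k in keys if k in seen or seen.add(k)]
            raise ValueError(f"duplicate keys in set {name}: {dups[:5]}")
        out.append(s)
    return out[0] & out[1]


def _normalize_code(value: Hashable) -> int:
    if isinstance(value, str):
        return GT_CODES[value]
    code = int(value)
    if code not in (-1, 0, 1, 2):
        raise ValueError(f"invalid genotype code {value!r}")
    return code


def genotype_concordance(
    seq_genotypes: Mapping[SiteKey, Hashable],
    array_genotypes: Mapping[SiteKey, Hashable],
    matched: set[SiteKey],
    n_seq: int | None = None,
    n_array: int | None = None,
) -> ConcordanceReport:
    """GEN-CONC over the matched keys; codes may be names or integer codes."""
    if not matched:
        raise ValueError("empty matched set")
    n_missing = 0
    gen_conc = hom_comp = hom_conc = het_comp = het_conc = compared = 0
    for key in matched:
        g_seq = _normalize_code(seq_genotypes[key])
        g_arr = _normalize_code(array_genotypes[key])
        if g_seq == MISSING or g_arr == MISSING:
            n_missing += 1
            continue
        compared += 1
        same = g_seq == g_arr
        gen_conc += same
        if g_arr in (0, 2):
            hom_comp += 1
            hom_conc += same
        else:
            het_comp += 1
            het_conc += same
    if n_missing:
        log.info(
            "genotype_concordance: %d matched sites excluded for missing genotypes",
            n_missing,
        )
    if compared == 0:
        raise ValueError("no matched sites with genotypes on both sides")
    return ConcordanceReport(
        n_seq=n_seq if n_seq is not None else len(seq_genotypes),
        n_array=n_array if n_array is not None else len(array_genotypes),
        pos_conc=len(matched),
        gen_conc=gen_conc,
        n_compared=compared,
        n_missing_excluded=n_missing,
        hom_compared=hom_comp,
        hom_concordant=hom_conc,
        het_compared=het_comp,
        het_concordant=het_conc,
    )


def read_array_genotypes(path: str, sample: str) -> pd.DataFrame:
    """Array genotypes from TSV with columns chrom, pos, ref, alt, <sample>...

    Genotype cells hold either code names (hom_ref/het/hom_alt/missing) or
    integer codes (0/1/2/-1).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "ref", "alt"}
    if not required <= set(df.columns):
        raise ValueError(f"array table must have columns {sorted(required)}")
    if sample not in df.columns:
        raise ValueError(f"sample {sample!r} not in array table")
    return df[["chrom", "pos", "ref", "alt", sample]].rename(columns={sample: "genotype"})


def compare_to_array(
    variants: VariantTable, array: pd.DataFrame, sample: str, mode: str = "pos"
) -> ConcordanceReport:
    """Full NGS-vs-array comparison for one sample."""
    if sample not in variants.samples:
        raise ValueError(f"sample {sample!r} not in variant table")
    col = variants.samples.index(sample)
    seq_keys = site_keys(variants, mode)
    if mode == "pos":
        arr_keys = list(zip(array["chrom"], array["pos"]))
    else:
        arr_keys = list(zip(array["chrom"], array["pos"], array["ref"], array["alt"]))
    matched = position_concordance(seq_keys, arr_keys)
    seq_gt = dict(zip(seq_keys, variants.genotypes[:, col]))
    arr_gt = dict(zip(arr_keys, array["genotype"]))
    return genotype_concordance(
        seq_gt, arr_gt, matched, n_seq=len(seq_keys), n_array=len(arr_keys)
    )
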