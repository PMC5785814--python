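"""Readers and writers for the standard formats the pipeline touches.

VCF 4.x goes through pysam; BED, population maps and array-genotype tables
are plain TSV via pandas.  In-memory coordinates are 1-based inclusive; BED
on disk is 0-based half-open, and this module is the single conversion point
(disk start+1 on read, start-1 on write).
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .containers import (
    MISSING,
    SITE_COLUMNS,
    PopulationAssignment,
    RegionSet,
    VariantTable,
    classify_alleles,
)

log = logging.getLogger(__name__)

_UNKNOWN_INT = -1


def _gt_code(gt: tuple) -> int:
    """Map a pysam GT tuple to a genotype code; half/haploid calls -> missing."""
    if gt is None or len(gt) != 2 or any(a is None for a in gt):
        return MISSING
    a, b = gt
    if a == 0 and b == 0:
        return 0
    if a == 1 and b == 1:
        return 2
    if {a, b} == {0, 1}:
        return 1
    return MISSING


def read_vcf(path: str, pop_map: PopulationAssignment | None = None) -> VariantTable:
    """Stream a multi-sample VCF into a :class:`VariantTable`.

    Multi-allelic records are skipped (count logged); missing DP/DP4 are
    stored as the -1 sentinel and only matter to filters that need them.
    """
    vf = pysam.VariantFile(path)
    samples = list(vf.header.samples)
    if pop_map is not None:
        absent = [s for s in pop_map.mapping if s not in samples]
        if absent:
            raise ValueError(f"samples in population map absent from VCF: {absent}")

    rows: list[tuple] = []
    geno_rows: list[list[int]] = []
    n_multi = 0
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            n_multi += 1
            continue
        ref, alt = rec.ref, rec.alts[0]
        try:
            var_class = classify_alleles(ref, alt)
        except ValueError:
            n_multi += 1
            continue
        try:
            dp = int(rec.info.get("DP", _UNKNOWN_INT))
        except (KeyError, ValueError):
            dp = _UNKNOWN_INT
        try:
            dp4 = rec.info.get("DP4")
        except (KeyError, ValueError):  # field absent from the header
            dp4 = None
        if dp4 is None or len(dp4) != 4:
            dp4 = (_UNKNOWN_INT,) * 4
        qual = float(rec.qual) if rec.qual is not None else np.nan
        rows.append(
            (rec.chrom, rec.pos, ref, alt, var_class, qual, dp, *map(int, dp4))
        )
        geno_rows.append([_gt_code(rec.samples[s].get("GT")) for s in samples])
    vf.close()
    if n_multi:
        log.info("read_vcf: skipped %d multi-allelic/complex records", n_multi)
    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    geno = (
        np.asarray(geno_rows, dtype=np.int8)
        if geno_rows
        else np.empty((0, len(samples)), dtype=np.int8)
    )
    return VariantTable(sites=sites, genotypes=geno, samples=samples)


def write_vcf(
    table: VariantTable,
    path: str,
    chrom_lengths: Mapping[str, int] | None = None,
    extra_header_lines: Sequence[str] = (),
) -> None:
    """Write a :class:`VariantTable` as uncompressed VCF 4.x (INFO DP/DP4, FORMAT GT)."""
    header = pysam.VariantHeader()
    for line in extra_header_lines:
        header.add_line(line)
    sites = table.sites
    if chrom_lengths is None:
        chrom_lengths = {
            c: int(g["pos"].max()) + 1000 for c, g in sites.groupby("chrom", sort=True)
        }
    for chrom, length in chrom_lengths.items():
        header.contigs.add(str(chrom), length=int(length))
    header.info.add("DP", 1, "Integer", "Total read depth at the site")
    header.info.add(
        "DP4", 4, "Integer", "Read counts: ref-forward, ref-reverse, alt-forward, alt-reverse"
    )
    header.formats.add("GT", 1, "String", "Genotype")
    for s in table.samples:
        header.add_sample(s)

    gt_tuples = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}
    with pysam.VariantFile(path, "w", header=header) as out:
        for i in range(table.n_sites):
            row = sites.iloc[i]
            rec = out.new_record(
                contig=str(row["chrom"]),
                start=int(row["pos"]) - 1,
                alleles=(str(row["ref"]), str(row["alt"])),
            )
            if not np.isnan(row["qual"]):
                rec.qual = float(row["qual"])
            if row["total_depth"] != _UNKNOWN_INT:
                rec.info["DP"] = int(row["total_depth"])
            dp4 = tuple(int(row[c]) for c in ("ref_fwd", "ref_rev", "alt_fwd", "alt_rev"))
            if all(v != _UNKNOWN_INT for v in dp4):
                rec.info["DP4"] = dp4
            for j, s in enumerate(table.samples):
                rec.samples[s]["GT"] = gt_tuples[int(table.genotypes[i, j])]
                rec.samples[s].phased = False
            out.write(rec)


def read_bed(path: str) -> RegionSet:
    """Read 3+ column BED (0-based half-open on disk) into 1-based inclusive regions."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if df.shape[1] < 3:
        raise ValueError(f"BED file {path} has fewer than 3 columns")
    if df.shape[1] == 3:
        df[3] = ""
    df = df.iloc[:, :4]
    df.columns = ["chrom", "start", "end", "label"]
    bad = df.index[df["start"] >= df["end"]]
    if len(bad):
        raise ValueError(f"BED start >= end at line {int(bad[0]) + 1} of {path}")
    df["start"] = df["start"].astype(int) + 1
    df["end"] = df["end"].astype(int)
    df["label"] = df["label"].fillna("")
    return RegionSet(df)


def write_bed(regions: RegionSet, path: str) -> None:
    """Write 1-based inclusive regions as standard 0-based half-open BED."""
    df = regions.regions.copy()
    df["start"] = df["start"] - 1
    df.to_csv(path, sep="\t", header=False, index=False)


def read_pop_map(path: str) -> PopulationAssignment:
    """Two-column TSV (sample_id, population) -> :class:`PopulationAssignment`."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "population"], dtype=str)
    if df["sample"].duplicated().any():
        dups = df.loc[df["sample"].duplicated(), "sample"].tolist()
        raise ValueError(f"duplicate samples in population map: {dups}")
    return PopulationAssignment(dict(zip(df["sample"], df["population"])))


def write_pop_map(assignment: PopulationAssignment, path: str) -> None:
    pd.DataFrame(assignment.mapping.items()).to_csv(
        path, sep="\t", header=False, index=False
    )
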