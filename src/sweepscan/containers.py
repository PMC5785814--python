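"""Core in-memory containers shared across the pipeline.

Coordinates are 1-based inclusive everywhere in memory; the single point of
conversion to/from on-disk BED (0-based half-open) lives in
:mod:`sweepscan.genomic_io`.

Genotypes are stored as an ``int8`` matrix of shape (n_sites, n_samples)
with codes ``HOM_REF=0``, ``HET=1``, ``HOM_ALT=2``, ``MISSING=-1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

HOM_REF: int = 0
HET: int = 1
HOM_ALT: int = 2
MISSING: int = -1

GT_NAMES: dict[int, str] = {
    HOM_REF: "hom_ref",
    HET: "het",
    HOM_ALT: "hom_alt",
    MISSING: "missing",
}
GT_CODES: dict[str, int] = {v: k for k, v in GT_NAMES.items()}

SNP = "SNP"
INDEL = "INDEL"

#: Per-site columns of :attr:`VariantTable.sites`. ``total_depth`` and the
#: four strand counts use ``-1`` as the "unknown" sentinel; ``qual`` uses NaN.
SITE_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "var_class",
    "qual",
    "total_depth",
    "ref_fwd",
    "ref_rev",
    "alt_fwd",
    "alt_rev",
]


def classify_alleles(ref: str, alt: str) -> str:
    """Return SNP for single-base substitutions, INDEL for length changes."""
    if len(ref) == 1 and len(alt) == 1:
        return SNP
    if len(ref) != len(alt):
        return INDEL
    raise ValueError(f"alleles {ref}>{alt} are neither a SNP nor an INDEL")


@dataclass
class VariantTable:
    """Biallelic variant records plus the sample genotype matrix.

    Parameters
    ----------
    sites
        One row per variant with columns :data:`SITE_COLUMNS`.
    genotypes
        ``int8`` array of shape ``(len(sites), len(samples))``.
    samples
        Sample identifiers, column order of ``genotypes``.
    """

    sites: pd.DataFrame
    genotypes: np.ndarray
    samples: list[str]

    def __post_init__(self) -> None:
        missing_cols = [c for c in SITE_COLUMNS if c not in self.sites.columns]
        if missing_cols:
            raise ValueError(f"sites table lacks columns: {missing_cols}")
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.sites), len(self.samples)):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.sites)} sites x {len(self.samples)} samples"
            )
        self.sites = self.sites.reset_index(drop=True)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def is_sorted(self) -> bool:
        s = self.sites
        key = pd.MultiIndex.from_arrays([s["chrom"], s["pos"]])
        return key.is_monotonic_increasing

    def sort(self) -> "VariantTable":
        order = self.sites.sort_values(["chrom", "pos"], kind="mergesort").index
        return self.subset(np.asarray(order))

    def subset(self, index: np.ndarray) -> "VariantTable":
        """Row-subset by boolean mask or integer index array."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return VariantTable(
            sites=self.sites.iloc[index].reset_index(drop=True),
            genotypes=self.genotypes[index],
            samples=list(self.samples),
        )

    def of_class(self, var_class: str) -> "VariantTable":
        return self.subset((self.sites["var_class"] == var_class).to_numpy())

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n_sites


@dataclass
class PopulationAssignment:
    """Sample -> population label map (exactly two populations for the scan)."""

    mapping: dict[str, str]

    @property
    def populations(self) -> list[str]:
        seen: list[str] = []
        for pop in self.mapping.values():
            if pop not in seen:
                seen.append(pop)
        return seen

    def require_two(self) -> tuple[str, str]:
        pops = self.populations
        if len(pops) != 2:
            raise ValueError(f"exactly two populations required, got {pops}")
        return pops[0], pops[1]

    def indices(self, samples: Sequence[str]) -> dict[str, np.ndarray]:
        """Column indices into a genotype matrix, per population."""
        missing = [s for s in self.mapping if s not in samples]
        if missing:
            raise ValueError(f"samples missing from table: {missing}")
        out: dict[str, list[int]] = {p: [] for p in self.populations}
        for i, s in enumerate(samples):
            if s in self.mapping:
                out[self.mapping[s]].append(i)
        return {p: np.asarray(ix, dtype=np.intp) for p, ix in out.items()}


@dataclass
class RegionSet:
    """Genomic intervals, 1-based inclusive, sorted by (chrom, start)."""

    regions: pd.DataFrame  # columns: chrom, start, end, label

    def __post_init__(self) -> None:
        df = self.regions.copy()
        if "label" not in df.columns:
            df["label"] = ""
        df = df[["chrom", "start", "end", "label"]]
        if len(df) and (df["start"] > df["end"]).any():
            bad = df[df["start"] > df["end"]].iloc[0]
            raise ValueError(f"interval start > end: {tuple(bad)}")
        if len(df) and (df["start"] < 1).any():
            raise ValueError("1-based interval start must be >= 1")
        self.regions = df.sort_values(["chrom", "start", "end"]).reset_index(drop=True)

    @classmethod
    def from_records(
        cls, records: Iterable[tuple], labels: bool = True
    ) -> "RegionSet":
        rows = []
        for rec in records:
            chrom, start, end = rec[0], int(rec[1]), int(rec[2])
            label = str(rec[3]) if labels and len(rec) > 3 else ""
            rows.append((chrom, start, end, label))
        return cls(pd.DataFrame(rows, columns=["chrom", "start", "end", "label"]))

    def total_length(self) -> int:
        if not len(self.regions):
            return 0
        return int((self.regions["end"] - self.regions["start"] + 1).sum())

    def by_chrom(self) -> Mapping[str, pd.DataFrame]:
        return {c: g for c, g in self.regions.groupby("chrom", sort=True)}

    def __len__(self) -> int:
        return len(self.regions)
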