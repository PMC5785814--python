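"""End-to-end orchestration: simulate or ingest -> filter -> stats -> dual
Fst scans -> regions -> QTL permutation -> concordance.

All randomness flows from one root seed, split per stage by a fixed
derivation (`numpy.random.SeedSequence`), so identical config + seed
reproduce byte-identical data artifacts; the manifest records a SHA-256
hash per artifact.  Plots are best-effort and excluded from hashing.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import concordance as conc
from . import genomic_io as gio
from . import region_analysis as ra
from . import variant_stats as vs
from .containers import SNP
from .filtration import FilterConfig, apply_filters
from .fst_scan import genome_weighted_fst, site_components_table, sliding_window_fst
from .synthetic_data import SimulationConfig, make_sweep_intervals, simulate_cohort

log = logging.getLogger(__name__)

_ALL_STAGES = ("filter", "stats", "scan", "regions", "qtl_overlap", "concordance")


@dataclass
class PipelineConfig:
    """One configuration object for a full run; exactly one input source."""

    out_dir: str = "sweepscan_out"
    seed: int = 0
    # input source: either a simulation...
    simulation: SimulationConfig | None = None
    # ...or files on disk
    vcf: str | None = None
    pop_map: str | None = None
    genes_bed: str | None = None
    qtls_bed: str | None = None
    chrom_sizes: str | None = None
    array_genotypes: str | None = None
    concordance_sample: str | None = None

    filter: FilterConfig = field(default_factory=FilterConfig)
    window_bp: int = 20_000
    step_bp: int = 10_000
    snp_min_markers: int = 10
    indel_min_markers: int = 5
    top_level: float = 0.99
    strong_level: float = 0.999
    n_perm: int = 1000
    per_chromosome: bool = False
    corruption_rate: float = 0.02  # simulated-array genotype error, simulation mode
    stages: tuple[str, ...] = _ALL_STAGES

    def validate(self) -> None:
        if (self.simulation is None) == (self.vcf is None):
            raise ValueError("exactly one input source: simulation or vcf")
        unknown = set(self.stages) - set(_ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "simulation" in raw and raw["simulation"] is not None:
            sim = raw.pop("simulation")
            if isinstance(sim, dict):
                if "sweep_intervals" in sim:
                    sim["sweep_intervals"] = tuple(
                        tuple(iv) for iv in sim["sweep_intervals"]
                    )
                raw["simulation"] = SimulationConfig(**sim)
            elif sim:
                raw["simulation"] = SimulationConfig()
        if "filter" in raw and isinstance(raw["filter"], dict):
            raw["filter"] = FilterConfig(**raw["filter"])
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


def _derived_seeds(root: int, n: int) -> list[int]:
    """Fixed per-stage derivation; values kept below 2**31."""
    state = np.random.SeedSequence(root).generate_state(n, dtype=np.uint32)
    return [int(s) & 0x7FFFFFFF for s in state]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _chrom_lengths_from_vcf(path: str) -> dict[str, int]:
    import pysam

    with pysam.VariantFile(path) as vf:
        out = {
            name: contig.length
            for name, contig in vf.header.contigs.items()
            if contig.length
        }
    if not out:
        raise ValueError("VCF header carries no contig lengths; provide chrom_sizes")
    return out


def run(config: PipelineConfig) -> dict:
    """Execute all enabled stages; return (and write) the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    logging.getLogger("sweepscan").addHandler(handler)
    sim_seed, corrupt_seed, perm_seed = _derived_seeds(config.seed, 3)

    artifacts: dict[str, str] = {}
    plots: dict[str, str] = {}
    counts: dict[str, float] = {}

    def _save_df(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, sep="\t", index=False)
        artifacts[name] = str(path)

    try:
        # --- input stage -------------------------------------------------
        if config.simulation is not None:
            sim = replace(config.simulation, seed=sim_seed)
            variants, pops, truth, genes, qtls = simulate_cohort(sim)
            chrom_lengths = dict(sim.chrom_lengths)
            gio.write_vcf(
                variants,
                str(out / "cohort.vcf"),
                chrom_lengths,
                extra_header_lines=[
                    "##simulation=balding-nichols two-population model"
                ],
            )
            artifacts["cohort.vcf"] = str(out / "cohort.vcf")
            truth.write(str(out / "truth.tsv"))
            artifacts["truth.tsv"] = str(out / "truth.tsv")
            gio.write_pop_map(pops, str(out / "pops.tsv"))
            artifacts["pops.tsv"] = str(out / "pops.tsv")
            gio.write_bed(genes, str(out / "genes.bed"))
            artifacts["genes.bed"] = str(out / "genes.bed")
            gio.write_bed(qtls, str(out / "qtls.bed"))
            artifacts["qtls.bed"] = str(out / "qtls.bed")
        else:
            pops = gio.read_pop_map(config.pop_map)
            variants = gio.read_vcf(config.vcf, pops).sort()
            genes = gio.read_bed(config.genes_bed) if config.genes_bed else None
            qtls = gio.read_bed(config.qtls_bed) if config.qtls_bed else None
            if config.chrom_sizes:
                sizes = pd.read_csv(
                    config.chrom_sizes, sep="\t", header=None,
                    names=["chrom", "length"], dtype={"chrom": str},
                )
                chrom_lengths = dict(zip(sizes["chrom"], sizes["length"].astype(int)))
            else:
                chrom_lengths = _chrom_lengths_from_vcf(config.vcf)
        counts["input_sites"] = variants.n_sites
        log.info("input: %d sites, %d samples", variants.n_sites, variants.n_samples)

        # --- filtration --------------------------------------------------
        if "filter" in config.stages:
            variants, report = apply_filters(variants, config.filter)
            _save_df(report.to_frame(), "filter_report.tsv")
            gio.write_vcf(variants, str(out / "filtered.vcf"), chrom_lengths)
            artifacts["filtered.vcf"] = str(out / "filtered.vcf")
            counts["filtered_sites"] = variants.n_sites
            log.info("filter: %d -> %d sites", report.input_count, report.output_count)

        # --- descriptive stats -------------------------------------------
        if "stats" in config.stages:
            idx = pops.indices(variants.samples)
            spectra = {}
            rows = []
            for pop, cols in idx.items():
                aafs = vs.aaf_by_site(variants, cols)
                spec = vs.aaf_spectrum(aafs)
                spectra[pop] = spec
                rows.append(
                    (pop, spec.n_sites, spec.fraction_fixed, spec.fraction_low)
                )
            _save_df(
                pd.DataFrame(
                    rows, columns=["population", "n_sites", "fraction_fixed", "fraction_low"]
                ),
                "aaf_summary.tsv",
            )
            _save_df(
                vs.per_individual_het_fraction(variants).rename_axis("sample").reset_index(),
                "het_fractions.tsv",
            )
            snps = variants.of_class(SNP)
            if snps.n_sites:
                try:
                    counts["tstv_ratio"] = vs.tstv_ratio(snps)
                except ValueError:
                    pass
                _save_df(
                    vs.substitution_spectrum(snps).rename_axis("substitution")
                    .reset_index(name="proportion"),
                    "substitution_spectrum.tsv",
                )
            part = vs.line_partition(variants, pops)
            _save_df(
                pd.DataFrame(
                    [
                        ("shared", part.shared),
                        (f"{part.pop1}_only", part.pop1_only),
                        (f"{part.pop2}_only", part.pop2_only),
                    ],
                    columns=["partition", "count"],
                ),
                "line_partition.tsv",
            )
            _save_df(vs.variant_density(variants, chrom_lengths), "density.tsv")
            try:
                from .plots import plot_aaf_spectrum

                plot_aaf_spectrum(spectra, str(out / "aaf_spectrum.png"))
                plots["aaf_spectrum.png"] = str(out / "aaf_spectrum.png")
            except Exception as exc:  # plots never fail a run
                log.warning("aaf plot failed: %s", exc)

        # --- dual Fst scans ----------------------------------------------
        windows: dict[str, pd.DataFrame] = {}
        if "scan" in config.stages:
            components = site_components_table(variants, pops)
            counts["genome_weighted_fst"] = genome_weighted_fst(components)
            for var_class, min_markers in (
                ("SNP", config.snp_min_markers),
                ("INDEL", config.indel_min_markers),
            ):
                sub = components[components["var_class"] == var_class]
                w = sliding_window_fst(
                    sub, chrom_lengths, config.window_bp, config.step_bp, min_markers
                )
                windows[var_class] = w
                _save_df(w, f"windows_{var_class.lower()}.tsv")
                counts[f"n_windows_{var_class.lower()}"] = int(w["qualifies"].sum())

        # --- region calling + annotation + correlation ---------------------
        if "regions" in config.stages and windows:
            for var_class, w in windows.items():
                lc = var_class.lower()
                try:
                    top = ra.percentile_select(w, config.top_level)
                    strong = ra.percentile_select(w, config.strong_level)
                except ValueError as exc:
                    log.warning("region calling skipped for %s: %s", var_class, exc)
                    continue
                merged = ra.merge_windows(top.windows)
                gio.write_bed(merged, str(out / f"regions_{lc}.bed"))
                artifacts[f"regions_{lc}.bed"] = str(out / f"regions_{lc}.bed")
                counts[f"n_regions_{lc}"] = len(merged)
                counts[f"top_cutoff_{lc}"] = top.cutoff
                counts[f"strong_cutoff_{lc}"] = strong.cutoff
                if genes is not None and len(genes):
                    table, n_unique = ra.annotate_regions(merged, genes)
                    _save_df(table, f"regions_{lc}_genes.tsv")
                    counts[f"n_genes_{lc}"] = n_unique
                try:
                    from .plots import plot_manhattan

                    plot_manhattan(
                        w,
                        {
                            "top": (top.cutoff, "tab:blue"),
                            "strong": (strong.cutoff, "tab:red"),
                        },
                        str(out / f"manhattan_{lc}.png"),
                        title=f"{var_class} windows",
                    )
                    plots[f"manhattan_{lc}.png"] = str(out / f"manhattan_{lc}.png")
                except Exception as exc:
                    log.warning("manhattan plot failed: %s", exc)
            if {"SNP", "INDEL"} <= windows.keys():
                try:
                    r, p, n = ra.correlate_scans(
                        windows["SNP"], windows["INDEL"], config.top_level
                    )
                    with open(out / "scan_correlation.json", "w") as fh:
                        json.dump({"r": r, "p": p, "n": n}, fh, indent=2, sort_keys=True)
                    artifacts["scan_correlation.json"] = str(out / "scan_correlation.json")
                except ValueError as exc:
                    log.warning("scan correlation skipped: %s", exc)

        # --- QTL overlap permutation ---------------------------------------
        if "qtl_overlap" in config.stages and windows and qtls is not None and len(qtls):
            overlap_out = {}
            for var_class in windows:
                lc = var_class.lower()
                bed = out / f"regions_{lc}.bed"
                if not bed.exists():
                    continue
                merged = gio.read_bed(str(bed))
                test = ra.qtl_overlap_permutation(
                    merged,
                    qtls,
                    chrom_lengths,
                    n_perm=config.n_perm,
                    seed=perm_seed,
                    per_chromosome=config.per_chromosome,
                )
                overlap_out[lc] = test.to_dict()
                try:
                    from .plots import plot_overlap_test

                    plot_overlap_test(
                        test, str(out / f"qtl_overlap_{lc}.png"), title=f"{var_class}"
                    )
                    plots[f"qtl_overlap_{lc}.png"] = str(out / f"qtl_overlap_{lc}.png")
                except Exception as exc:
                    log.warning("overlap plot failed: %s", exc)
            if overlap_out:
                with open(out / "qtl_overlap.json", "w") as fh:
                    json.dump(overlap_out, fh, indent=2, sort_keys=True)
                artifacts["qtl_overlap.json"] = str(out / "qtl_overlap.json")

        # --- concordance ----------------------------------------------------
        if "concordance" in config.stages:
            report = None
            if config.simulation is not None:
                sample = config.concordance_sample or variants.samples[0]
                snps = variants.of_class(SNP)
                col = snps.samples.index(sample)
                rng = np.random.default_rng(corrupt_seed)
                arr = snps.sites[["chrom", "pos", "ref", "alt"]].copy()
                gt = snps.genotypes[:, col].astype(int).copy()
                flip = (gt >= 0) & (rng.random(len(gt)) < config.corruption_rate)
                shift = rng.integers(1, 3, size=len(gt))
                gt[flip] = (gt[flip] + shift[flip]) % 3
                arr["genotype"] = gt
                arr.to_csv(out / "array_genotypes.tsv", sep="\t", index=False)
                artifacts["array_genotypes.tsv"] = str(out / "array_genotypes.tsv")
                report = conc.compare_to_array(snps, arr, sample, mode="pos")
            elif config.array_genotypes and config.concordance_sample:
                arr = conc.read_array_genotypes(
                    config.array_genotypes, config.concordance_sample
                )
                report = conc.compare_to_array(
                    variants.of_class(SNP), arr, config.concordance_sample, mode="pos"
                )
            if report is not None:
                with open(out / "concordance.json", "w") as fh:
                    json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
                artifacts["concordance.json"] = str(out / "concordance.json")
                counts["concordance_error_rate_pct"] = report.error_rate_pct

        manifest = {
            "seed": config.seed,
            "stages": list(config.stages),
            "model": "balding-nichols" if config.simulation is not None else "vcf-input",
            "counts": counts,
            "artifacts": {
                name: {"path": path, "sha256": _sha256(Path(path))}
                for name, path in sorted(artifacts.items())
            },
            "plots": sorted(plots),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return manifest
    finally:
        logging.getLogger("sweepscan").removeHandler(handler)
        handler.close()
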