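"""Best-effort figure artifacts: AAF spectra, window-Fst Manhattan plots,
and observed-vs-null overlap bars.  Plot failures never fail a run."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .region_analysis import OverlapTest
from .variant_stats import AafSpectrum


def plot_aaf_spectrum(spectra: dict[str, AafSpectrum], path: str) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    for label, spec in spectra.items():
        centers = 0.5 * (spec.bin_edges[:-1] + spec.bin_edges[1:])
        ax.bar(
            centers,
            spec.hist / spec.hist.sum(),
            width=np.diff(spec.bin_edges) * 0.9 / max(1, len(spectra)),
            alpha=0.6,
            label=label,
        )
    ax.set_xlabel("Alternate allele frequency")
    ax.set_ylabel("Fraction of sites")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_manhattan(
    windows: pd.DataFrame, cutoffs: dict[str, float], path: str, title: str = ""
) -> None:
    """Window weighted Fst along the concatenated genome with cutoff lines."""
    fig, ax = plt.subplots(figsize=(9, 3.5))
    offset = 0
    ticks, tick_labels = [], []
    for i, (chrom, grp) in enumerate(windows.groupby("chrom", sort=False)):
        grp = grp[grp["qualifies"]]
        x = grp["start"].to_numpy() + offset
        ax.scatter(x, grp["weighted_fst"], s=3, color=f"C{i % 2}")
        ticks.append(offset + (grp["start"].max() if len(grp) else 0) / 2)
        tick_labels.append(str(chrom))
        offset += int(windows.loc[windows["chrom"] == chrom, "end"].max())
    for label, (value, color) in cutoffs.items():
        ax.axhline(value, color=color, lw=1, label=f"{label} ({value:.3f})")
    ax.set_xticks(ticks)
    ax.set_xticklabels(tick_labels)
    ax.set_ylabel("Weighted Fst")
    ax.set_title(title)
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_overlap_test(test: OverlapTest, path: str, title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.bar(
        ["observed", "null mean"],
        [test.observed_overlap_mb, test.null_mean],
        yerr=[0, test.null_sd],
        color=["firebrick", "steelblue"],
        capsize=4,
    )
    ax.set_ylabel("Region bp overlapping QTLs (Mb)")
    ax.set_title(title or f"p = {test.p_value:.4g}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
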