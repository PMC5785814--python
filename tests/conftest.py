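"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sweepscan.containers import PopulationAssignment, VariantTable


def make_variants(
    records: list[dict],
    n_samples: int = 4,
    genotypes: np.ndarray | None = None,
    samples: list[str] | None = None,
) -> VariantTable:
    """Build a VariantTable from partial per-site dicts with passing defaults."""
    defaults = dict(
        chrom="1",
        ref="A",
        alt="G",
        var_class="SNP",
        qual=100.0,
        total_depth=30,
        ref_fwd=10,
        ref_rev=10,
        alt_fwd=5,
        alt_rev=5,
    )
    rows = [{**defaults, **r} for r in records]
    sites = pd.DataFrame(rows)
    if samples is None:
        samples = [f"s{i}" for i in range(n_samples)]
    if genotypes is None:
        genotypes = np.ones((len(rows), len(samples)), dtype=np.int8)
    return VariantTable(sites=sites, genotypes=genotypes, samples=samples)


def two_pop_assignment(samples: list[str]) -> PopulationAssignment:
    half = len(samples) // 2
    return PopulationAssignment(
        {s: ("pop1" if i < half else "pop2") for i, s in enumerate(samples)}
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A small simulated cohort with engineered filter failures, shared read-only."""
    from sweepscan.synthetic_data import SimulationConfig, simulate_cohort

    config = SimulationConfig(
        seed=42,
        chrom_lengths={"1": 500_000, "2": 300_000},
        snp_density=4.0,
        indel_density=1.0,
        fail_fraction=0.01,
    )
    return config, simulate_cohort(config)
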