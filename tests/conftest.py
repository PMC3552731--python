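"""Shared fixtures: small synthetic panels generated at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from wgpkit.genotypes import GenotypePanel, StandardizedGenotypes
from wgpkit.simulate import SimConfig, simulate_genotypes, simulate_trait


def small_sim_config(**overrides) -> SimConfig:
    """A fast desk-scale configuration: 120 lines x 600 SNPs on short chromosomes."""
    defaults = dict(
        n_lines=120,
        n_snps_per_chrom=[60] * 10,
        chrom_lengths_bp=[3_000_000] * 10,
        seed=0,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def small_panel():
    return simulate_genotypes(small_sim_config())


@pytest.fixture(scope="session")
def small_polygenic():
    cfg = small_sim_config(architecture="polygenic", heritability=0.9, seed=1)
    panel = simulate_genotypes(cfg)
    trait, truth = simulate_trait(panel, cfg)
    return panel, trait, truth


@pytest.fixture(scope="session")
def small_major_qtl():
    cfg = small_sim_config(
        architecture="major_qtl", qtl_variance_fraction=0.29,
        qtl_chromosome=2, heritability=0.95, seed=2,
    )
    panel = simulate_genotypes(cfg)
    trait, truth = simulate_trait(panel, cfg)
    return panel, trait, truth


def toy_panel(dosages, chrom=None, pos=None, **kwargs) -> GenotypePanel:
    """Hand-built panel from an explicit dosage matrix."""
    X = np.asarray(dosages, dtype=float)
    n, p = X.shape
    snp_map = pd.DataFrame({
        "snp_id": [f"s{j}" for j in range(p)],
        "chrom": chrom if chrom is not None else [1] * p,
        "pos": pos if pos is not None else list(range(1, p + 1)),
    })
    return GenotypePanel(
        dosages=X,
        line_ids=[f"l{i}" for i in range(n)],
        snp_map=snp_map,
        **kwargs,
    )


def random_standardized(rng: np.random.Generator, n: int, p: int) -> StandardizedGenotypes:
    """Standardized genotypes from random inbred dosages, for model unit tests."""
    X = rng.choice([0.0, 2.0], size=(n, p), p=[0.6, 0.4])
    # guarantee polymorphism
    for j in range(p):
        if X[:, j].std() == 0:
            X[rng.integers(n), j] = 2.0 - X[0, j]
    means, sds = X.mean(0), X.std(0)
    snp_map = pd.DataFrame({"snp_id": [f"s{j}" for j in range(p)],
                            "chrom": [1] * p, "pos": list(range(1, p + 1))})
    return StandardizedGenotypes(
        Z=(X - means) / sds, col_means=means, col_sds=sds,
        snp_map=snp_map, line_ids=[f"l{i}" for i in range(n)],
    )
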