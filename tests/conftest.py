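"""Shared fixtures: small synthetic bundles generated at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from rfigp.genio import GenotypeMatrix
from rfigp.pipeline import DataBundle, prepare_phenotypes
from rfigp.synthetic_data import SimulationConfig, simulate_bundle


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Desk-scale bundle: 3 countries, heifers, nested panels."""
    return SimulationConfig(
        n_countries=3, animals_per_country=(120, 100, 100), n_heifers=60,
        n_chrom=4, n_sequence_variants=1600, n_qtl=300, n_large_qtl=8,
        n_bw_qtl=60, n_bw_large=4,
        array_fraction=0.4, n_founder_haplotypes=60, n_sires_per_country=10,
        seed=20210712)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    gm, ped, records, truth = simulate_bundle(small_config)
    return DataBundle(gm, ped, records, small_config, truth)


@pytest.fixture(scope="session")
def small_phenos(small_bundle):
    return prepare_phenotypes(small_bundle)


@pytest.fixture()
def tiny_gm() -> GenotypeMatrix:
    variants = pd.DataFrame({
        "id": ["v1", "v2", "v3"], "chrom": ["1", "1", "2"],
        "pos": [100, 900, 250], "a1": ["A", "C", "G"], "a2": ["B", "T", "A"],
    })
    dosages = np.array([[2, 1, 0], [1, 0, 2], [0, 1, 1], [2, 2, 0]])
    return GenotypeMatrix(["a1", "a2", "a3", "a4"], variants, dosages)


def hwe_genotypes(n: int, m: int, seed: int = 0,
                  p: np.ndarray | None = None) -> GenotypeMatrix:
    """Unstructured Hardy-Weinberg population (iid binomial dosages)."""
    rng = np.random.default_rng(seed)
    if p is None:
        p = rng.uniform(0.05, 0.95, size=m)
    dosages = rng.binomial(2, p, size=(n, m)).astype(np.int8)
    variants = pd.DataFrame({
        "id": [f"s{i}" for i in range(m)],
        "chrom": ["1"] * m, "pos": np.arange(1, m + 1),
        "a1": ["A"] * m, "a2": ["B"] * m,
    })
    return GenotypeMatrix([f"i{i}" for i in range(n)], variants, dosages)
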