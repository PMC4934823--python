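"""Shared fixtures: small synthetic panels generated at test time."""

import numpy as np
import pandas as pd
import pytest

import hybridpred as hp


@pytest.fixture(scope="session")
def small_panel():
    """10 female + 3 male inbred parents, 60 markers on 3 chromosomes."""
    geno, parents = hp.simulate_parents(
        n_female=10, n_male=3, n_markers=60, n_chromosomes=3, seed=11
    )
    return geno, parents


@pytest.fixture(scope="session")
def factorial(small_panel):
    """Full factorial plan, hybrid genotypes and the combined matrix."""
    geno, parents = small_panel
    plan = hp.make_factorial(parents, "full")
    hybrids = hp.derive_hybrid_genotypes(geno, plan)
    return plan, hybrids, geno.concat(hybrids)


@pytest.fixture()
def toy_geno():
    """Hand-built 6 x 4 genotype matrix with known dosage patterns."""
    dosages = pd.DataFrame(
        [
            [0.0, 2.0, 2.0, 0.0],
            [2.0, 0.0, 2.0, 0.0],
            [0.0, 0.0, 2.0, 2.0],
            [1.0, 1.0, 2.0, 0.0],
            [1.0, 0.0, 2.0, 1.0],
            [2.0, 1.0, 2.0, 2.0],
        ],
        index=[f"g{i}" for i in range(6)],
        columns=["m1", "m2", "m3", "m4"],
    )
    mmap = pd.DataFrame(
        {"chrom": ["c1", "c1", "c2", "c2"], "pos_cm": [0.0, 10.0, 0.0, 5.0]},
        index=dosages.columns,
    )
    return hp.GenotypeMatrix(dosages, mmap)


def random_design_matrices(n, m, seed):
    """Random dosage panel coded into design matrices (test helper)."""
    rng = np.random.default_rng(seed)
    dosages = pd.DataFrame(
        rng.integers(0, 3, size=(n, m)).astype(float),
        index=[f"i{i}" for i in range(n)],
        columns=[f"mk{j}" for j in range(m)],
    )
    mmap = pd.DataFrame(
        {"chrom": "c1", "pos_cm": np.arange(m, dtype=float)}, index=dosages.columns
    )
    return hp.code_design_matrices(hp.GenotypeMatrix(dosages, mmap))
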