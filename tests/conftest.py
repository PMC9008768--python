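"""Shared fixtures: small seeded cohorts and toy genotype matrices."""

import numpy as np
import pandas as pd
import pytest

from rvscca import BlockSpec, GenotypeMatrix, SimulationConfig, simulate_cohort


def make_genotypes(values, chrom=None, bp=None, region=None) -> GenotypeMatrix:
    """Toy GenotypeMatrix from a plain array with auto annotations."""
    values = np.asarray(values, dtype=float)
    p = values.shape[1]
    snps = pd.DataFrame(
        {
            "snp_id": [f"rs{k}" for k in range(p)],
            "chrom": chrom if chrom is not None else [1] * p,
            "bp": bp if bp is not None else [1000 * (k + 1) for k in range(p)],
            "minor_allele": ["A"] * p,
            "major_allele": ["G"] * p,
            "region": region if region is not None else [None] * p,
        }
    )
    return GenotypeMatrix(
        values=values,
        snps=snps,
        subject_ids=[f"S{i:03d}" for i in range(values.shape[0])],
    )


@pytest.fixture(scope="session")
def unlinked_config() -> SimulationConfig:
    """Moderate cohort with independent SNPs: causal/null sharply defined."""
    return SimulationConfig(
        seed=11,
        q_rois=8,
        block_spec=[
            BlockSpec("6p21.1-q15", 6, 43_000_000, 91_000_000, [1] * 30, 0.0),
            BlockSpec("10p14-q24", 10, 10_000_000, 100_000_000, [1] * 30, 0.0),
        ],
    )


@pytest.fixture(scope="session")
def unlinked_cohort(unlinked_config):
    return simulate_cohort(unlinked_config)


@pytest.fixture(scope="session")
def default_cohort():
    """Defaults: LD blocks of 5 inside two linkage regions, 10 causal SNPs."""
    cfg = SimulationConfig(seed=7, q_rois=8)
    return cfg, simulate_cohort(cfg)
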