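import numpy as np
import pytest

from aglsgwas import CausalEffect, SimulationConfig, TraitSpec, simulate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def small_dataset():
    """400 individuals x 30 SNPs, one strong causal SNP, one pleiotropic pair."""
    cfg = SimulationConfig(
        n_individuals=400,
        n_snps=30,
        seed=7,
        traits={
            "milk": TraitSpec(sigma_a2=0.3, sigma_e2=0.7, pta_reliability=0.8),
            "fat": TraitSpec(sigma_a2=0.3, sigma_e2=0.7, pta_reliability=0.8),
        },
        causal=[
            CausalEffect(3, "milk", alpha=1.5),
            CausalEffect(3, "fat", alpha=-1.0),  # antagonistic pleiotropy
            CausalEffect(11, "fat", alpha=0.8, delta=0.4),
        ],
    )
    return simulate_dataset(cfg)
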