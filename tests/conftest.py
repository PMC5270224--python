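import numpy as np
import pytest

from hypervar import InjectedSet, SimConfig, simulate_cohort

CELLS = ("monocyte", "neutrophil", "naive_T")


def gene_ids(n, start=0):
    return [f"gene_{i:05d}" for i in range(start, start + n)]


def cpg_ids(n, start=0):
    return [f"cg{i:07d}" for i in range(start, start + n)]


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-donor cohort with injected effects of every kind."""
    cfg = SimConfig(
        n_donors=60,
        n_genes=400,
        n_cpgs=400,
        seed=7,
        injected_sets=(
            InjectedSet(gene_ids(20), "specific:neutrophil", 4.0),
            InjectedSet(gene_ids(10, 20), "shared:monocyte+neutrophil", 4.0),
            InjectedSet(gene_ids(10, 30), "common", 4.0),
            InjectedSet(cpg_ids(20), "specific:neutrophil", 4.0, "methylation"),
        ),
        sex_effect_genes=(("gene_00050", 2.0),),
        trait_effect_features=(("gene_00051", "bmi", 0.6),),
        seasonal_features=(("gene_00052", 1.0),),
        age_effect_cpgs=(("cg0000050", 0.05),),
        coupled_cpgs=(("cg0000060", "gene_00060", -0.7),),
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """A trend-bearing cohort with no injected effects of any kind."""
    cfg = SimConfig(n_donors=60, n_genes=800, n_cpgs=200, seed=19)
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
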