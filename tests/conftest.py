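import numpy as np
import pytest

from drpkit import cohort as cohort_mod
from drpkit import simulate


@pytest.fixture(scope="session")
def planted_cohort():
    """Default synthetic benchmark cohort (1,000 pairs, strong effect)."""
    cohort, truth = simulate.generate_cohort(simulate.SimConfig(seed=1))
    cohort_mod.assign_labels(cohort)
    return cohort, truth


@pytest.fixture(scope="session")
def small_cohort():
    """Small labeled cohort for fast pipeline tests (250 pairs)."""
    cfg = simulate.SimConfig(
        n_cell_lines=50, n_genes=40, n_drugs=5, planted_causal_genes=6, seed=3
    )
    cohort, truth = simulate.generate_cohort(cfg)
    cohort_mod.assign_labels(cohort)
    return cohort, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
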