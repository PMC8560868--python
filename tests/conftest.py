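"""Shared fixtures: small cohorts and the two session-scoped reduced-scale
pipeline runs (separable and null) that several protocol tests examine."""

from __future__ import annotations

import numpy as np
import pytest

import neurodct as nd
from neurodct import cnn, ranking

#: reduced execution profile used by the end-to-end tests: 32^3 grid,
#: 20 subjects per class, 10 training epochs
REDUCED_SHAPE = (32, 32, 32)
REDUCED_N = 20
REDUCED_EPOCHS = 10
COHORT_SEED = 7
TRAIN_SEED = 1


def reduced_cohort(effect_size: float, seed: int = COHORT_SEED):
    spec = nd.CohortSpec(
        n_per_class=REDUCED_N,
        effect_size=effect_size,
        noise_sd=0.5,
        seed=seed,
        shape=REDUCED_SHAPE,
    )
    return nd.generate_cohort(spec)


@pytest.fixture(scope="session")
def signal_cohort():
    """Separable cohort: regional effect five times the voxel noise s.d."""
    return reduced_cohort(effect_size=2.5)


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with no class signal at all."""
    return reduced_cohort(effect_size=0.0)


@pytest.fixture(scope="session")
def signal_run(signal_cohort):
    """Method 1 (spatial domain, blur augmentation, 5-fold CV) run end to end
    on the separable cohort."""
    cfg = nd.enumerate_methods()[0]
    return ranking.run_method(
        cfg, signal_cohort, cnn.TrainConfig(max_epochs=REDUCED_EPOCHS, seed=TRAIN_SEED)
    )


@pytest.fixture(scope="session")
def null_run(null_cohort):
    """The same method-1 configuration on the signal-free cohort."""
    cfg = nd.enumerate_methods()[0]
    return ranking.run_method(
        cfg, null_cohort, cnn.TrainConfig(max_epochs=REDUCED_EPOCHS, seed=TRAIN_SEED)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
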