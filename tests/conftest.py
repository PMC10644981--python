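import numpy as np
import pytest

from connectomlp import (
    SimConfig,
    TrainConfig,
    cohort_arrays,
    generate_cohort,
    make_folds,
    run_repeated,
)

# hidden widths for fast unit-test networks; acceptance tests use the defaults
SMALL_HIDDEN = (32, 16, 8)


def small_train_config(**kw) -> TrainConfig:
    kw.setdefault("hidden", SMALL_HIDDEN)
    return TrainConfig(**kw)


@pytest.fixture(scope="session")
def dk_table():
    from connectomlp import NodeTable
    return NodeTable.default()


@pytest.fixture(scope="session")
def separable_sim():
    """A 12-node cohort with an overwhelming planted effect: linearly separable."""
    cfg = SimConfig(n_nodes=12, n_per_group=(10, 10), effect_size=5.0,
                    subject_noise_sd=0.01, n_planted=4,
                    n_cross_hemisphere_planted=2, seed=7)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def separable_cohort(separable_sim):
    return cohort_arrays(separable_sim)


@pytest.fixture(scope="session")
def separable_run(separable_cohort):
    """3 repeats of 5-fold CV on the separable cohort, models retained."""
    co = separable_cohort
    folds = make_folds(co.y, k=5, split_seed=0)
    return run_repeated(co.X, co.y, folds, n_seeds=3, cfg=small_train_config())
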