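import numpy as np
import pytest

from mtlprofile import (
    ArchitectureConfig,
    CohortSpec,
    TrainingConfig,
    encode,
    fit_encoders,
    generate_cohort,
    make_plan,
    synthetic_profile_spec,
    uniform_dependence,
)


@pytest.fixture(scope="session")
def tiny_arch():
    return ArchitectureConfig(h=2, r=8)


@pytest.fixture(scope="session")
def fast_cfg():
    return TrainingConfig(max_epochs=12, patience=4, min_epochs=3, batch_size=16, seed=0)


@pytest.fixture(scope="session")
def small_cohort():
    """150-row cohort, 3 correlated 3-level items."""
    spec = CohortSpec(
        n_rows=150,
        profile=synthetic_profile_spec(3),
        dependence=uniform_dependence(3, 0.6),
        seed=11,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def encoded_splits(small_cohort):
    """(train, val, test) EncodedMatrix triple for the small cohort."""
    plan = make_plan(small_cohort.n_rows, seed=0, k=3)
    enc = fit_encoders(small_cohort, plan.full_train_rows)
    return (
        encode(small_cohort, enc, plan.train_rows),
        encode(small_cohort, enc, plan.val_rows),
        encode(small_cohort, enc, plan.test_rows),
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)
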