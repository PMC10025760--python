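import numpy as np
import pytest

from encodeaudit.models import (
    build_backbone,
    train_multitask,
    train_single_task,
)
from encodeaudit.synthetic import (
    CohortConfig,
    composition_shift_config,
    make_cohort,
)

SEED = 0


@pytest.fixture(scope="session")
def small_cohort():
    """Moderate cohort for metrics / inspection unit tests."""
    cfg = CohortConfig(n=2000)
    return make_cohort(cfg, seed=42)


@pytest.fixture(scope="session")
def cohort4k_bundle():
    """Default cohort (n=4000) with a trained single-task model."""
    cohort = make_cohort(CohortConfig(n=4000), seed=SEED)
    backbone = build_backbone("mlp", {"input_dim": cohort.features.shape[1]}, seed=SEED)
    bundle = train_single_task(backbone, cohort, epochs=30, seed=SEED)
    return cohort, bundle


@pytest.fixture(scope="session")
def composition_cohort_bundle():
    """Composition-shift cohort (n=10000) with a trained single-task model."""
    cohort = make_cohort(composition_shift_config(n=10_000), seed=SEED)
    backbone = build_backbone("mlp", {"input_dim": cohort.features.shape[1]}, seed=SEED)
    bundle = train_single_task(backbone, cohort, epochs=30, seed=SEED)
    return cohort, bundle


@pytest.fixture(scope="session")
def orthogonal_cohort_models():
    """Default (orthogonally encoded) cohort with single and multitask models."""
    cohort = make_cohort(CohortConfig(n=10_000), seed=SEED)
    spec = {"input_dim": cohort.features.shape[1]}
    single = train_single_task(build_backbone("mlp", spec, seed=SEED), cohort, epochs=30, seed=SEED)
    multi = train_multitask(build_backbone("mlp", spec, seed=SEED), cohort, epochs=30, seed=SEED)
    return cohort, single, multi


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
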