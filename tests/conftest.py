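import numpy as np
import pytest

import egfrdp as E


@pytest.fixture(scope="session")
def base_params() -> E.ParameterSet:
    return E.default_base_parameters()


@pytest.fixture(scope="session")
def final_params() -> E.ParameterSet:
    return E.default_final_parameters()


@pytest.fixture(scope="session")
def base_spec() -> E.ModelSpec:
    return E.base_model_spec()


@pytest.fixture(scope="session")
def final_spec() -> E.ModelSpec:
    return E.final_model_spec()


@pytest.fixture(scope="session")
def small_cohort(base_params, base_spec):
    """Five-subject cohort for oracle-scale comparisons."""
    cfg = E.CohortConfig(
        n_subjects=5, target_obs=60, seed=101,
        truth_params=base_params, truth_spec=base_spec,
    )
    return E.generate_cohort(cfg)


@pytest.fixture(scope="session")
def medium_cohort(base_params, base_spec):
    """Sixty-subject cohort: large enough to fit, small enough to be quick."""
    cfg = E.CohortConfig(
        n_subjects=60, target_obs=775, seed=202,
        truth_params=base_params, truth_spec=base_spec,
    )
    return E.generate_cohort(cfg)


@pytest.fixture(scope="session")
def study_cohort(base_params, base_spec):
    """Full study-design cohort (251 subjects, ~3241 observations)."""
    cfg = E.CohortConfig(seed=42, truth_params=base_params, truth_spec=base_spec)
    return E.generate_cohort(cfg)


@pytest.fixture(scope="session")
def study_base_fit(study_cohort, base_spec):
    return E.fit_model(study_cohort, base_spec)
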