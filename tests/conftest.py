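import numpy as np
import pytest

from confbayes.design import generate_schedule
from confbayes.simulate import (
    GroupSpec,
    SubjectParams,
    default_group_specs,
    simulate_experiment,
    simulate_subject,
)


@pytest.fixture(scope="session")
def default_dataset():
    """One full three-arm experiment at the calibrated defaults."""
    return simulate_experiment(seed=20260927)


@pytest.fixture(scope="session")
def small_dataset():
    """A small, fast experiment for pipeline plumbing tests."""
    specs = {
        name: GroupSpec(
            name=name, n_subjects=4, p_true=0.78, p_est=0.5524, beta=beta,
            beta_log_sd=0.0,
        )
        for name, beta in (("anodal", 2.0), ("sham", 1.0), ("cathodal", 0.5))
    }
    return simulate_experiment(group_specs=specs, n_trials=20, seed=7)


@pytest.fixture()
def subject_params():
    return SubjectParams(
        subject_id="s01", group="sham", p_true=0.78, p_est=0.5524, beta=1.0
    )


@pytest.fixture()
def schedule60():
    return generate_schedule(60, seed=11)
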