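import numpy as np
import pytest

from gfmed import calibration
from gfmed.cohort import build_analytic
from gfmed.config import ALL_MEDIATORS, GeneratorConfig
from gfmed.models import fit_bundle
from gfmed.synthetic import generate_cohort


@pytest.fixture(scope="session")
def calibrated_config():
    """Generator fully calibrated to the registry targets (shared, ~30 s)."""
    return calibration.calibrate_cohort_config()


@pytest.fixture(scope="session")
def small_config():
    """Fast, resolved config with non-trivial income gradients for unit tests."""
    grads = {m: 0.15 for m in ALL_MEDIATORS}
    grads["gpa"] = 0.10
    # the two rarest mediators are lifted above their registry prevalence so
    # that 20k-record fits stay away from quasi-separation
    prev = dict(GeneratorConfig().mediator_base_prevalences)
    prev["adolescent_self_harm"] = 0.012
    prev["violent_victimization"] = 0.012
    # a 3% outcome keeps 20k-record bootstrap refits well conditioned
    cfg = GeneratorConfig(n_children=20_000, seed=11, income_gradients=grads,
                          mediator_base_prevalences=prev, outcome_base_rate=0.03)
    return calibration.attach(cfg, calibration.resolve(cfg))


@pytest.fixture(scope="session")
def small_cohort(small_config):
    raw = generate_cohort(small_config)
    analytic, report = build_analytic(raw)
    return raw, analytic, report


@pytest.fixture(scope="session")
def small_bundle(small_cohort):
    return fit_bundle(small_cohort[1])


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
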