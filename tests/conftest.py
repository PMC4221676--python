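import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pacea.cdm import Demography, DiseaseSpec, PADistribution
from pacea.trial import TrialConfig, generate_trial

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_trial():
    """A modest five-arm trial used by several estimation tests."""
    return generate_trial(TrialConfig(n_per_arm=300, seed=42))


@pytest.fixture(scope="session")
def nodropout_trial():
    """Same structure but with dropout switched off (intercept -> -inf-ish)."""
    cfg = TrialConfig(n_per_arm=300, seed=7, dropout_intercept=-30.0,
                      dropout_coef_env=0.0, dropout_coef_web=0.0,
                      dropout_coef_age=0.0)
    return generate_trial(cfg)


def make_demography(n_ages=2, counts=1000.0, mortality=0.1, female_only=True):
    """Tiny demography helper: by default only the female column is occupied."""
    c = np.zeros((n_ages, 2))
    c[:, 1] = counts
    if not female_only:
        c[:, 0] = counts
    m = np.full((n_ages, 2), mortality)
    return Demography(50, c, m)


def make_pa(values=(10.0, 40.0), occupancy=(0.5, 0.5), drift=0.0):
    values = np.asarray(values, dtype=float)
    bounds = np.concatenate([[0.0], (values[:-1] + values[1:]) / 2, [np.inf]])
    return PADistribution(bounds, values, np.asarray(occupancy, dtype=float),
                          annual_drift=drift)


def make_disease(name="diabetes", incidence=0.05, beta=-0.01,
                 reference_met=40.0, excess=0.02, disutility=0.2,
                 cost=1000.0, female_only=False):
    return DiseaseSpec(name, incidence, beta, reference_met, excess,
                       disutility, cost, female_only=female_only)


@pytest.fixture
def tiny_model_parts():
    return make_demography, make_pa, make_disease
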