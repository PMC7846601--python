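import numpy as np
import pytest
from hypothesis import settings

from peatcarbon import synthetic as syn
from peatcarbon.dataio import SiteConfig
from peatcarbon.pipeline import run_synthetic_site

settings.register_profile("suite", derandomize=True, database=None,
                          max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def identity_curve():
    """Exact identity calibration curve: mu(theta) = theta, sigma_c = 0."""
    return syn.make_calcurve(cal_min=-2000.0, cal_max=4000.0, step=1.0,
                             curve_sigma=0.0)


@pytest.fixture(scope="session")
def cas0_zero():
    """Noise-free shallow-site run: observations are exactly invertible."""
    cfg = SiteConfig(mc_iterations=300)
    scenario = syn.cas0_scenario(noise_scale=0.0)
    scenario.pb_depth_max_cm = None   # measure 210Pb over the whole core
    return run_synthetic_site(scenario, syn.cas0_cohort(noise_scale=0.0),
                              cfg, seed=11,
                              curve=syn.make_calcurve(curve_sigma=0.0))


@pytest.fixture(scope="session")
def cas0_default():
    """Shallow-site run at the generator's default noise levels."""
    cfg = SiteConfig(mc_iterations=500)
    return run_synthetic_site(syn.cas0_scenario(), syn.cas0_cohort(),
                              cfg, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
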