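import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

# mixed-model boundary fits and ROI-placement warnings are expected noise
warnings.filterwarnings("ignore", message=".*stratum.*")
warnings.filterwarnings("ignore", message=".*region.*ROIs.*")


@pytest.fixture
def noiseless_curve_params():
    from hippomech.synthgen import CurveGenParams

    def make(elastic_modulus=300.0, **kwargs):
        defaults = dict(contact_point=20.0, noise_sd=0.0, baseline_slope=0.0)
        defaults.update(kwargs)
        return CurveGenParams(elastic_modulus=elastic_modulus, **defaults)

    return make


@pytest.fixture
def small_cohort_table():
    """Moderate synthetic cohort table for statistics tests (seeded)."""
    from hippomech.synthgen import CohortDesign, simulate_cohort

    design = CohortDesign(points_per_region=60, seed=42)
    return simulate_cohort(design).points


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
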