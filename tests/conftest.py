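import numpy as np
import pytest

from cardicca import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort():
    """A small, clearly discriminative two-view cohort for pipeline tests."""
    cfg = CohortConfig(n_subjects=40, prevalence=0.5, d_shared=3,
                       q_discriminative=2, effect_size=3.0,
                       d_view1=8, d_view2=8,
                       noise_sd_view1=0.8, noise_sd_view2=0.8,
                       native_frames_view1=(12, 20), native_frames_view2=(18, 30),
                       seed=42)
    return cfg, generate_cohort(cfg)
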