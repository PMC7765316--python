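import numpy as np
import pytest

from imuheat import CohortConfig, RasterConfig, default_activity_specs, make_cohort
from imuheat.heatmap import samples_from_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def tiny_cohort():
    """2 subjects x 3 classes, 20 s at 30 Hz: enough for one 600-frame image
    segment per recording while staying fast."""
    specs = default_activity_specs()
    cfg = CohortConfig(
        n_subjects=2,
        classes=(specs[1], specs[3], specs[10]),  # circles, raises, squats
        sampling_rate=30.0,
        duration_per_class=20.0,
        noise_sd=0.003,
        seed=11,
    )
    return make_cohort(cfg)


@pytest.fixture(scope="session")
def tiny_image_samples(tiny_cohort):
    cfg = RasterConfig(height=8, width=8)
    return samples_from_cohort(tiny_cohort, cfg, n_sub=2, sub_window=60)
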