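import numpy as np
import pytest

from anemiadss.cohort import Medication
from anemiadss.features import apply_normalizer, build_features, fit_normalizer
from anemiadss.simulate import GeneratorConfig, generate, generate_with_stats


@pytest.fixture(scope="session")
def small_clean_cohort():
    """20 patients, no recording corruption: recorded == latent labels."""
    return generate(GeneratorConfig(n_patients=20, n_occasions=40, seed=11))


@pytest.fixture(scope="session")
def small_noisy_cohort():
    """Benchmark-style corruption at desk scale."""
    return generate(GeneratorConfig(n_patients=20, n_occasions=40, seed=12,
                                    p_delay=0.15, p_label_noise=0.05))


@pytest.fixture(scope="session")
def esa_training_data(small_clean_cohort):
    ds = build_features(small_clean_cohort, Medication.ESA)
    norm = fit_normalizer(ds)
    return apply_normalizer(norm, ds)
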