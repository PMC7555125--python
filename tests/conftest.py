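import numpy as np
import pytest

from enose import SynthConfig, generate_cohort, generate_record


@pytest.fixture(scope="session")
def default_cohort():
    """Full 59-subject cohort at the default study conditions."""
    return generate_cohort(SynthConfig(seed=123))


@pytest.fixture(scope="session")
def small_cohort():
    """Five-subject cohort for cheap structural tests."""
    return generate_cohort(SynthConfig(n_cancer=3, n_control=2, seed=7))


@pytest.fixture(scope="session")
def clean_record():
    """Noise-, drift- and subject-variability-free control record."""
    cfg = SynthConfig(noise_sd=0.0, subject_sd=0.0, drift_per_cycle=0.0, seed=1)
    return generate_record(cfg, 0, 50, "F", "no", np.random.default_rng(0), "clean")


@pytest.fixture()
def noisy_record():
    cfg = SynthConfig(seed=2)
    return generate_record(cfg, 1, 63, "M", "yes", np.random.default_rng(3), "noisy")
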