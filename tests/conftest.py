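import numpy as np
import pytest

import fibrospec as fs


@pytest.fixture(scope="session")
def uniform_axis() -> fs.WavenumberAxis:
    """Full-range axis, 950-3500 cm^-1 at 4 cm^-1 step."""
    return fs.WavenumberAxis(np.arange(950.0, 3500.0 + 1e-9, 4.0))


@pytest.fixture(scope="session")
def quiet_config() -> fs.SyntheticCohortConfig:
    """Small noise-free cohort: every nuisance term switched off."""
    return fs.SyntheticCohortConfig(
        n_per_group=2,
        n_rows=8,
        n_cols=8,
        noise_sd=0.0,
        between_sample_sd=0.0,
        band_jitter_sd=0.0,
        baseline_jitter_sd=0.0,
        mie_amplitude=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_noisy_config() -> fs.SyntheticCohortConfig:
    """Small cohort with all default nuisance terms, desk-scale geometry."""
    return fs.SyntheticCohortConfig(n_per_group=3, n_rows=8, n_cols=8, seed=23)


@pytest.fixture(scope="session")
def default_cohort_spectra():
    """Default-condition cohort at the spectrum level (10/group, noisy)."""
    cfg = fs.SyntheticCohortConfig(seed=101)
    return fs.generate_cohort_spectra(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
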