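import warnings

import numpy as np
import pytest

from hccdetect.synthetic_cohort import (
    CohortConfig,
    ShotSpectrum,
    SpectrumParams,
    generate_cohort,
    render_shot_spectrum,
)

warnings.filterwarnings("ignore", message="only .* features definable")
warnings.filterwarnings("ignore", message="dropout_leave_in")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def tiny_cohort_config(**overrides):
    """A very small spectral geometry for fast end-to-end tests."""
    base = dict(
        n_hcc=12,
        n_no_hcc=12,
        n_healthy=6,
        n_positions=3,
        n_spots=1,
        mz_range=(3000.0, 8000.0),
        mz_step=2.0,
        n_peaks=20,
        n_informative=4,
        n_acute_phase=4,
        class_effect=0.5,
        seed=0,
    )
    base.update(overrides)
    return CohortConfig(**base)


@pytest.fixture(scope="session")
def tiny_cohort():
    return generate_cohort(tiny_cohort_config())


def gaussian_spectrum(
    centers, areas, sigmas, *, mz=(3000.0, 8000.0, 1.0), noise=0.0,
    baseline=0.0, seed=0, sample_id="fix",
) -> ShotSpectrum:
    lo, hi, step = mz
    grid = np.arange(lo, hi + step / 2, step)
    params = SpectrumParams(
        mz_grid=grid, baseline_amp=baseline, noise_floor=noise
    )
    return render_shot_spectrum(
        (np.asarray(centers, float), np.asarray(areas, float), np.asarray(sigmas, float)),
        params,
        np.random.default_rng(seed),
        sample_id=sample_id,
    )
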