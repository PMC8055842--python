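import numpy as np
import pytest

from pbem import (
    AcquisitionParams,
    GroundTruth,
    fit_spectrum,
    simulate_cohort,
    simulate_spectrum,
)
from pbem.synth import CohortDesign, _effective_panel
from pbem.calibration import DEFAULT_CALIBRATION


@pytest.fixture(scope="session")
def default_truth():
    return GroundTruth()


@pytest.fixture(scope="session")
def effective_panel(default_truth):
    """Panel with pH/Mg-driven centers, keyed by resonance name."""
    return {r.name: r for r in _effective_panel(default_truth, DEFAULT_CALIBRATION)}


@pytest.fixture(scope="session")
def clean_spectrum(default_truth):
    """Noiseless 13-resonance spectrum, default acquisition (2048 -> 4096)."""
    return simulate_spectrum(default_truth)


@pytest.fixture(scope="session")
def clean_fit(clean_spectrum):
    """Fit of the noiseless default spectrum (reused across tests)."""
    fit = fit_spectrum(clean_spectrum)
    assert fit.converged
    return fit


@pytest.fixture(scope="session")
def default_cohort():
    """Default 15/15/11 cohort table, no spectra (markers + cognition)."""
    table, _ = simulate_cohort(CohortDesign(seed=7), with_spectra=False)
    return table


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
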