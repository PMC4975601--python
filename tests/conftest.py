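import pytest

from biocogs import calibration, fixtures
from biocogs.uncertainty import run_monte_carlo


@pytest.fixture(scope="session")
def calibrated():
    """Calibration result for the base fixture set."""
    return calibration.calibrate()


@pytest.fixture(scope="session")
def model(calibrated):
    """Cost model assembled from the calibrated constants."""
    return fixtures.build_model(calibrated.constants)


@pytest.fixture(scope="session")
def base():
    return fixtures.base_parameters()


@pytest.fixture(scope="session")
def mc_before(model, base):
    """300-run Monte Carlo at the unoptimized titer (seed 1)."""
    return run_monte_carlo(fixtures.mc_config_before(seed=1), model, base)


@pytest.fixture(scope="session")
def mc_after(model, base):
    """300-run Monte Carlo at the optimized titer (seed 2)."""
    return run_monte_carlo(fixtures.mc_config_after(seed=2), model, base)
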