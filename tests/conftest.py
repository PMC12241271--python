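import numpy as np
import pytest

from cesakit import synthetic_data as sd

# Designed occupancies spanning the full recovery grid: contact at
# {0, 25, 50, 80, 100}%, hydrogen bonds at {25, 40}%, CH-π at 60%.
DESIGN_PAIRS = (
    sd.PairSpec("SER", contact_pct=80, hbond_pct=40, chpi_pct=0),
    sd.PairSpec("PHE", contact_pct=100, hbond_pct=0, chpi_pct=60),
    sd.PairSpec("GLU", contact_pct=50, hbond_pct=25, chpi_pct=0),
    sd.PairSpec("LEU", contact_pct=25, hbond_pct=0, chpi_pct=0),
    sd.PairSpec("ARG", contact_pct=0, hbond_pct=0, chpi_pct=0),
    sd.PairSpec("TRP", contact_pct=60, hbond_pct=0, chpi_pct=60),
)


@pytest.fixture(scope="session")
def designed_traj():
    """200-frame toy trajectory with exactly designed occupancies."""
    spec = sd.TrajectorySpec(pairs=DESIGN_PAIRS, n_frames=200, seed=1)
    return spec, sd.synth_trajectory(spec)


@pytest.fixture(scope="session")
def scatter_clean():
    """Noiseless synthetic GIWAXS + rocking images, χ-FWHM 30°."""
    spec = sd.ScatterSpec(seed=3)
    giwaxs, rocking = sd.synth_detector_image(spec)
    return spec, giwaxs, rocking


@pytest.fixture(scope="session")
def scatter_noisy():
    """Poisson-noisy images with an arbitrary GIWAXS intensity scale."""
    spec = sd.ScatterSpec(seed=7, poisson_noise=True, giwaxs_scale=5.0)
    giwaxs, rocking = sd.synth_detector_image(spec)
    return spec, giwaxs, rocking


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
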