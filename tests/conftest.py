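from pathlib import Path

import numpy as np
import pytest

import foveate as fv

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def linear_spec():
    """Radially linear retina: 500 -> 4000 cells/mm^2, fovea at center."""
    return fv.RetinaSpec(
        radius=6.0,
        fovea_xy=(0.0, 0.0),
        base_density=500.0,
        peak_density=4000.0,
    )


@pytest.fixture(scope="session")
def linear_field(linear_spec):
    return fv.generate_density_field(linear_spec, grid_step=0.05)


@pytest.fixture(scope="session")
def toy_study_dir():
    return DATA_DIR / "synthetic_toy_study"


def exact_moment_sample(mean: float, se: float, n: int) -> np.ndarray:
    """A sample of size n with exactly the given mean and standard error.

    Standardizes a fixed spread to zero mean and unit sample SD (ddof=1),
    then rescales; lets summary-level published statistics drive tests of
    sample-level code paths.
    """
    z = np.linspace(-1.0, 1.0, n)
    z = (z - z.mean()) / z.std(ddof=1)
    return mean + se * np.sqrt(n) * z
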