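import numpy as np
import pytest

from slablight import MCConfig, OpticalProperties, load_reference_table

# (mu_a, mu_s) at 800 nm for the three dose groups, from the packaged table
ROWS_800 = {
    "P-0": (6.09, 128.02),
    "P-30": (6.65, 102.78),
    "P-100": (6.47, 109.11),
}

THICKNESS = 0.05  # cm, the molded sheet thickness
G = 0.9


@pytest.fixture(scope="session")
def reference():
    """Packaged reference coefficient table (tidy DataFrame, 54 rows)."""
    return load_reference_table()


@pytest.fixture()
def props_800_p0():
    return OpticalProperties(*ROWS_800["P-0"], g=G)


@pytest.fixture()
def small_mc_config():
    """Cheap but statistically usable simulation size for unit tests."""
    return MCConfig(n_photons=50_000, seed=20_240, nz=50)


def standard_error(p: float, n: int) -> float:
    """Binomial standard error of a scored fraction."""
    return np.sqrt(max(p * (1 - p), 1e-12) / n)
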