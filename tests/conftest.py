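import numpy as np
import pytest

import fumamap as fm
from fumamap.synth import cell_phantom_config, generate_cell_phantom


@pytest.fixture(scope="session")
def axis():
    return fm.default_axis()


@pytest.fixture(scope="session")
def noiseless_model():
    """Calibration fitted on a noiseless synthetic dilution series."""
    series = fm.generate_calibration_series(
        [0, 10, 20, 30], replicates=2, dwell=1.0, noise_sd=0.0, seed=0,
        keep_spectra=False)
    return fm.fit_calibration(series)


@pytest.fixture(scope="session")
def ko19_phantom():
    cfg = cell_phantom_config("KO19", seed=1)
    return generate_cell_phantom(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
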