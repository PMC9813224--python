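import numpy as np
import pytest

import ramanhisto as rh
from ramanhisto.peaks import default_peak_table
from ramanhisto.profiles import default_profiles
from ramanhisto.synthetic import CohortConfig, generate_cohort, generate_map


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def peaks():
    return default_peak_table()


@pytest.fixture(scope="session")
def small_cohort():
    """12 patients x 2 samples x 10 spectra = 240 spectra, fast to generate."""
    cfg = CohortConfig(n_patients=12, n_hcc=9, n_icc=3, spectra_per_sample=10, seed=42)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def margin_phantom(profiles):
    """Noiseless 25x25 two-component map with a diagonal carcinoma margin."""
    yy, xx = np.mgrid[0:25, 0:25]
    layout = ((xx + yy) >= 25).astype(int)
    return generate_map(
        [profiles["paracancer"], profiles["HCC"]],
        layout,
        rh.FINGERPRINT_AXIS,
        pixel_size=2.0,
        noise_sd=0.0,
    )
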