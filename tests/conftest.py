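import numpy as np
import pandas as pd
import pytest

import plaquedce as p


@pytest.fixture(scope="session")
def ge_protocol():
    return p.GE_PROTOCOL


@pytest.fixture(scope="session")
def philips_protocol():
    return p.PHILIPS_PROTOCOL


@pytest.fixture(scope="session")
def aif(ge_protocol):
    return p.generate_aif(ge_protocol)


@pytest.fixture(scope="session")
def phantom(ge_protocol):
    return p.build_phantom(ge_protocol, lumen_radius=3.0, wall_thickness=1.5,
                           plaque_bulge=2.0, ktrans_wall=0.062, vp_wall=0.067,
                           seed=0)


@pytest.fixture(scope="session")
def clean_series(phantom, aif, ge_protocol):
    """Noise-free, motion-free dynamic series of the default phantom."""
    return p.simulate_series(phantom, aif, ge_protocol, noise_sd=0.0,
                             motion_amplitude=0.0, seed=0)


@pytest.fixture()
def cohort_table():
    """One draw of the default 35-subject scan-rescan cohort."""
    return p.generate_measurement_cohort(p.CohortSpec.from_cv_icc(seed=42))


@pytest.fixture()
def tiny_table():
    """Three-subject hand-checkable cohort."""
    return pd.DataFrame({
        "subject_id": ["a", "b", "c"],
        "vendor": ["GE", "GE", "Philips"],
        "y1": [1.0, 2.0, 4.0],
        "y2": [3.0, 2.0, 6.0],
        "area1": [30.0, 20.0, 40.0],
        "area2": [28.0, 22.0, 44.0],
    })
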