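import numpy as np
import pytest

import tomopipe as tp


@pytest.fixture(scope="session")
def disc_phantom():
    return tp.Phantom([tp.Ellipse((0.0, 0.0), (0.3, 0.3), 0.0, 1.0)], field_of_view=1.0)


@pytest.fixture(scope="session")
def shepp():
    return tp.shepp_like_phantom()


@pytest.fixture(scope="session")
def offcentre():
    return tp.off_centre_phantom()


@pytest.fixture(scope="session")
def noiseless_scan(shepp):
    """Small artefact-free noiseless scan: (block, flats, darks, truth)."""
    scan = tp.ScanConfig(
        n_angles=32, n_det=64, n_rows=4, noise_on=False, include_final_180=False
    )
    return tp.simulate_scan(shepp, scan)


@pytest.fixture()
def registry():
    return tp.default_registry()
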