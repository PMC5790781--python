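import numpy as np
import pytest

import diamotion as dm


@pytest.fixture(scope="session")
def control_spec():
    return dm.preset_spec("control")


@pytest.fixture(scope="session")
def control_phantom(control_spec):
    """Noiseless control-preset series with its analytic truth."""
    return dm.generate_phantom(control_spec)


@pytest.fixture(scope="session")
def control_landmarks(control_spec):
    return dm.phantom_landmarks(control_spec)


@pytest.fixture(scope="session")
def control_results(control_phantom, control_landmarks):
    """End-to-end fit of the noiseless control phantom."""
    series, _ = control_phantom
    return dm.DiaphragmMotion(series, control_landmarks).fit()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)
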