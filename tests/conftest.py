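import warnings

import pytest

from neuroloop import synthetic_data as sd

# short calibration trials legitimately trigger the <60 s advisory
warnings.filterwarnings("ignore",
                        message="calibration trial shorter than 60 s.*")


@pytest.fixture(scope="session")
def intact_session():
    """One default intact-condition session shared across read-only tests."""
    return sd.generate_session(sd.SessionParams(seed=1), with_kinematics=False)


@pytest.fixture(scope="session")
def intact_behavior(intact_session):
    return intact_session.behavior
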