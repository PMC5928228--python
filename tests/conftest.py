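import pytest

import finchloop as fl


@pytest.fixture(scope="session")
def motif() -> fl.MotifSpec:
    return fl.default_motif()


@pytest.fixture(scope="session")
def detector_cfg() -> fl.DetectorConfig:
    return fl.DetectorConfig()


@pytest.fixture(scope="session")
def pitch_cfg() -> fl.PitchConfig:
    return fl.PitchConfig()


@pytest.fixture(scope="session")
def short_schedule() -> fl.DaySchedule:
    """Two-hour lights-on days to keep perch simulations fast."""
    return fl.DaySchedule(lights_on_s=25_200.0, lights_off_s=25_200.0 + 7_200.0, n_days=4)
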