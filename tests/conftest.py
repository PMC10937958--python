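import math

import numpy as np
import pandas as pd
import pytest

from lfpstate.io import Recording, ChannelMap
from lfpstate.synth import (SyntheticSessionConfig, ConditionSpec,
                            OscillationSpec, generate_session)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_recording():
    """4 channels, 10 s, white noise plus a shared epoch table."""
    gen = np.random.default_rng(0)
    samples = gen.standard_normal((4, 20_000))
    epochs = pd.DataFrame({"label": ["baseline", "drug"],
                           "start_s": [0.0, 5.0], "end_s": [5.0, 10.0]})
    return Recording(samples=samples, fs=2000.0,
                     channel_ids=["mPFC-L00", "mPFC-L01", "vStr-L00", "vStr-L01"],
                     epochs=epochs, session="s01", animal="a01")


@pytest.fixture
def small_channel_map():
    return ChannelMap(pd.DataFrame({
        "channel_id": ["mPFC-L00", "mPFC-L01", "vStr-L00", "vStr-L01"],
        "structure": ["mPFC", "mPFC", "vStr", "vStr"],
        "hemisphere": ["lesioned"] * 4,
        "animal": "a01", "session": "s01"}))


@pytest.fixture(scope="session")
def hfo_session():
    """Two-structure session with a continuous 6 dB HFO at lag pi/8."""
    cfg = SyntheticSessionConfig(
        duration_s=120.0,
        structures=[("mPFC", "lesioned"), ("vStr", "lesioned")],
        conditions=[ConditionSpec("vehicle", [OscillationSpec(
            band_center=145.0, bandwidth=10.0, amplitude_db=6.0,
            episode_schedule=[(0.0, 120.0)],
            phase_lag_map={"mPFC": math.pi / 8, "vStr": 0.0})])],
        condition_epochs=[("vehicle", 0.0, 120.0)],
        seed=42)
    return generate_session(cfg)
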