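import numpy as np
import pytest

from rhythmtag import stimuli as st
from rhythmtag import synthetic as syn


@pytest.fixture(scope="session")
def roi_channels():
    return ("T7", "T8", "TP7", "TP8", "O1", "Oz", "O2")


@pytest.fixture(scope="session")
def short_recording(roi_channels):
    """3-minute synthetic condition block (high metricality / high regularity)."""
    return syn.gen_condition_recording(
        "high", "high", seed=11, n_measures=60,
        eeg_params=syn.EEGParams(channels=roi_channels),
    )


@pytest.fixture(scope="session")
def small_stimulus():
    """36 s rendered high/high stimulus at a light audio rate."""
    seq = st.build_sequence("high", "high", measure_id=2, seed=3, n_measures=12)
    return st.render_audio(seq, None, rate_hz=8000.0)
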