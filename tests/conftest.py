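import numpy as np
import pytest

from emgpr import (
    easy_preset,
    filter_recording,
    generate_session,
    segment_windows,
    trim_contractions,
)
from emgpr.dimred import assemble


@pytest.fixture(scope="session")
def x4():
    """The shared hand-computable fixture window."""
    return np.array([1.0, -2.0, 3.0, -4.0])


@pytest.fixture(scope="session")
def easy_windows():
    """Preprocessed windows of one well-separated synthetic session."""
    rec = generate_session(easy_preset(seed=1))
    rec = filter_recording(rec)
    rec = trim_contractions(rec)
    return segment_windows(rec)


@pytest.fixture(scope="session")
def fs_features(easy_windows):
    """The proposed feature set extracted from the easy session."""
    return assemble("FS", easy_windows)


@pytest.fixture(scope="session")
def two_windows(easy_windows):
    """A tiny two-window subset for cheap full-set assemblies."""
    from emgpr import WindowSet

    ws = easy_windows
    return WindowSet(ws.windows[:2], ws.labels[:2], ws.N, ws.step, ws.fs, ws.entry_index[:2])
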