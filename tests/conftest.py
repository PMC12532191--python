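import numpy as np
import pandas as pd
import pytest


def make_table(frames, x, y, precision=0.0, fiducial=False):
    """Minimal localization table from parallel arrays."""
    frames = np.asarray(frames)
    n = len(frames)
    return pd.DataFrame({
        "frame": frames.astype(int),
        "x_nm": np.asarray(x, dtype=float),
        "y_nm": np.asarray(y, dtype=float),
        "precision_nm": np.broadcast_to(np.asarray(precision, dtype=float), n).copy(),
        "is_fiducial": np.broadcast_to(np.asarray(fiducial, dtype=bool), n).copy(),
    }).sort_values("frame", kind="stable").reset_index(drop=True)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
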