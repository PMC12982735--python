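import numpy as np
import pytest

from paintdenoise import LocalizationTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_table(x, y, frame=None, precision=10.0, frame_duration_s=0.2, n_frames=None):
    x = np.asarray(x, dtype=float)
    frame = np.zeros(x.size, np.int64) if frame is None else np.asarray(frame)
    prec = np.full(x.size, precision) if np.isscalar(precision) else np.asarray(precision)
    if n_frames is None:
        n_frames = int(frame.max()) + 1 if x.size else 1
    return LocalizationTable(
        x_nm=x, y_nm=np.asarray(y, dtype=float), frame=frame, precision_nm=prec,
        frame_duration_s=frame_duration_s, n_frames=n_frames,
    ).validate()


@pytest.fixture
def blob_table(rng):
    """Two well-separated blobs of 100 points each."""
    a = rng.normal(0, 10, size=(100, 2))
    b = rng.normal(0, 10, size=(100, 2)) + [500.0, 0.0]
    pts = np.vstack([a, b])
    return make_table(pts[:, 0], pts[:, 1])
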