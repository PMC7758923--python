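"""Shared fixtures: small simulated recordings reused across test modules."""

import numpy as np
import pytest

from pgesdet.io import resample, to_bipolar_montage
from pgesdet.simulate import SimConfig, simulate_recording


@pytest.fixture(scope="session")
def easy_recording():
    """One artifact-free 60 s recording at 200 Hz with a known transition."""
    cfg = SimConfig(
        seed=11, duration_s=60.0, sampling_rate_hz=200.0, transition_s=25.0
    ).artifact_free()
    rec, truth = simulate_recording(cfg, "easy000")
    return rec, truth


@pytest.fixture(scope="session")
def easy_montaged(easy_recording):
    """The same recording after the standard montage + 200 Hz chain."""
    rec, _ = easy_recording
    return resample(to_bipolar_montage(rec), 200.0)


def make_flat_montaged(
    n_montages=10, duration_s=40.0, rate_hz=200.0, pges_end_s=20.0, seed=0,
    recording_id="flat000",
):
    """A montaged recording of seeded white noise (no structure), for tests
    that only exercise windowing/shape logic."""
    from pgesdet.io import MontagedRecording

    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate_hz))
    return MontagedRecording(
        recording_id=recording_id,
        montage_labels=[f"ch{i}" for i in range(n_montages)],
        data=rng.standard_normal((n_montages, n)),
        sampling_rate_hz=rate_hz,
        pges_end_s=pges_end_s,
    )


class RmsProbe:
    """A deterministic stand-in detector: probability from the window's RMS.

    Depends only on the crop content, so it is suitable for causality and
    trace-shape tests without any training.
    """

    def __init__(self, scale_uv: float = 10.0):
        self.scale_uv = scale_uv

    def predict_proba_crops(self, X):
        rms = np.sqrt(np.mean(np.asarray(X, dtype=np.float64) ** 2, axis=(1, 2)))
        return 1.0 / (1.0 + np.exp(-(rms - self.scale_uv)))
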