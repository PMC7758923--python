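"""Synthetic post-GTCS EEG with a known end of suppression.

Real postictal recordings carry protected health information, so every stage
of the pipeline is exercised on simulated 13-electrode recordings instead.
Each recording has two regimes around a known transition time:

* **suppression** — low-amplitude (default 3 uV RMS) broadband noise on all
  channels, the near-flat EEG that follows a generalized tonic-clonic seizure;
* **intermittent slow waves** — from the transition onward, bursts of
  band-limited delta activity (default 0.5-4 Hz, 30 uV RMS during bursts)
  arrive via a two-state renewal process with exponential dwell times, so the
  slow activity is intermittent rather than continuous.

Physiological nuisance signals (eye-movement transients on frontal channels,
a global breathing oscillation, broadband muscle bursts on temporal channels)
can be superposed at configurable amplitudes. The burst envelope is smoothed
causally, so no slow-wave energy ever precedes the annotated transition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io import ELECTRODES_13, Recording, write_simple

_FRONTAL = ("Fp1", "Fp2", "F7", "F8")
_TEMPORAL = ("F7", "F8", "T7", "T8")
_RATE_CHOICES = (150.0, 200.0, 256.0)


@dataclass(frozen=True)
class SimConfig:
    """Generation parameters for one synthetic postictal recording.

    ``sampling_rate_hz=None`` draws the rate from {150, 200, 256} Hz, the
    range seen across clinical acquisition systems; ``transition_s=None``
    draws the suppression end uniformly from (20 s, duration - 30 s).
    Artifact amplitudes are RMS scales in microvolts; set them to zero for an
    artifact-free recording.
    """

    seed: int = 0
    duration_s: float = 300.0
    sampling_rate_hz: float | None = None
    suppression_rms_uv: float = 3.0
    slow_rms_uv: float = 30.0
    slow_band_hz: tuple[float, float] = (0.5, 4.0)
    transition_s: float | None = None
    intermittency_duty: float = 0.6
    burst_mean_s: float = 3.0
    eye_artifact_uv: float = 20.0
    breathing_artifact_uv: float = 2.0
    muscle_artifact_uv: float = 5.0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.slow_rms_uv <= self.suppression_rms_uv:
            raise ValueError("slow_rms_uv must exceed suppression_rms_uv")
        if not (0.0 < self.intermittency_duty <= 1.0):
            raise ValueError("intermittency_duty must lie in (0, 1]")
        if self.transition_s is not None and not (0.0 < self.transition_s < self.duration_s):
            raise ValueError("transition_s must lie strictly inside the recording")

    def artifact_free(self) -> "SimConfig":
        return replace(self, eye_artifact_uv=0.0, breathing_artifact_uv=0.0,
                       muscle_artifact_uv=0.0)


@dataclass(frozen=True)
class GroundTruth:
    """True suppression-end time for a simulated recording."""

    recording_id: str
    pges_end_s: float
    config: SimConfig


def _pink_noise(rng, n, fs, f_flat=0.5):
    """1/f-spectrum noise, unit RMS; flat below `f_flat` to bound slow drift.

    The suppression-floor EEG keeps the brain's characteristic 1/f power
    distribution even at low amplitude, so band-limited slow-wave bursts are
    detectable by their amplitude contrast rather than by occupying an
    otherwise empty band.
    """
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n, 1.0 / fs)
    scale = 1.0 / np.sqrt(np.maximum(f, f_flat))
    scale[0] = 0.0  # remove DC
    x = np.fft.irfft(spec * scale, n)
    return x / np.sqrt(np.mean(x**2))


def _bandpassed_noise(rng, n, fs, band, order=4):
    lo, hi = band
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    return x / max(np.sqrt(np.mean(x**2)), 1e-30)


def _burst_envelope(rng, n, fs, start_idx, duty, burst_mean_s):
    """0/1 burst process from start_idx on, causally smoothed (0.3 s attack)."""
    env = np.zeros(n)
    if duty >= 1.0:
        env[start_idx:] = 1.0
    else:
        quiet_mean_s = burst_mean_s * (1.0 - duty) / duty
        t = start_idx
        in_burst = True  # the transition is defined by the first burst's onset
        while t < n:
            dwell = rng.exponential(burst_mean_s if in_burst else quiet_mean_s)
            dwell_n = max(int(round(dwell * fs)), 1)
            if in_burst:
                env[t: t + dwell_n] = 1.0
            t += dwell_n
            in_burst = not in_burst
    k = max(int(round(0.3 * fs)), 2)
    kernel = sps.windows.hann(2 * k + 1)[: k + 1]  # rising half: causal attack
    kernel = kernel / kernel.sum()
    smoothed = np.convolve(env, kernel)[:n]
    smoothed[:start_idx] = 0.0
    return smoothed


def simulate_recording(cfg: SimConfig, recording_id: str = "sim000") -> tuple[Recording, GroundTruth]:
    """Generate one annotated 13-electrode recording from `cfg`.

    Fully reproducible: the same config (including its seed) gives bitwise
    identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.sampling_rate_hz if cfg.sampling_rate_hz is not None else float(rng.choice(_RATE_CHOICES))
    n = int(round(cfg.duration_s * fs))
    if cfg.transition_s is not None:
        transition = float(cfg.transition_s)
    else:
        lo, hi = 20.0, cfg.duration_s - 30.0
        if hi <= lo:
            raise ValueError("duration too short to draw a transition from (20, duration-30)")
        transition = float(rng.uniform(lo, hi))
    start_idx = int(round(transition * fs))
    n_ch = len(ELECTRODES_13)
    data = np.empty((n_ch, n))

    # suppression-floor background: 1/f noise at exact RMS per row
    for c in range(n_ch):
        data[c] = _pink_noise(rng, n, fs) * cfg.suppression_rms_uv

    # intermittent slow waves: shared delta source plus per-channel variation
    env = _burst_envelope(rng, n, fs, start_idx, cfg.intermittency_duty, cfg.burst_mean_s)
    common = _bandpassed_noise(rng, n, fs, cfg.slow_band_hz)
    for c in range(n_ch):
        own = _bandpassed_noise(rng, n, fs, cfg.slow_band_hz)
        slow = (0.6 * common + 0.8 * own)
        slow = slow / np.sqrt(np.mean(slow**2))
        data[c] += cfg.slow_rms_uv * env * slow

    _add_artifacts(rng, data, fs, cfg)

    rec = Recording(
        recording_id=recording_id,
        channel_labels=list(ELECTRODES_13),
        data=data,
        sampling_rate_hz=fs,
        pges_end_s=transition,
    )
    return rec, GroundTruth(recording_id, transition, cfg)


def _add_artifacts(rng, data, fs, cfg):
    n = data.shape[1]
    t = np.arange(n) / fs
    if cfg.eye_artifact_uv > 0:
        # blink-like sub-1 Hz transients on frontal electrodes
        pulse = sps.windows.hann(max(int(0.5 * fs), 3))
        n_events = rng.poisson(0.25 * n / fs)
        onsets = rng.integers(0, max(n - len(pulse), 1), size=n_events)
        track = np.zeros(n)
        for o in onsets:
            track[o: o + len(pulse)] += pulse[: n - o] * rng.uniform(0.5, 1.5)
        for name in _FRONTAL:
            ci = ELECTRODES_13.index(name)
            data[ci] += cfg.eye_artifact_uv * track * rng.uniform(0.7, 1.0)
    if cfg.breathing_artifact_uv > 0:
        phase = rng.uniform(0, 2 * np.pi)
        wave = np.sin(2 * np.pi * 0.3 * t + phase)
        for ci in range(data.shape[0]):
            data[ci] += cfg.breathing_artifact_uv * rng.uniform(0.5, 1.0) * wave
    if cfg.muscle_artifact_uv > 0:
        sos_hp = sps.butter(4, 20.0, btype="highpass", fs=fs, output="sos")
        for name in _TEMPORAL:
            ci = ELECTRODES_13.index(name)
            burst = np.zeros(n)
            n_events = rng.poisson(0.1 * n / fs)
            for o in rng.integers(0, n, size=n_events):
                w = int(rng.uniform(0.5, 2.0) * fs)
                burst[o: o + w] = 1.0
            emg = sps.sosfiltfilt(sos_hp, rng.standard_normal(n))
            emg = emg / max(np.sqrt(np.mean(emg**2)), 1e-30)
            data[ci] += cfg.muscle_artifact_uv * burst * emg


def simulate_cohort(
    n: int,
    base_cfg: SimConfig,
    seed: int,
    out_dir: str | Path | None = None,
    fmt: str = "edf",
) -> tuple[list[tuple[Recording, GroundTruth]], pd.DataFrame]:
    """Generate a cohort of `n` recordings with per-recording seeds.

    Per-recording seeds, sampling rates and transition times are derived
    deterministically from `seed` (overriding nothing the base config fixes).
    Returns the recordings with their ground truth and a manifest table
    (recording_id, seed, pges_end_s, sampling_rate_hz); when `out_dir` is
    given the recordings are written there as EDF (``fmt="edf"``) or the
    plain-text simple format (``fmt="simple"``), plus ``manifest.csv``.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    if fmt not in ("edf", "simple"):
        raise ValueError(f"unknown format {fmt!r}")
    rng = np.random.default_rng(seed)
    cohort = []
    rows = []
    for i in range(n):
        rec_seed = int(rng.integers(0, 2**31 - 1))
        cfg_i = replace(base_cfg, seed=rec_seed)
        rec, truth = simulate_recording(cfg_i, recording_id=f"rec{i:03d}")
        cohort.append((rec, truth))
        rows.append(
            {
                "recording_id": rec.recording_id,
                "seed": rec_seed,
                "pges_end_s": truth.pges_end_s,
                "sampling_rate_hz": rec.sampling_rate_hz,
            }
        )
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        if fmt == "edf":
            from .edf import write_edf

            for rec, _ in cohort:
                write_edf(rec, out_dir / f"{rec.recording_id}.edf")
        else:
            for rec, _ in cohort:
                write_simple(rec, out_dir / rec.recording_id)
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return cohort, manifest
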