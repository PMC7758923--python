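"""Reading, writing and preprocessing of scalp EEG recordings.

A :class:`Recording` holds referential (per-electrode) signals in microvolts.
The clinical preprocessing chain for suppression-end detection is

    referential 13-electrode EEG
      -> 10 bipolar montage channels (adjacent-electrode differences)
      -> uniform 200 Hz sampling grid
      -> optional Hann-window smoothing.

Times are seconds from recording start; sample index 0 sits at t = 0 and a
window [start, start + w) is half-open.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

logger = logging.getLogger(__name__)

#: The 13 scalp electrodes (10-20 system) required for the default montage.
ELECTRODES_13 = (
    "Fp1", "Fp2", "O1", "O2", "F7", "F8", "T7", "T8", "P7", "P8",
    "Fz", "Cz", "Pz",
)


@dataclass(frozen=True)
class MontagePair:
    """A bipolar derivation ``anode - cathode`` between two electrodes."""

    anode: str
    cathode: str

    def __post_init__(self) -> None:
        if self.anode == self.cathode:
            raise ValueError(f"montage pair must use two distinct electrodes, got {self.anode!r} twice")

    @property
    def label(self) -> str:
        return f"{self.anode}-{self.cathode}"


#: The 10 standard bipolar montages used for suppression-end detection:
#: two temporal chains, and the midline Fz-Cz / Cz-Pz derivations.
DEFAULT_MONTAGE: tuple[MontagePair, ...] = tuple(
    MontagePair(a, c)
    for a, c in [
        ("Fp1", "F7"), ("F7", "T7"), ("T7", "P7"), ("P7", "O1"),
        ("Fp2", "F8"), ("F8", "T8"), ("T8", "P8"), ("P8", "O2"),
        ("Fz", "Cz"), ("Cz", "Pz"),
    ]
)


def _validate_signal_block(labels, data, sampling_rate_hz, duration_s, pges_end_s):
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError(f"data must be 2-D (channels x samples), got shape {data.shape}")
    if data.shape[0] != len(labels):
        raise ValueError(
            f"{len(labels)} channel labels but data has {data.shape[0]} rows"
        )
    if sampling_rate_hz <= 0:
        raise ValueError("sampling_rate_hz must be positive")
    n_expected = int(round(duration_s * sampling_rate_hz))
    if data.shape[1] != n_expected:
        raise ValueError(
            f"sample count {data.shape[1]} does not match duration_s * rate = {n_expected}"
        )
    if pges_end_s is not None and not (0.0 <= pges_end_s <= duration_s):
        raise ValueError(
            f"pges_end_s={pges_end_s} outside recording [0, {duration_s}]"
        )
    return data


@dataclass
class Recording:
    """A referential multichannel EEG recording in microvolts.

    Parameters
    ----------
    recording_id
        Stable identifier used in manifests, crop provenance and reports.
    channel_labels
        Electrode names, one per data row, in row order.
    data
        Array of shape ``(n_channels, n_samples)``, amplitudes in microvolts.
    sampling_rate_hz
        Sampling rate shared by every channel.
    pges_end_s
        Annotation of the end of postictal suppression (onset of the first
        intermittent slow-wave burst), seconds from recording start, or None
        when the recording is unannotated.
    """

    recording_id: str
    channel_labels: list[str]
    data: np.ndarray
    sampling_rate_hz: float
    pges_end_s: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"data must be 2-D (channels x samples), got shape {self.data.shape}")
        self.channel_labels = list(self.channel_labels)
        _validate_signal_block(
            self.channel_labels, self.data, self.sampling_rate_hz,
            self.duration_s, self.pges_end_s,
        )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.sampling_rate_hz

    def channel(self, label: str) -> np.ndarray:
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"electrode {label!r} not in recording {self.recording_id!r}") from None
        return self.data[idx]


@dataclass
class MontagedRecording:
    """Bipolar-montage EEG: one row per anode-cathode derivation."""

    recording_id: str
    montage_labels: list[str]
    data: np.ndarray
    sampling_rate_hz: float
    pges_end_s: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"data must be 2-D (channels x samples), got shape {self.data.shape}")
        self.montage_labels = list(self.montage_labels)
        _validate_signal_block(
            self.montage_labels, self.data, self.sampling_rate_hz,
            self.duration_s, self.pges_end_s,
        )

    @property
    def n_montages(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.sampling_rate_hz


def to_bipolar_montage(
    rec: Recording, pairs: tuple[MontagePair, ...] | list[MontagePair] = DEFAULT_MONTAGE
) -> MontagedRecording:
    """Derive bipolar channels (anode minus cathode) from a referential recording.

    Every electrode named by `pairs` must exist in `rec`; extra electrodes in
    the recording are simply unused. Duplicate pairs are rejected.
    """
    labels = [p.label for p in pairs]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate montage pair in pair list")
    rows = [rec.channel(p.anode) - rec.channel(p.cathode) for p in pairs]
    return MontagedRecording(
        recording_id=rec.recording_id,
        montage_labels=labels,
        data=np.vstack(rows),
        sampling_rate_hz=rec.sampling_rate_hz,
        pges_end_s=rec.pges_end_s,
    )


def resample(mrec: MontagedRecording, target_rate_hz: float = 200.0) -> MontagedRecording:
    """Resample every montage row to `target_rate_hz` (default 200 Hz).

    Uses polyphase rational resampling with the built-in anti-aliasing filter,
    so the result is deterministic and band-limited. Annotations are in
    seconds and carry through unchanged.
    """
    if target_rate_hz <= 0:
        raise ValueError("target rate must be positive")
    src = mrec.sampling_rate_hz
    if not (50.0 <= src <= 2000.0):
        raise ValueError(f"source rate {src} Hz outside the supported 50-2000 Hz band")
    if src == target_rate_hz:
        return replace(mrec, data=mrec.data.copy())
    frac = Fraction(target_rate_hz / src).limit_denominator(1000)
    # line padding avoids the zero-padding transient at the recording edges
    out = sps.resample_poly(mrec.data, frac.numerator, frac.denominator,
                            axis=1, padtype="line")
    n_expected = int(round(mrec.duration_s * target_rate_hz))
    if out.shape[1] > n_expected:
        out = out[:, :n_expected]
    elif out.shape[1] < n_expected:  # pad by edge value; off-by-one from rational rounding
        pad = np.repeat(out[:, -1:], n_expected - out.shape[1], axis=1)
        out = np.hstack([out, pad])
    return MontagedRecording(
        recording_id=mrec.recording_id,
        montage_labels=list(mrec.montage_labels),
        data=out,
        sampling_rate_hz=target_rate_hz,
        pges_end_s=mrec.pges_end_s,
    )


def hann_denoise(mrec: MontagedRecording, window_len_samples: int = 11) -> MontagedRecording:
    """Smooth each montage row with a unit-sum Hann window (zero-phase).

    The kernel is symmetric so there is no phase shift; edges are handled by
    reflection. `window_len_samples` must be odd and at least 3 (a centred
    symmetric kernel needs an odd length). At 200 Hz the default 11 samples
    spans 55 ms.
    """
    if window_len_samples < 3 or window_len_samples % 2 == 0:
        raise ValueError("window_len_samples must be an odd integer >= 3")
    win = sps.windows.hann(window_len_samples, sym=True)
    win = win / win.sum()
    half = window_len_samples // 2
    padded = np.pad(mrec.data, ((0, 0), (half, half)), mode="reflect")
    out = np.apply_along_axis(lambda r: np.convolve(r, win, mode="valid"), 1, padded)
    return replace(mrec, data=out)


# ---------------------------------------------------------------------------
# Simple plain-text interchange format: signals.csv + meta.json
# ---------------------------------------------------------------------------

def write_simple(rec: Recording, directory: str | Path) -> Path:
    """Write `rec` as ``signals.csv`` (rows = channels) + ``meta.json``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savetxt(directory / "signals.csv", rec.data, delimiter=",", fmt="%.17g")
    meta = {
        "recording_id": rec.recording_id,
        "channel_labels": rec.channel_labels,
        "sampling_rate_hz": rec.sampling_rate_hz,
    }
    if rec.pges_end_s is not None:
        meta["pges_end_s"] = rec.pges_end_s
    (directory / "meta.json").write_text(json.dumps(meta, indent=1))
    return directory


def read_simple(directory: str | Path) -> Recording:
    """Read a recording written by :func:`write_simple`.

    The metadata is validated against the matrix shape; a label/row-count
    mismatch, missing keys, or an annotation outside the recording raise
    ``ValueError``.
    """
    directory = Path(directory)
    meta_path = directory / "meta.json"
    sig_path = directory / "signals.csv"
    if not meta_path.exists() or not sig_path.exists():
        raise FileNotFoundError(f"{directory} must contain signals.csv and meta.json")
    meta = json.loads(meta_path.read_text())
    for key in ("recording_id", "channel_labels", "sampling_rate_hz"):
        if key not in meta:
            raise ValueError(f"meta.json missing required key {key!r}")
    data = np.loadtxt(sig_path, delimiter=",", ndmin=2)
    return Recording(
        recording_id=meta["recording_id"],
        channel_labels=meta["channel_labels"],
        data=data,
        sampling_rate_hz=float(meta["sampling_rate_hz"]),
        pges_end_s=meta.get("pges_end_s"),
    )


def read_annotations(path: str | Path) -> dict[str, float]:
    """Read a sidecar CSV with columns ``recording_id, pges_end_s``."""
    df = pd.read_csv(path)
    missing = {"recording_id", "pges_end_s"} - set(df.columns)
    if missing:
        raise ValueError(f"annotation sidecar {path} missing columns {sorted(missing)}")
    return dict(zip(df["recording_id"].astype(str), df["pges_end_s"].astype(float)))


def write_annotations(annotations: dict[str, float], path: str | Path) -> None:
    pd.DataFrame(
        {"recording_id": list(annotations), "pges_end_s": list(annotations.values())}
    ).to_csv(path, index=False)
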