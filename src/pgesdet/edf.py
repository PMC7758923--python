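"""EDF (European Data Format) export and import for recordings.

Reading goes through MNE's EDF reader. Writing is done by a minimal 16-bit
EDF writer: one-second data records, per-channel physical calibration taken
from the data range, amplitudes in microvolts. The writer covers exactly what
the simulator and the round-trip tests need (uniform rate, integer number of
one-second records); it is not a general-purpose EDF+ implementation.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from .io import Recording

logger = logging.getLogger(__name__)

_DIG_MIN, _DIG_MAX = -32768, 32767


def _fixed(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"field {text!r} longer than {width} bytes")
    return b.ljust(width)


def write_edf(rec: Recording, path: str | Path) -> Path:
    """Write `rec` to `path` as a 16-bit EDF file.

    Requires an integer number of seconds and an integer sampling rate so the
    signal divides into one-second records.
    """
    path = Path(path)
    rate = rec.sampling_rate_hz
    if abs(rate - round(rate)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    rate = int(round(rate))
    n_records, rem = divmod(rec.n_samples, rate)
    if rem:
        raise ValueError("EDF writer requires a whole number of one-second records")
    ns = rec.n_channels

    # Physical range per channel, symmetric, with headroom so that the
    # quantisation step stays well below 0.01 uV for typical suppression data.
    phys_max = np.maximum(np.abs(rec.data).max(axis=1) * 1.001, 1.0)
    phys_min = -phys_max
    gain = (phys_max - phys_min) / (_DIG_MAX - _DIG_MIN)
    digital = np.clip(
        np.round((rec.data - phys_min[:, None]) / gain[:, None]) + _DIG_MIN,
        _DIG_MIN, _DIG_MAX,
    ).astype("<i2")

    header = bytearray()
    header += _fixed("0", 8)                      # version
    header += _fixed(rec.recording_id[:80], 80)   # patient id field
    header += _fixed(f"Startdate 01-JAN-2000 {rec.recording_id[:50]}", 80)
    header += _fixed("01.01.00", 8)
    header += _fixed("00.00.00", 8)
    header += _fixed(str(256 * (ns + 1)), 8)
    header += _fixed("", 44)
    header += _fixed(str(n_records), 8)
    header += _fixed("1", 8)                      # record duration, seconds
    header += _fixed(str(ns), 4)
    for label in rec.channel_labels:
        header += _fixed(label[:16], 16)
    header += b"".join(_fixed("", 80) for _ in range(ns))       # transducer
    header += b"".join(_fixed("uV", 8) for _ in range(ns))      # dimension
    header += b"".join(_fixed(f"{v:.6g}"[:8], 8) for v in phys_min)
    header += b"".join(_fixed(f"{v:.6g}"[:8], 8) for v in phys_max)
    header += b"".join(_fixed(str(_DIG_MIN), 8) for _ in range(ns))
    header += b"".join(_fixed(str(_DIG_MAX), 8) for _ in range(ns))
    header += b"".join(_fixed("", 80) for _ in range(ns))       # prefiltering
    header += b"".join(_fixed(str(rate), 8) for _ in range(ns))
    header += b"".join(_fixed("", 32) for _ in range(ns))

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        # records: for each second, all channels back to back
        rec3d = digital.reshape(ns, n_records, rate)
        for r in range(n_records):
            fh.write(rec3d[:, r, :].tobytes())
    return path


def _header_sample_rates(path: Path) -> list[float]:
    """Per-signal sampling rates straight from the EDF header."""
    with open(path, "rb") as fh:
        head = fh.read(256)
        ns = int(head[252:256].decode("ascii").strip())
        sig = fh.read(256 * ns)
    dur = float(head[244:252].decode("ascii").strip())
    off = (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80) * ns
    rates = []
    for i in range(ns):
        n = int(sig[off + 8 * i: off + 8 * (i + 1)].decode("ascii").strip())
        rates.append(n / dur)
    return rates


def read_edf(
    path: str | Path,
    pges_end_s: float | None = None,
    electrodes: list[str] | None = None,
) -> Recording:
    """Read an EDF/EDF+ file into a :class:`Recording` (microvolts).

    Parameters
    ----------
    path
        EDF file. All signals must share one sampling rate; clinical scalp
        montage channels do, and heterogeneous-rate files are rejected rather
        than silently harmonised.
    pges_end_s
        Optional suppression-end annotation to attach, seconds from start.
    electrodes
        If given, keep only these channels (extra channels in the file are
        dropped with a logged warning); order follows the file.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rates = _header_sample_rates(path)
    if len(set(rates)) > 1:
        raise ValueError(
            f"{path.name}: channels have mixed sampling rates {sorted(set(rates))}; "
            "one rate per recording is required"
        )
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    labels = list(raw.ch_names)
    if electrodes is not None:
        missing = [e for e in electrodes if e not in labels]
        if missing:
            raise ValueError(f"{path.name}: required electrodes {missing} absent")
        dropped = [l for l in labels if l not in electrodes]
        if dropped:
            logger.warning("%s: ignoring extra channels %s", path.name, dropped)
        keep_idx = [i for i, l in enumerate(labels) if l in electrodes]
        labels = [labels[i] for i in keep_idx]
        data = raw.get_data()[keep_idx] * 1e6
    else:
        data = raw.get_data() * 1e6  # MNE returns volts
    rec = Recording(
        recording_id=path.stem,
        channel_labels=labels,
        data=data,
        sampling_rate_hz=float(raw.info["sfreq"]),
        pges_end_s=pges_end_s,
    )
    return rec
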