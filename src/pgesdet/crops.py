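"""Sliding-window crop extraction, labeling and leakage-safe splits.

A recording annotated with the end of suppression is cut into fixed-length
windows on a regular stride grid anchored at t = 0. A crop is positive when
its window end reaches or passes the annotated suppression end, negative when
it lies entirely within suppression. Windows extending more than one latency
period past the suppression end are excluded from the dataset, so no training
content lies beyond onset + latency; at inference time the whole recording is
scanned instead (see :mod:`pgesdet.infer`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import MontagedRecording

_EPS = 1e-9  # guards strict float comparisons on the second-valued grid


@dataclass(frozen=True)
class CropSpec:
    """Window length, stride and detection latency, in seconds.

    Defaults are 10 s windows every 100 ms with a 10 s latency period: a
    detector must flag the suppression end no later than 10 s after it.
    """

    window_s: float = 10.0
    stride_s: float = 0.1
    latency_s: float = 10.0

    def __post_init__(self) -> None:
        if not (self.window_s > self.stride_s > 0):
            raise ValueError("require window_s > stride_s > 0")
        if self.latency_s <= 0:
            raise ValueError("latency_s must be positive")


@dataclass(frozen=True)
class Crop:
    """One labeled fixed-length window of a montaged recording."""

    recording_id: str
    start_s: float
    end_s: float
    label: int
    data: np.ndarray  # (n_montages, window samples), view into the recording


@dataclass
class CropSet:
    """An ordered collection of crops plus the spec that produced them."""

    crops: list[Crop]
    spec: CropSpec

    def __len__(self) -> int:
        return len(self.crops)

    @property
    def recording_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.crops:
            seen.setdefault(c.recording_id, None)
        return list(seen)

    def stacked(self, dtype=np.float32) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(X, y)`` with X of shape (n_crops, n_montages, n_samples)."""
        X = np.stack([c.data for c in self.crops]).astype(dtype)
        y = np.array([c.label for c in self.crops], dtype=np.int64)
        return X, y

    def labels(self) -> np.ndarray:
        return np.array([c.label for c in self.crops], dtype=np.int64)

    def index_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "recording_id": [c.recording_id for c in self.crops],
                "start_s": [c.start_s for c in self.crops],
                "label": [c.label for c in self.crops],
            }
        )

    def subset(self, recording_ids) -> "CropSet":
        wanted = set(recording_ids)
        return CropSet([c for c in self.crops if c.recording_id in wanted], self.spec)

    def save(self, directory: str | Path) -> Path:
        """Persist as ``crops.npy`` (float32 array) + ``index.csv`` + ``spec.json``."""
        import json

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        X, _ = self.stacked()
        np.save(directory / "crops.npy", X)
        self.index_frame().to_csv(directory / "index.csv", index=False)
        (directory / "spec.json").write_text(json.dumps({
            "window_s": self.spec.window_s,
            "stride_s": self.spec.stride_s,
            "latency_s": self.spec.latency_s,
        }))
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "CropSet":
        import json

        directory = Path(directory)
        spec = CropSpec(**json.loads((directory / "spec.json").read_text()))
        X = np.load(directory / "crops.npy")
        idx = pd.read_csv(directory / "index.csv")
        crops = [
            Crop(
                recording_id=str(r.recording_id),
                start_s=float(r.start_s),
                end_s=float(r.start_s) + spec.window_s,
                label=int(r.label),
                data=X[i],
            )
            for i, r in enumerate(idx.itertuples(index=False))
        ]
        return cls(crops, spec)


def count_crops(segment_len_s: float, spec: CropSpec) -> int:
    """Number of whole windows fitting a segment: floor((L - w)/s) + 1, or 0."""
    if segment_len_s < 0:
        raise ValueError("segment length must be nonnegative")
    if segment_len_s < spec.window_s - _EPS:
        return 0
    return int(np.floor((segment_len_s - spec.window_s) / spec.stride_s + _EPS)) + 1


def label_crop(end_s: float, pges_end_s: float) -> int:
    """1 if the window end reaches or passes the suppression end, else 0."""
    return int(end_s >= pges_end_s - _EPS)


def enumerate_crops(mrec: MontagedRecording, spec: CropSpec = CropSpec()) -> CropSet:
    """Extract every retained labeled crop from an annotated recording.

    Crop starts lie at 0, stride, 2*stride, ...; a crop whose end exceeds
    ``pges_end_s + latency_s`` is excluded entirely (no content beyond
    onset + latency enters the dataset). The retained count therefore equals
    ``count_crops(min(duration, pges_end + latency), spec)``.
    """
    if mrec.pges_end_s is None:
        raise ValueError(f"recording {mrec.recording_id!r} has no suppression-end annotation")
    fs = mrec.sampling_rate_hz
    win_n = int(round(spec.window_s * fs))
    limit_s = min(mrec.duration_s, mrec.pges_end_s + spec.latency_s)
    crops: list[Crop] = []
    i = 0
    while True:
        start_s = i * spec.stride_s
        end_s = start_s + spec.window_s
        if end_s > limit_s + _EPS:
            break
        start_n = int(round(start_s * fs))
        crops.append(
            Crop(
                recording_id=mrec.recording_id,
                start_s=start_s,
                end_s=end_s,
                label=label_crop(end_s, mrec.pges_end_s),
                data=mrec.data[:, start_n: start_n + win_n],
            )
        )
        i += 1
    return CropSet(crops, spec)


def split_dataset(
    recording_ids: list[str], train_fraction: float = 0.8, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Shuffle recording ids and split at the recording level.

    All crops of a recording land on one side, so no signal content leaks
    between train and test. The train side gets ``floor(fraction * n)`` ids
    (168 ids at 0.8 give the 134/34 split).
    """
    if not recording_ids:
        raise ValueError("recording id list is empty")
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must lie in (0, 1)")
    ids = list(recording_ids)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_train = int(np.floor(train_fraction * len(ids)))
    train = [ids[i] for i in perm[:n_train]]
    test = [ids[i] for i in perm[n_train:]]
    return train, test
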