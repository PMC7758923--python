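"""Hand-crafted per-crop EEG features and tree-ensemble classifiers.

The feature bank covers the families that distinguish suppressed from
slow-wave EEG: distribution moments, band power / power spectral intensity /
peak and median frequency, Petrosian fractal dimension, SVD entropy,
inter-channel Pearson correlation, and first-half vs second-half temporal
ratios. Degenerate inputs (constant or all-zero windows) never produce
non-finite values: the affected features are returned as 0 together with a
per-montage degeneracy flag column, so tree models train unimpeded.

Each montage row is demeaned before feature extraction (standard drift
removal), which also makes every feature invariant to a constant amplitude
offset of the raw signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import signal as sps
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .crops import Crop, CropSet

#: Standard clinical EEG frequency bands, Hz.
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 70.0),
}

_DEGENERATE_RMS = 1e-12


def moment_features(series: np.ndarray) -> tuple[float, float, float, bool]:
    """Population variance, skewness (m3/m2^1.5) and kurtosis (m4/m2^2).

    Kurtosis is non-excess (a Gaussian gives 3). A constant series has zero
    variance and undefined shape moments; those are returned as 0 with the
    degenerate flag set.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 samples for third/fourth moments")
    d = x - x.mean()
    m2 = np.mean(d**2)
    if m2 <= _DEGENERATE_RMS**2:
        return 0.0, 0.0, 0.0, True
    skew = np.mean(d**3) / m2**1.5
    kurt = np.mean(d**4) / m2**2
    return float(m2), float(skew), float(kurt), False


@dataclass(frozen=True)
class SpectralFeatures:
    band_power: dict[str, float]
    band_psi: dict[str, float]          # power spectral intensity: sum |X(f)| over band
    band_rir: dict[str, float]          # relative intensity ratio, PSI_band / PSI_total
    peak_freq_hz: float
    median_freq_hz: float
    total_energy: float
    degenerate: bool


def spectral_features(
    series: np.ndarray, rate_hz: float, bands: dict[str, tuple[float, float]] = DEFAULT_BANDS
) -> SpectralFeatures:
    """Periodogram-based band powers, spectral intensities and landmark frequencies.

    The DC bin is excluded throughout, so results do not depend on a constant
    offset. ``peak_freq_hz`` is the frequency of maximum power;
    ``median_freq_hz`` is the smallest frequency at which cumulative power
    reaches half the total.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 2 * rate_hz:
        raise ValueError("series shorter than 2 s; spectral features need >= 2 s of signal")
    freqs, pxx = sps.periodogram(x, fs=rate_hz, detrend=False)
    mags = np.sqrt(pxx)
    freqs, pxx, mags = freqs[1:], pxx[1:], mags[1:]  # drop DC
    nyq = rate_hz / 2.0
    total = float(pxx.sum())
    band_power, band_psi, band_rir = {}, {}, {}
    psi_total = float(mags.sum())
    for name, (lo, hi) in bands.items():
        if lo >= nyq:
            raise ValueError(f"band {name} ({lo}-{hi} Hz) lies above Nyquist {nyq} Hz")
        sel = (freqs >= lo) & (freqs < min(hi, nyq))
        if not sel.any():
            raise ValueError(f"band {name} maps to no periodogram bin")
        band_power[name] = float(pxx[sel].sum())
        band_psi[name] = float(mags[sel].sum())
    degenerate = total <= _DEGENERATE_RMS**2
    if degenerate:
        peak = median = 0.0
        band_rir = {k: 0.0 for k in bands}
    else:
        peak = float(freqs[np.argmax(pxx)])
        cum = np.cumsum(pxx)
        median = float(freqs[np.searchsorted(cum, 0.5 * total)])
        band_rir = {k: band_psi[k] / psi_total for k in bands}
    return SpectralFeatures(band_power, band_psi, band_rir, peak, median, total, degenerate)


def petrosian_fd(series: np.ndarray) -> float:
    """Petrosian fractal dimension of a series.

    ``PFD = log10(N) / (log10(N) + log10(N / (N + 0.4 * Nd)))`` where Nd is
    the number of sign changes in the first difference. A constant series has
    Nd = 0 and the formula collapses to exactly 1.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 samples")
    diff = np.diff(x)
    n_delta = int(np.sum(diff[:-1] * diff[1:] < 0))
    log_n = np.log10(n)
    return float(log_n / (log_n + np.log10(n / (n + 0.4 * n_delta))))


def svd_entropy(series: np.ndarray, embed_dim: int = 20, delay: int = 1) -> tuple[float, bool]:
    """Entropy (bits) of normalized singular values of the delay embedding.

    Rows of the embedding matrix are ``x[i], x[i+delay], ...,
    x[i+(dim-1)*delay]``. Singular values are normalized to sum to one and
    fed through the Shannon formula; an all-zero series gives entropy 0 with
    the degenerate flag set. Upper bound: log2(embed_dim).
    """
    x = np.asarray(series, dtype=float)
    if x.size <= embed_dim * delay:
        raise ValueError("series too short for the requested embedding")
    if np.sqrt(np.mean(x**2)) <= _DEGENERATE_RMS:
        return 0.0, True
    n_rows = x.size - (embed_dim - 1) * delay
    idx = np.arange(n_rows)[:, None] + np.arange(embed_dim)[None, :] * delay
    sv = np.linalg.svd(x[idx], compute_uv=False)
    total = sv.sum()
    p = sv[sv > 0] / total
    return float(-(p * np.log2(p)).sum()), False


def cross_channel_correlation(crop_data: np.ndarray) -> np.ndarray:
    """Pearson correlation for each unordered montage pair (C(n,2) values).

    Pairs involving a constant row get correlation 0 (flagged degenerate via
    the per-montage flags in the full feature vector).
    """
    x = np.asarray(crop_data, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a (montages x samples) array with >= 2 rows")
    stds = x.std(axis=1)
    ok = stds > _DEGENERATE_RMS
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x)
    out = []
    for i, j in combinations(range(x.shape[0]), 2):
        out.append(float(corr[i, j]) if ok[i] and ok[j] else 0.0)
    return np.array(out)


def _line_length(x: np.ndarray) -> float:
    return float(np.abs(np.diff(x)).sum())


def _band_power(x: np.ndarray, rate_hz: float, band: tuple[float, float]) -> float:
    freqs, pxx = sps.periodogram(x, fs=rate_hz, detrend=False)
    sel = (freqs >= band[0]) & (freqs < band[1])
    return float(pxx[sel].sum())


def temporal_ratio(
    crop_data: np.ndarray, rate_hz: float, prop: str = "rms",
    band: tuple[float, float] = DEFAULT_BANDS["delta"],
) -> np.ndarray:
    """Second-half / first-half ratio of a signal property, per montage row.

    ``prop`` is one of ``rms``, ``band_power`` (over `band`) or
    ``line_length``. A small additive guard (1e-12) keeps the ratio finite on
    silent first halves. Values above 1 indicate emerging activity in the
    second half of the window — the signature of a crop straddling the end of
    suppression.
    """
    x = np.asarray(crop_data, dtype=float)
    half = x.shape[-1] // 2
    first, second = x[..., :half], x[..., half: 2 * half]
    if prop == "rms":
        f = lambda h: np.sqrt(np.mean(h**2, axis=-1))
        a, b = f(second), f(first)
    elif prop == "band_power":
        a = np.array([_band_power(r, rate_hz, band) for r in np.atleast_2d(second)])
        b = np.array([_band_power(r, rate_hz, band) for r in np.atleast_2d(first)])
    elif prop == "line_length":
        a = np.array([_line_length(r) for r in np.atleast_2d(second)])
        b = np.array([_line_length(r) for r in np.atleast_2d(first)])
    else:
        raise ValueError(f"unknown property {prop!r}")
    return np.atleast_1d(a / (b + 1e-12))


@dataclass(frozen=True)
class FeatureConfig:
    """Which feature families to extract and their parameters."""

    moments: bool = True
    spectral: bool = True
    fractal: bool = True
    entropy: bool = True
    correlation: bool = True
    ratios: bool = True
    bands: tuple[tuple[str, tuple[float, float]], ...] = tuple(DEFAULT_BANDS.items())
    svd_embed_dim: int = 20
    svd_delay: int = 1
    ratio_props: tuple[str, ...] = ("rms", "band_power", "line_length")

    def feature_names(self, n_montages: int) -> list[str]:
        names: list[str] = []
        per = []
        if self.moments:
            per += ["variance", "skewness", "kurtosis"]
        if self.spectral:
            per += [f"power_{b}" for b, _ in self.bands]
            per += [f"psi_{b}" for b, _ in self.bands]
            per += [f"rir_{b}" for b, _ in self.bands]
            per += ["peak_freq", "median_freq", "total_energy"]
        if self.fractal:
            per += ["petrosian_fd"]
        if self.entropy:
            per += ["svd_entropy"]
        if self.ratios:
            per += [f"ratio_{p}" for p in self.ratio_props]
        per += ["degenerate"]
        for m in range(n_montages):
            names += [f"m{m:02d}_{p}" for p in per]
        if self.correlation:
            names += [f"corr_{i:02d}_{j:02d}" for i, j in combinations(range(n_montages), 2)]
        return names

    def n_features(self, n_montages: int) -> int:
        return len(self.feature_names(n_montages))


def extract_feature_vector(
    crop_data: np.ndarray, rate_hz: float, config: FeatureConfig = FeatureConfig()
) -> np.ndarray:
    """Concatenate all enabled feature families over all montage rows.

    Deterministic, stable ordering given by ``config.feature_names``. Rows
    are demeaned first; degenerate rows contribute zeros plus a set flag.
    """
    x = np.asarray(crop_data, dtype=float)
    x = x - x.mean(axis=1, keepdims=True)
    bands = dict(config.bands)
    values: list[float] = []
    for row in x:
        degenerate = False
        if config.moments:
            v, s, k, deg = moment_features(row)
            values += [v, s, k]
            degenerate |= deg
        if config.spectral:
            sf = spectral_features(row, rate_hz, bands)
            values += [sf.band_power[b] for b in bands]
            values += [sf.band_psi[b] for b in bands]
            values += [sf.band_rir[b] for b in bands]
            values += [sf.peak_freq_hz, sf.median_freq_hz, sf.total_energy]
            degenerate |= sf.degenerate
        if config.fractal:
            values.append(petrosian_fd(row))
        if config.entropy:
            ent, deg = svd_entropy(row, config.svd_embed_dim, config.svd_delay)
            values.append(ent)
            degenerate |= deg
        if config.ratios:
            for p in config.ratio_props:
                values.append(float(temporal_ratio(row, rate_hz, p)[0]))
        values.append(float(degenerate))
    if config.correlation:
        values += list(cross_channel_correlation(x))
    out = np.array(values)
    assert np.all(np.isfinite(out)), "feature extraction produced non-finite values"
    return out


def extract_feature_matrix(
    X: np.ndarray, rate_hz: float, config: FeatureConfig = FeatureConfig()
) -> np.ndarray:
    """Feature matrix for a stack of crops, shape (n_crops, n_features)."""
    return np.stack([extract_feature_vector(c, rate_hz, config) for c in X])


class FeatureClassifier:
    """Tree ensemble over the hand-crafted feature bank.

    Wraps feature extraction + train-set z-scoring + a random forest or
    gradient-boosted-trees model behind the crop-level probability interface
    shared with the CNN: ``predict_proba_crops(X)`` maps a
    ``(n, montages, samples)`` stack to P(window reaches the suppression end).
    """

    def __init__(self, model: str = "random_forest", config: FeatureConfig = FeatureConfig(),
                 seed: int = 0, n_estimators: int = 200):
        if model == "random_forest":
            # balanced subsample weights: crop labeling is imbalanced whenever
            # suppression lasts much longer than the latency period
            est = RandomForestClassifier(
                n_estimators=n_estimators, random_state=seed, n_jobs=1,
                class_weight="balanced_subsample",
            )
        elif model == "gradient_boosted_trees":
            est = GradientBoostingClassifier(n_estimators=n_estimators, random_state=seed)
        else:
            raise ValueError(f"unknown model {model!r}")
        self.model_name = model
        self.config = config
        self.rate_hz: float | None = None
        self.pipeline = Pipeline([("scale", StandardScaler()), ("clf", est)])
        self.feature_names_: list[str] | None = None

    def fit(self, X: np.ndarray, y: np.ndarray, rate_hz: float) -> "FeatureClassifier":
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both classes")
        self.rate_hz = rate_hz
        self.feature_names_ = self.config.feature_names(X.shape[1])
        F = extract_feature_matrix(X, rate_hz, self.config)
        self.pipeline.fit(F, y)
        return self

    def predict_proba_crops(self, X: np.ndarray) -> np.ndarray:
        if self.rate_hz is None:
            raise RuntimeError("classifier is not fitted")
        F = extract_feature_matrix(X, self.rate_hz, self.config)
        return self.pipeline.predict_proba(F)[:, 1]

    @property
    def feature_importances_(self) -> dict[str, float]:
        clf = self.pipeline.named_steps["clf"]
        return dict(zip(self.feature_names_, clf.feature_importances_))


def train_feature_classifier(
    train: CropSet, model: str = "random_forest",
    config: FeatureConfig = FeatureConfig(), seed: int = 0,
) -> FeatureClassifier:
    """Fit a tree-ensemble detector on the crops of a training set."""
    X, y = train.stacked(dtype=np.float64)
    rate = _crop_rate(train)
    return FeatureClassifier(model=model, config=config, seed=seed).fit(X, y, rate)


def _crop_rate(cs: CropSet) -> float:
    n_samples = cs.crops[0].data.shape[1]
    return n_samples / cs.spec.window_s
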