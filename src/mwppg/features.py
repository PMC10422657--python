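"""Window-level feature computation and feature-matrix assembly.

Implements the ten-feature custom set natively (peak statistics, spectral
band summaries, turning points, entropies, median difference) and encodes the
TSFEL/tsfresh final sets as named specifications with per-feature channel
assignments.  Additional feature implementations can be plugged in through
:func:`register_feature`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import signal as _sig

from mwppg.signal_synth import CHANNELS, MultiChannelRecord
from mwppg.windowing import WindowSet

_CH_ALIASES = {"ch1": "green", "ch2": "red", "ch3": "ir"}


class UnknownFeatureError(KeyError):
    pass


# ---------------------------------------------------------------------------
# Peak detection
# ---------------------------------------------------------------------------

def detect_peaks(
    window: np.ndarray,
    fs: float,
    hr_max_bpm: float = 180.0,
    prominence_frac: float = 0.1,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Strict local maxima with physiological spacing and prominence gates.

    Peaks must be separated by at least ``fs * 60 / hr_max_bpm`` samples and
    have topographic prominence of at least ``prominence_frac`` of the window
    range.  Widths are measured at half prominence, in samples.

    Returns ``(indices, amplitudes, widths_samples)``.
    """
    x = np.asarray(window, dtype=float)
    if x.size == 0 or np.ptp(x) == 0:
        empty = np.zeros(0)
        return empty.astype(int), empty, empty
    distance = max(1, int(round(fs * 60.0 / hr_max_bpm)))
    prominence = prominence_frac * np.ptp(x)
    idx, _ = _sig.find_peaks(x, distance=distance, prominence=prominence)
    if idx.size == 0:
        empty = np.zeros(0)
        return empty.astype(int), empty, empty
    widths = _sig.peak_widths(x, idx, rel_height=0.5)[0]
    return idx, x[idx], widths


# ---------------------------------------------------------------------------
# Individual features
# ---------------------------------------------------------------------------

def _unbiased_var(v: np.ndarray) -> float:
    return float(np.var(v, ddof=1)) if v.size >= 2 else 0.0


def _welch(x: np.ndarray, fs: float, nperseg: int, nfft: Optional[int] = None):
    nperseg = min(len(x), nperseg)
    return _sig.welch(
        x - np.mean(x), fs=fs, window="hann", nperseg=nperseg,
        noverlap=nperseg // 2, nfft=nfft, scaling="density",
    )


def feat_num_of_peaks(x: np.ndarray, fs: float, **kw) -> float:
    idx, _, _ = detect_peaks(x, fs, **kw)
    return float(idx.size)


def feat_peak_var(x: np.ndarray, fs: float, **kw) -> float:
    _, amps, _ = detect_peaks(x, fs, **kw)
    return _unbiased_var(amps)


def feat_peak_width_var(x: np.ndarray, fs: float, **kw) -> float:
    _, _, widths = detect_peaks(x, fs, **kw)
    return _unbiased_var(widths / fs)


def feat_psd_mean(
    x: np.ndarray, fs: float, nfft: int = 512, lo_bin: int = 50, hi_bin: int = 200
) -> float:
    """Mean power density over FFT bins [lo_bin, hi_bin] of an nfft-point
    spectrum (an above-cardiac noise band; ~12.2-48.8 Hz at 125 Hz)."""
    if x.size < 2:
        return 0.0
    _, p = _welch(x, fs, nperseg=nfft, nfft=nfft)
    hi = min(hi_bin, p.size - 1)
    return float(np.mean(p[lo_bin : hi + 1]))


def feat_frequency_bands_slope(
    x: np.ndarray,
    fs: float,
    low_band: Tuple[float, float] = (1.0, 2.0),
    high_band: Tuple[float, float] = (3.0, 10.0),
) -> float:
    """Mean dB power in the cardiac band minus the above-cardiac band, per Hz
    of band-center separation.  Clean pulsatile windows score higher than
    broadband-noise windows."""
    if x.size < 4:
        return 0.0
    f, p = _welch(x, fs, nperseg=int(2 * fs))
    p_db = 10.0 * np.log10(p + 1e-30)
    lo = (f >= low_band[0]) & (f <= low_band[1])
    hi = (f >= high_band[0]) & (f <= high_band[1])
    if not lo.any() or not hi.any():
        return 0.0
    gap = (high_band[0] + high_band[1]) / 2.0 - (low_band[0] + low_band[1]) / 2.0
    return float((p_db[lo].mean() - p_db[hi].mean()) / gap)


def _turning_points(x: np.ndarray) -> Tuple[int, int]:
    d = np.diff(np.asarray(x, dtype=float))
    s = np.sign(d)
    s = s[s != 0]
    if s.size < 2:
        return 0, 0
    pos = int(np.sum((s[:-1] > 0) & (s[1:] < 0)))  # local maxima
    neg = int(np.sum((s[:-1] < 0) & (s[1:] > 0)))  # local minima
    return pos, neg


def feat_pos_turning_points(x: np.ndarray, fs: float = 0.0, **kw) -> float:
    return float(_turning_points(x)[0])


def feat_neg_turning_points(x: np.ndarray, fs: float = 0.0, **kw) -> float:
    return float(_turning_points(x)[1])


def feat_binned_entropy(x: np.ndarray, fs: float = 0.0, bins: int = 10) -> float:
    """Shannon entropy (nats) of the normalized equal-width histogram."""
    x = np.asarray(x, dtype=float)
    if x.size == 0 or np.ptp(x) == 0:
        return 0.0
    counts, _ = np.histogram(x, bins=bins)
    p = counts[counts > 0] / x.size
    return float(-np.sum(p * np.log(p)))


def _ricker(points: int, a: float) -> np.ndarray:
    # Mexican-hat wavelet; mirrors the classical discretization.
    A = 2.0 / (np.sqrt(3.0 * a) * np.pi**0.25)
    vec = np.arange(0, points) - (points - 1.0) / 2.0
    xsq = (vec / a) ** 2
    return A * (1.0 - xsq) * np.exp(-xsq / 2.0)


def ricker_cwt(x: np.ndarray, scales: Sequence[float]) -> np.ndarray:
    """Continuous wavelet transform with the Ricker (Mexican-hat) wavelet."""
    x = np.asarray(x, dtype=float)
    out = np.empty((len(scales), x.size))
    for i, a in enumerate(scales):
        points = min(10 * int(np.ceil(a)), x.size)
        out[i] = np.convolve(x, _ricker(points, a), mode="same")
    return out


def feat_wavelet_entropy(
    x: np.ndarray, fs: float = 0.0, scales: Sequence[float] = tuple(range(1, 10))
) -> float:
    """Shannon entropy (nats) of the energy distribution across CWT scales."""
    x = np.asarray(x, dtype=float)
    if x.size < 3 or np.ptp(x) == 0:
        return 0.0
    coeffs = ricker_cwt(x - x.mean(), scales)
    energy = np.sum(coeffs**2, axis=1)
    total = energy.sum()
    if total <= 0:
        return 0.0
    p = energy[energy > 0] / total
    return float(-np.sum(p * np.log(p)))


def feat_median_diff(x: np.ndarray, fs: float = 0.0, **kw) -> float:
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        return 0.0
    return float(np.median(np.diff(x)))


_FEATURE_REGISTRY: Dict[str, Callable[..., float]] = {
    "num_of_peaks": feat_num_of_peaks,
    "peak_var": feat_peak_var,
    "peak_width_var": feat_peak_width_var,
    "PSD_mean": feat_psd_mean,
    "frequency_bands_slope": feat_frequency_bands_slope,
    "pos_turning_points": feat_pos_turning_points,
    "neg_turning_points": feat_neg_turning_points,
    "binned_entropy": feat_binned_entropy,
    "wavelet_entropy": feat_wavelet_entropy,
    "median_diff": feat_median_diff,
}


def register_feature(name: str, func: Callable[..., float]) -> None:
    """Plug in an implementation for a feature name (e.g. a TSFEL feature)."""
    _FEATURE_REGISTRY[name] = func


def compute_feature(name: str, window: np.ndarray, fs: float, params: Optional[dict] = None) -> float:
    try:
        func = _FEATURE_REGISTRY[name]
    except KeyError:
        raise UnknownFeatureError(
            f"feature {name!r} has no registered implementation"
        ) from None
    return float(func(window, fs, **(params or {})))


# ---------------------------------------------------------------------------
# Feature-set specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureDef:
    name: str
    channels: Tuple[str, ...]
    params: Tuple[Tuple[str, object], ...] = ()

    @property
    def params_dict(self) -> dict:
        return dict(self.params)


@dataclass(frozen=True)
class FeatureSetSpec:
    """Ordered feature definitions with sensor-level channel assignments."""

    name: str
    features: Tuple[FeatureDef, ...]

    def __post_init__(self) -> None:
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")
        if any(not f.channels for f in self.features):
            raise ValueError("every channel assignment must be non-empty")

    @property
    def feature_names(self) -> Tuple[str, ...]:
        return tuple(f.name for f in self.features)

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_attributes(self) -> int:
        """Sensor-level column count: sum of channel-assignment sizes."""
        return sum(len(f.channels) for f in self.features)

    @property
    def attribute_names(self) -> Tuple[str, ...]:
        return tuple(
            f"{f.name}__{c}" for f in self.features for c in f.channels
        )


def _defs(rows: Sequence[Tuple[str, Sequence[str]]]) -> Tuple[FeatureDef, ...]:
    return tuple(
        FeatureDef(name, tuple(_CH_ALIASES.get(c, c) for c in chans))
        for name, chans in rows
    )


def custom_feature_set() -> FeatureSetSpec:
    """The built-in custom set: 10 features, 16 channel-wise attributes."""
    return FeatureSetSpec(
        "custom",
        _defs([
            ("peak_var", ("ch2", "ch3")),
            ("frequency_bands_slope", ("ch1", "ch2")),
            ("neg_turning_points", ("ch3",)),
            ("pos_turning_points", ("ch3",)),
            ("binned_entropy", ("ch2", "ch3")),
            ("wavelet_entropy", ("ch1", "ch2", "ch3")),
            ("PSD_mean", ("ch2",)),
            ("num_of_peaks", ("ch1",)),
            ("peak_width_var", ("ch2",)),
            ("median_diff", ("ch2", "ch3")),
        ]),
    )


def tsfel_feature_set() -> FeatureSetSpec:
    """The retained TSFEL set (15 features, 21 attributes); computation of
    the spectral/MFCC members requires plug-in implementations."""
    return FeatureSetSpec(
        "tsfel",
        _defs([
            ("neg_turning_points", ("ch3",)),
            ("pos_turning_points", ("ch3",)),
            ("wavelet_entropy", ("ch1", "ch2", "ch3")),
            ("median_diff", ("ch2", "ch3")),
            ("median_absolute_diff", ("ch3",)),
            ("entropy", ("ch1", "ch2", "ch3")),
            ("MFCC_3", ("ch1", "ch2")),
            ("MFCC_2", ("ch2",)),
            ("MFCC_7", ("ch1",)),
            ("MFCC_6", ("ch2",)),
            ("MFCC_1", ("ch2",)),
            ("median_frequency", ("ch3",)),
            ("FFT_mean_coefficient_130", ("ch2",)),
            ("spectral_kurtosis", ("ch3",)),
            ("spectral_skewness", ("ch2",)),
        ]),
    )


def tsfresh_feature_set() -> FeatureSetSpec:
    """The retained tsfresh set (13 features, 21 attributes); computation
    requires plug-in implementations."""
    return FeatureSetSpec(
        "tsfresh",
        _defs([
            ("binned_entropy", ("ch2", "ch3")),
            ("change_quantiles_14", ("ch3",)),
            ("change_quantiles_16", ("ch3",)),
            ("change_quantiles_18", ("ch3",)),
            ("change_quantiles_17", ("ch1",)),
            ("cid_ce_normalize", ("ch1", "ch2", "ch3")),
            ("lempel_ziv_complexity", ("ch2", "ch3")),
            ("change_quantiles_15", ("ch3",)),
            ("agg_linear_trend_5", ("ch1", "ch2", "ch3")),
            ("change_quantiles_19", ("ch2",)),
            ("change_quantiles_20", ("ch3",)),
            ("reoccurring_datapoints", ("ch1", "ch2", "ch3")),
            ("change_quantiles_10", ("ch1",)),
        ]),
    )


BUILTIN_SETS = {
    "custom": custom_feature_set,
    "tsfel": tsfel_feature_set,
    "tsfresh": tsfresh_feature_set,
}


# ---------------------------------------------------------------------------
# Feature matrices
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Windows x attributes matrix with binary labels.

    ``mode`` is ``"channel"`` (one row per window-channel pair, plain feature
    names as columns), ``"sensor"`` (one row per window, ``feature__channel``
    columns) or ``"aggregated"`` (sensor rows, per-feature channel means).
    """

    X: np.ndarray
    columns: Tuple[str, ...]
    labels: np.ndarray
    mode: str
    split: Optional[np.ndarray] = None
    row_channels: Optional[np.ndarray] = None  # channel-mode bookkeeping

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    def rows(self, split_name: str) -> "FeatureMatrix":
        if self.split is None:
            raise ValueError("matrix has no split assignment")
        idx = np.where(self.split == split_name)[0]
        return FeatureMatrix(
            X=self.X[idx],
            columns=self.columns,
            labels=self.labels[idx],
            mode=self.mode,
            split=self.split[idx],
            row_channels=self.row_channels[idx] if self.row_channels is not None else None,
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(self.columns))
        df["label"] = self.labels
        if self.split is not None:
            df["split"] = self.split
        return df


def _records_map(
    records: Union[MultiChannelRecord, Mapping[str, MultiChannelRecord], Sequence[MultiChannelRecord]]
) -> Mapping[str, MultiChannelRecord]:
    if isinstance(records, MultiChannelRecord):
        return {records.record_id: records}
    if isinstance(records, Mapping):
        return records
    return {r.record_id: r for r in records}


def feature_table(
    ws: WindowSet,
    records,
    spec: FeatureSetSpec,
) -> np.ndarray:
    """Raw per-window, per-channel, per-feature values.

    Shape ``(n_windows, n_channels, n_features)``; channel order follows
    ``ws.channel_names`` and feature order follows ``spec.features``.
    """
    recmap = _records_map(records)
    n_w, n_c, n_f = ws.n_windows, len(ws.channel_names), spec.n_features
    out = np.empty((n_w, n_c, n_f))
    fs = ws.sample_rate
    w = ws.window_samples
    for i in range(n_w):
        rec = recmap[ws.record_ids[i]]
        s0 = int(ws.starts[i])
        for j, ch in enumerate(ws.channel_names):
            seg = rec.samples[ch][s0 : s0 + w]
            for k, fdef in enumerate(spec.features):
                out[i, j, k] = compute_feature(fdef.name, seg, fs, fdef.params_dict)
    return out


def _standardize(
    X: np.ndarray, split: Optional[np.ndarray]
) -> np.ndarray:
    """Impute NaNs to the train median and z-score with train statistics."""
    train_mask = (
        np.ones(X.shape[0], dtype=bool) if split is None else split == "train"
    )
    if not train_mask.any():
        train_mask = np.ones(X.shape[0], dtype=bool)
    Xt = X[train_mask]
    med = np.nanmedian(Xt, axis=0)
    med = np.where(np.isnan(med), 0.0, med)
    X = np.where(np.isnan(X), med, X)
    mean = X[train_mask].mean(axis=0)
    std = X[train_mask].std(axis=0)
    std = np.where(std > 0, std, 1.0)
    return (X - mean) / std


def extract_features(
    ws: WindowSet,
    records,
    spec: Optional[FeatureSetSpec] = None,
    mode: str = "sensor",
    standardize: bool = True,
    table: Optional[np.ndarray] = None,
) -> FeatureMatrix:
    """Assemble the feature matrix for a window set.

    Channel-level mode yields one row per (window, channel) with one column
    per feature and that channel's window label.  Sensor-level mode yields
    one row per window with ``feature__channel`` columns restricted to the
    spec's channel assignments and the OR-ed sensor label.  Attributes are
    z-scored with train-split statistics when a split is present (all rows
    otherwise); missing values are imputed to the train median first.

    ``table`` may carry a precomputed :func:`feature_table` over *all*
    channels to avoid recomputation across modes.
    """
    if spec is None:
        spec = custom_feature_set()
    if mode not in ("channel", "sensor"):
        raise ValueError("mode must be 'channel' or 'sensor'")
    if table is None:
        table = feature_table(ws, records, spec)
    n_w = ws.n_windows
    ch_index = {c: j for j, c in enumerate(ws.channel_names)}

    if mode == "channel":
        columns = spec.feature_names
        X = table.transpose(0, 1, 2).reshape(n_w * len(ws.channel_names), spec.n_features)
        labels = np.concatenate(
            [ws.channel_labels[c][:, None] for c in ws.channel_names], axis=1
        ).reshape(-1) if n_w else np.zeros(0, dtype=np.int8)
        split = (
            np.repeat(ws.split, len(ws.channel_names)) if ws.split is not None else None
        )
        row_channels = np.tile(np.array(ws.channel_names, dtype=object), n_w)
    else:
        columns = spec.attribute_names
        cols = []
        for k, fdef in enumerate(spec.features):
            for c in fdef.channels:
                if c not in ch_index:
                    raise ValueError(f"channel {c!r} not present in window set")
                cols.append(table[:, ch_index[c], k])
        X = np.stack(cols, axis=1) if cols and n_w else np.zeros((n_w, len(columns)))
        labels = ws.sensor_labels
        split = ws.split
        row_channels = None

    if standardize and X.shape[0]:
        X = _standardize(X, split)
    return FeatureMatrix(
        X=X, columns=tuple(columns), labels=np.asarray(labels, dtype=np.int8),
        mode=mode, split=split, row_channels=row_channels,
    )
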