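"""Filtering, fixed-length window segmentation, vote labeling and splitting."""

from __future__ import annotations

from dataclasses import dataclass, field, replace as _replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as _sig

from mwppg.signal_synth import MultiChannelRecord


def butter_lowpass_sos(order: int, cutoff: float, fs: float) -> np.ndarray:
    """Butterworth low-pass design shared by the filter and its tests."""
    if cutoff >= fs / 2:
        raise ValueError("cutoff must lie below the Nyquist frequency")
    if order < 1:
        raise ValueError("order must be >= 1")
    return _sig.butter(order, cutoff, btype="low", fs=fs, output="sos")


def lowpass_filter(
    record: MultiChannelRecord, order: int = 5, cutoff: float = 10.0
) -> MultiChannelRecord:
    """Zero-phase (forward-backward) Butterworth low-pass on every channel.

    Labels are untouched; defaults are a 5th-order design with a 10 Hz cutoff.
    """
    sos = butter_lowpass_sos(order, cutoff, record.sample_rate)
    out = record.copy()
    for c in record.channel_names:
        x = record.samples[c]
        if x.size > 3 * (2 * order + 1):
            out.samples[c] = _sig.sosfiltfilt(sos, x)
    return out


@dataclass
class WindowSet:
    """Fixed-length overlapped windows over one or more source records."""

    record_ids: np.ndarray  # per-window source record id
    starts: np.ndarray  # per-window start sample within its record
    window_samples: int
    overlap: float
    channel_labels: Dict[str, np.ndarray]
    channel_names: Tuple[str, ...]
    sample_rate: float
    split: Optional[np.ndarray] = None  # per-window 'train' | 'val' | 'test'

    @property
    def n_windows(self) -> int:
        return len(self.starts)

    @property
    def sensor_labels(self) -> np.ndarray:
        """Sensor-level label: OR over channel labels."""
        if self.n_windows == 0:
            return np.zeros(0, dtype=np.int8)
        stacked = np.stack([self.channel_labels[c] for c in self.channel_names])
        return stacked.max(axis=0).astype(np.int8)

    def subset(self, idx: np.ndarray) -> "WindowSet":
        return WindowSet(
            record_ids=self.record_ids[idx],
            starts=self.starts[idx],
            window_samples=self.window_samples,
            overlap=self.overlap,
            channel_labels={c: self.channel_labels[c][idx] for c in self.channel_names},
            channel_names=self.channel_names,
            sample_rate=self.sample_rate,
            split=self.split[idx] if self.split is not None else None,
        )


def concat_window_sets(sets: Sequence[WindowSet]) -> WindowSet:
    if not sets:
        raise ValueError("nothing to concatenate")
    first = sets[0]
    for ws in sets[1:]:
        if ws.window_samples != first.window_samples or ws.channel_names != first.channel_names:
            raise ValueError("window sets are incompatible")
    return WindowSet(
        record_ids=np.concatenate([ws.record_ids for ws in sets]),
        starts=np.concatenate([ws.starts for ws in sets]),
        window_samples=first.window_samples,
        overlap=first.overlap,
        channel_labels={
            c: np.concatenate([ws.channel_labels[c] for ws in sets])
            for c in first.channel_names
        },
        channel_names=first.channel_names,
        sample_rate=first.sample_rate,
        split=(
            np.concatenate([ws.split for ws in sets])
            if all(ws.split is not None for ws in sets)
            else None
        ),
    )


def vote_label(
    sample_labels: Sequence[int],
    weights: Optional[Sequence[float]] = None,
    threshold: Optional[float] = None,
    alpha: float = 0.2,
) -> int:
    """Weighted vote over per-sample labels: 1 iff sum(w_i * l_i) >= m.

    Defaults: unit weights and ``m = ceil(alpha * n)``, so the required count
    of anomalous samples grows with window size.
    """
    labels = np.asarray(sample_labels, dtype=float)
    n = labels.size
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.size != n:
            raise ValueError("weights and labels must have equal length")
    m = float(np.ceil(alpha * n)) if threshold is None else float(threshold)
    return int(np.dot(w, labels) >= m)


def segment_windows(
    record: MultiChannelRecord,
    window_s: float,
    overlap: float = 0.5,
    alpha: float = 0.2,
) -> WindowSet:
    """Segment a record into fixed windows with the given overlap fraction.

    Start offsets form the arithmetic progression 0, step, 2*step, ... with
    ``step = round(window_samples * (1 - overlap))``; a trailing partial
    window is discarded.  Per-window channel labels come from the default
    :func:`vote_label` with anomalous fraction ``alpha``.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must lie in [0, 1)")
    w = int(round(window_s * record.sample_rate))
    step = max(1, int(round(w * (1.0 - overlap))))
    n = record.n_samples
    count = (n - w) // step + 1 if n >= w else 0
    starts = np.arange(count) * step

    m = float(np.ceil(alpha * w))
    channel_labels: Dict[str, np.ndarray] = {}
    for c in record.channel_names:
        lab = np.asarray(record.labels[c])
        if count:
            idx = starts[:, None] + np.arange(w)[None, :]
            sums = lab[idx].sum(axis=1)
            channel_labels[c] = (sums >= m).astype(np.int8)
        else:
            channel_labels[c] = np.zeros(0, dtype=np.int8)

    return WindowSet(
        record_ids=np.array([record.record_id] * count, dtype=object),
        starts=starts,
        window_samples=w,
        overlap=overlap,
        channel_labels=channel_labels,
        channel_names=record.channel_names,
        sample_rate=record.sample_rate,
    )


def split_windows(
    ws: WindowSet,
    fractions: Tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
    by_record: bool = True,
) -> Tuple[WindowSet, WindowSet, WindowSet]:
    """Split windows into train/validation/test sets.

    By default whole source records are assigned to one split (overlapping
    windows never straddle splits); ``by_record=False`` shuffles individual
    windows instead.  Fractions must sum to 1.
    """
    if abs(sum(fractions) - 1.0) > 1e-9 or any(f < 0 for f in fractions):
        raise ValueError("fractions must be non-negative and sum to 1")
    n = ws.n_windows
    rng = np.random.default_rng(seed)
    assignment = np.empty(n, dtype=object)

    if by_record:
        unique_ids = list(dict.fromkeys(ws.record_ids.tolist()))
        order = rng.permutation(len(unique_ids))
        targets = np.array(fractions) * n
        filled = np.zeros(3)
        names = ("train", "val", "test")
        for j in order:
            rid = unique_ids[j]
            mask = ws.record_ids == rid
            # assign to the split with the largest remaining deficit
            with np.errstate(divide="ignore", invalid="ignore"):
                deficit = targets - filled
            k = int(np.argmax(np.where(targets > 0, deficit / np.maximum(targets, 1e-12), -np.inf)))
            assignment[mask] = names[k]
            filled[k] += mask.sum()
    else:
        order = rng.permutation(n)
        n_test = int(round(fractions[2] * n))
        n_val = int(round(fractions[1] * n))
        assignment[order[: n - n_val - n_test]] = "train"
        assignment[order[n - n_val - n_test : n - n_test]] = "val"
        assignment[order[n - n_test :]] = "test"

    out = _replace(ws, split=assignment)
    idx_train = np.where(assignment == "train")[0]
    idx_val = np.where(assignment == "val")[0]
    idx_test = np.where(assignment == "test")[0]
    return out.subset(idx_train), out.subset(idx_val), out.subset(idx_test)


def assign_split(
    ws: WindowSet,
    fractions: Tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
    by_record: bool = True,
) -> WindowSet:
    """Like :func:`split_windows` but returns one set with a split column."""
    train, val, test = split_windows(ws, fractions, seed, by_record)
    merged = concat_window_sets([train, val, test])
    return merged
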