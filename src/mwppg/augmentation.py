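"""Channel-level augmentation operators: shift, scale, warp, drift, noise, dropout.

Every operator preserves series length.  ``apply_augmenter`` also reports a
per-sample modified mask (samples whose value changed), which callers may OR
into anomaly labels when the transform is meant to create a synthetic fault
rather than a natural variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np

from mwppg.signal_synth import MultiChannelRecord

AUGMENTER_KINDS = ("shift", "scale", "warp", "drift", "noise", "dropout")


class UnsupportedAugmenterError(ValueError):
    pass


class InvalidAugmenterSpec(ValueError):
    pass


@dataclass
class AugmenterSpec:
    """One augmentation transform and its parameters.

    kind-specific fields:

    - ``shift``: ``shift`` (samples, circular).
    - ``scale``: ``scale`` (scalar or per-sample vector multiplier).
    - ``warp``: ``anchors`` (monotone (src, dst) index pairs) or ``n_knots``
      random knots with relative jitter ``warp_strength``.
    - ``drift``: ``coeffs`` — up to 5 polynomial coefficients (a0..a4) of a
      degree <= 4 polynomial evaluated on a normalized [0, 1] time grid.
    - ``noise``: ``sigma`` — Gaussian noise standard deviation.
    - ``dropout``: ``p`` — i.i.d. Bernoulli drop probability; ``fill`` value
      (float, or ``"hold"`` for last-value hold).

    ``label_as_anomaly`` marks whether :func:`augment_record` should OR the
    modified mask into the channel's anomaly labels.  Dropout defaults to
    anomalous; shift/scale/warp emulate natural variation and default clean;
    noise and drift count as anomalies only above magnitude thresholds.
    """

    kind: str
    shift: int = 0
    scale: Union[float, Sequence[float]] = 1.0
    anchors: Optional[Sequence[Tuple[float, float]]] = None
    n_knots: int = 3
    warp_strength: float = 0.2
    coeffs: Sequence[float] = (0.0,)
    sigma: float = 0.0
    p: float = 0.0
    fill: Union[float, str] = 0.0
    seed: Optional[int] = None
    label_as_anomaly: Optional[bool] = None
    # thresholds above which noise/drift default to "anomalous"
    noise_anomaly_sigma: float = np.inf
    drift_anomaly_amp: float = np.inf

    def validate(self) -> None:
        if self.kind not in AUGMENTER_KINDS:
            raise UnsupportedAugmenterError(f"unknown augmenter kind {self.kind!r}")
        if not 0.0 <= self.p <= 1.0:
            raise InvalidAugmenterSpec("dropout probability must lie in [0, 1]")
        if len(tuple(self.coeffs)) > 5:
            raise InvalidAugmenterSpec("drift polynomial degree must be <= 4")
        if self.anchors is not None:
            src = [a[0] for a in self.anchors]
            dst = [a[1] for a in self.anchors]
            if sorted(src) != list(src) or sorted(dst) != list(dst):
                raise InvalidAugmenterSpec("warp anchors must be monotone")

    def is_anomaly(self) -> bool:
        if self.label_as_anomaly is not None:
            return self.label_as_anomaly
        if self.kind == "dropout":
            return True
        if self.kind == "noise":
            return self.sigma >= self.noise_anomaly_sigma
        if self.kind == "drift":
            amp = float(np.abs(np.asarray(self.coeffs)).sum())
            return amp >= self.drift_anomaly_amp
        return False


def _warp_map(spec: AugmenterSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Monotone piecewise-linear index map phi: [0, n-1] -> [0, n-1]."""
    if spec.anchors is not None:
        src = np.array([0.0] + [a[0] for a in spec.anchors] + [n - 1.0])
        dst = np.array([0.0] + [a[1] for a in spec.anchors] + [n - 1.0])
    else:
        k = spec.n_knots
        base = np.linspace(0, n - 1, k + 2)
        jitter = rng.uniform(-spec.warp_strength, spec.warp_strength, k)
        interior = base[1:-1] + jitter * (n - 1) / (k + 1)
        src = base
        dst = np.concatenate(([0.0], np.sort(interior), [n - 1.0]))
    if np.any(np.diff(src) < 0) or np.any(np.diff(dst) < 0):
        raise InvalidAugmenterSpec("warp anchors must be monotone")
    return np.interp(np.arange(n), src, dst)


def apply_augmenter(
    series: np.ndarray, spec: AugmenterSpec
) -> Tuple[np.ndarray, np.ndarray]:
    """Apply one augmenter to a single channel.

    Returns ``(augmented, modified_mask)``; output length always equals input
    length and the mask marks samples whose value changed.  Stochastic kinds
    (warp without anchors, noise, dropout) are reproducible per ``spec.seed``.
    """
    spec.validate()
    x = np.asarray(series, dtype=float)
    n = x.size
    if n == 0:
        return x.copy(), np.zeros(0, dtype=bool)
    rng = np.random.default_rng(spec.seed)

    if spec.kind == "shift":
        out = np.roll(x, -int(spec.shift))
    elif spec.kind == "scale":
        s = np.asarray(spec.scale, dtype=float)
        if s.ndim not in (0, 1):
            raise InvalidAugmenterSpec("scale must be scalar or 1-D")
        if s.ndim == 1 and s.size != n:
            raise InvalidAugmenterSpec("scale vector length must match series")
        out = x * s
    elif spec.kind == "warp":
        phi = _warp_map(spec, n, rng)
        out = np.interp(phi, np.arange(n), x)
    elif spec.kind == "drift":
        coeffs = np.zeros(5)
        c = np.asarray(tuple(spec.coeffs), dtype=float)
        coeffs[: c.size] = c
        t = np.linspace(0.0, 1.0, n) if n > 1 else np.zeros(1)
        out = x + np.polyval(coeffs[::-1], t)
    elif spec.kind == "noise":
        out = x + rng.normal(0.0, spec.sigma, n) if spec.sigma > 0 else x.copy()
    elif spec.kind == "dropout":
        out = x.copy()
        hit = rng.random(n) < spec.p
        if spec.fill == "hold":
            idx = np.where(~hit, np.arange(n), 0)
            np.maximum.accumulate(idx, out=idx)
            out = np.where(hit, x[idx], x)
        else:
            out[hit] = float(spec.fill)
    else:  # pragma: no cover
        raise UnsupportedAugmenterError(spec.kind)

    mask = out != x
    return out, mask


def augment_record(
    record: MultiChannelRecord, specs: Dict[str, Sequence[AugmenterSpec]]
) -> MultiChannelRecord:
    """Apply per-channel augmenter lists; other channels stay untouched.

    For specs whose :meth:`AugmenterSpec.is_anomaly` is true, the modified
    mask is OR-ed into that channel's labels.
    """
    unknown = set(specs) - set(record.channel_names)
    if unknown:
        raise ValueError(f"unknown channels: {sorted(unknown)}")
    out = record.copy()
    for channel, channel_specs in specs.items():
        for spec in channel_specs:
            augmented, mask = apply_augmenter(out.samples[channel], spec)
            out.samples[channel] = augmented
            if spec.is_anomaly():
                out.labels[channel] = np.where(mask, 1, out.labels[channel]).astype(np.int8)
    return out
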