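"""Synthetic three-channel PPG generation and labeled artifact injection.

Records carry green/red/infrared intensity channels sampled at a common rate
together with per-sample binary anomaly labels.  The clean waveform is a
beat-train of two smooth lobes (systolic pulse, dicrotic notch, diastolic
bump) riding on a channel-specific DC level, modulated by a slow respiratory
baseline.  Artifacts are injected as localized transformations whose exact
footprint (the set of samples whose value changed) becomes the ground-truth
label.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field, replace as _replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as _sig

CHANNELS: Tuple[str, ...] = ("green", "red", "ir")

#: Artifact kinds affecting a single sensor component by default.
SENSOR_KINDS = frozenset({"sensor_dropout", "sensor_clipping"})
#: Artifact kinds affecting all channels simultaneously by default.
GLOBAL_KINDS = frozenset({"motion", "ambient_light", "low_temperature"})
ARTIFACT_KINDS = frozenset(
    {"motion", "contact_force", "sensor_dropout", "sensor_clipping",
     "ambient_light", "low_temperature"}
)


class InvalidConfigError(ValueError):
    """Raised for configurations violating their invariants."""


class UnsupportedArtifactError(ValueError):
    """Raised when an :class:`ArtifactSpec` names an unknown kind."""


@dataclass(frozen=True)
class ChannelGain:
    """Per-channel intensity model: ``dc + ac * cardiac``."""

    dc: float
    ac: float


# Green carries the largest relative pulsatile modulation, red the smallest.
DEFAULT_CHANNEL_GAINS: Mapping[str, ChannelGain] = {
    "green": ChannelGain(dc=60_000.0, ac=3_000.0),
    "red": ChannelGain(dc=80_000.0, ac=800.0),
    "ir": ChannelGain(dc=70_000.0, ac=1_500.0),
}


@dataclass
class SynthConfig:
    """Parameters of the clean-signal generator.

    Defaults mirror the acquisition setup being emulated: 125 Hz sampling,
    18-bit full scale, heart rate 91.6 +/- 8.9 BPM and respiration
    0.172 +/- 0.08 Hz.
    """

    duration: float = 60.0
    sample_rate: float = 125.0
    heart_rate_mean: float = 91.6
    heart_rate_sd: float = 8.9
    respiration_mean: float = 0.172
    respiration_sd: float = 0.08
    beat_jitter_cv: float = 0.03
    respiration_amp_frac: float = 0.2
    channel_gains: Mapping[str, ChannelGain] = field(
        default_factory=lambda: dict(DEFAULT_CHANNEL_GAINS)
    )
    # Beat template: Gaussian lobe positions/widths as fractions of the beat
    # period; the diastolic bump trails the systolic peak by ``dicrotic_delay``
    # seconds and has ``dicrotic_amplitude`` relative height.
    systolic_frac: float = 0.22
    systolic_width_frac: float = 0.11
    dicrotic_amplitude: float = 0.3
    dicrotic_delay: float = 0.24
    dicrotic_width_frac: float = 0.14
    adc_bits: int = 18
    quantize: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.sample_rate <= 0:
            raise InvalidConfigError("sample_rate must be positive")
        if self.duration < 0:
            raise InvalidConfigError("duration must be non-negative")
        if self.heart_rate_mean <= 0 or self.respiration_mean <= 0:
            raise InvalidConfigError("rate means must be positive")
        for name, g in self.channel_gains.items():
            if g.ac >= g.dc:
                raise InvalidConfigError(
                    f"channel {name!r}: AC amplitude must stay below DC offset"
                )

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sample_rate))

    @property
    def full_scale(self) -> float:
        return float(2 ** self.adc_bits - 1)


@dataclass
class MultiChannelRecord:
    """Synchronized multi-channel samples with per-sample anomaly labels."""

    samples: Dict[str, np.ndarray]
    labels: Dict[str, np.ndarray]
    sample_rate: float
    channel_names: Tuple[str, ...] = CHANNELS
    metadata: dict = field(default_factory=dict)
    record_id: str = ""

    def __post_init__(self) -> None:
        lengths = {len(self.samples[c]) for c in self.channel_names}
        lengths |= {len(self.labels[c]) for c in self.channel_names}
        if len(lengths) > 1:
            raise ValueError("all channel/label arrays must share one length")
        for c in self.channel_names:
            lab = np.asarray(self.labels[c])
            if lab.size and not np.isin(lab, (0, 1)).all():
                raise ValueError("labels must be binary")

    @property
    def n_samples(self) -> int:
        return len(self.samples[self.channel_names[0]])

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate

    def copy(self) -> "MultiChannelRecord":
        return MultiChannelRecord(
            samples={c: self.samples[c].copy() for c in self.channel_names},
            labels={c: self.labels[c].copy() for c in self.channel_names},
            sample_rate=self.sample_rate,
            channel_names=self.channel_names,
            metadata=_copy.deepcopy(self.metadata),
            record_id=self.record_id,
        )


@dataclass
class ArtifactSpec:
    """One artifact injection: kind, channel mask, time window and strength.

    ``channels=None`` selects the kind's natural mask: sensor faults hit the
    green channel only, motion/environment kinds hit every channel.
    """

    kind: str
    onset: float
    duration: float
    magnitude: float = 1.0
    channels: Optional[Sequence[str]] = None
    params: dict = field(default_factory=dict)
    seed: Optional[int] = None

    def validate(self, record: MultiChannelRecord) -> Tuple[int, int, Tuple[str, ...]]:
        if self.kind not in ARTIFACT_KINDS:
            raise UnsupportedArtifactError(f"unknown artifact kind {self.kind!r}")
        if self.onset < 0 or self.magnitude < 0 or self.duration < 0:
            raise ValueError("onset, duration and magnitude must be non-negative")
        if self.onset + self.duration > record.duration + 1e-9:
            raise ValueError("artifact window extends past the end of the record")
        if self.channels is None:
            mask = ("green",) if self.kind in SENSOR_KINDS else record.channel_names
        else:
            mask = tuple(self.channels)
            unknown = set(mask) - set(record.channel_names)
            if unknown:
                raise ValueError(f"unknown channels in mask: {sorted(unknown)}")
        fs = record.sample_rate
        i0 = int(round(self.onset * fs))
        i1 = int(round((self.onset + self.duration) * fs))
        return i0, min(i1, record.n_samples), mask

    def manifest(self) -> dict:
        return {
            "kind": self.kind,
            "onset": self.onset,
            "duration": self.duration,
            "magnitude": self.magnitude,
            "channels": list(self.channels) if self.channels is not None else None,
            "params": dict(self.params),
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# Clean generation
# ---------------------------------------------------------------------------

def _draw_vitals(config: SynthConfig, rng: np.random.Generator) -> Tuple[float, float, float]:
    hr = config.heart_rate_mean
    if config.heart_rate_sd > 0:
        hr = float(np.clip(rng.normal(hr, config.heart_rate_sd), 40.0, 180.0))
    resp = config.respiration_mean
    if config.respiration_sd > 0:
        resp = float(np.clip(rng.normal(resp, config.respiration_sd), 0.05, 0.5))
    resp_phase = float(rng.uniform(0.0, 2.0 * np.pi))
    return hr, resp, resp_phase


def cardiac_waveform(
    config: SynthConfig, rng: Optional[np.random.Generator] = None
) -> Tuple[np.ndarray, float, float, float]:
    """Noise-free cardiac component on [0, ~1] plus the drawn vitals.

    Returns ``(cardiac, heart_rate_bpm, respiration_hz, respiration_phase)``.
    Sharing the generator with :func:`generate_clean_record` keeps the two
    views of the same record consistent.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    hr, resp, resp_phase = _draw_vitals(config, rng)
    n = config.n_samples
    fs = config.sample_rate
    out = np.zeros(n)
    if n == 0:
        return out, hr, resp, resp_phase

    mean_period = 60.0 / hr
    # Beat onsets with multiplicative interval jitter; overshoot one beat so
    # the final partial beat is still shaped.
    n_beats = int(np.ceil(config.duration / mean_period)) + 2
    jitter = 1.0 + config.beat_jitter_cv * rng.standard_normal(n_beats)
    periods = mean_period * np.clip(jitter, 0.5, 1.5)
    onsets = np.concatenate(([0.0], np.cumsum(periods)[:-1]))

    for onset, period in zip(onsets, periods):
        mu_s = onset + config.systolic_frac * period
        sig_s = config.systolic_width_frac * period
        mu_d = mu_s + config.dicrotic_delay * period / mean_period
        sig_d = config.dicrotic_width_frac * period
        lo = max(0, int((onset - 0.5 * period) * fs))
        hi = min(n, int((onset + 1.5 * period) * fs) + 1)
        if lo >= hi:
            continue
        t = np.arange(lo, hi) / fs
        out[lo:hi] += np.exp(-0.5 * ((t - mu_s) / sig_s) ** 2)
        out[lo:hi] += config.dicrotic_amplitude * np.exp(
            -0.5 * ((t - mu_d) / sig_d) ** 2
        )
    return out, hr, resp, resp_phase


def generate_clean_record(config: SynthConfig) -> MultiChannelRecord:
    """Generate an artifact-free record; all labels are zero.

    Each channel is ``dc + ac * cardiac + resp_amp * sin(2*pi*f_resp*t)``,
    optionally quantized to ``adc_bits``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    cardiac, hr, resp, resp_phase = cardiac_waveform(config, rng)
    n = config.n_samples
    t = np.arange(n) / config.sample_rate
    baseline = np.sin(2.0 * np.pi * resp * t + resp_phase)

    samples: Dict[str, np.ndarray] = {}
    labels: Dict[str, np.ndarray] = {}
    names = tuple(config.channel_gains)
    for name in names:
        g = config.channel_gains[name]
        x = g.dc + g.ac * cardiac + config.respiration_amp_frac * g.ac * baseline
        if config.quantize:
            x = np.clip(np.round(x), 0, config.full_scale)
        samples[name] = x
        labels[name] = np.zeros(n, dtype=np.int8)

    return MultiChannelRecord(
        samples=samples,
        labels=labels,
        sample_rate=config.sample_rate,
        channel_names=names,
        metadata={
            "seed": config.seed,
            "heart_rate_bpm": hr,
            "respiration_hz": resp,
            "full_scale": config.full_scale,
            "artifacts": [],
            "category": "clean",
        },
    )


# ---------------------------------------------------------------------------
# Artifact injection
# ---------------------------------------------------------------------------

def _lowpass_noise(rng: np.random.Generator, n: int, fs: float, cutoff: float = 8.0) -> np.ndarray:
    """Band-limited unit-variance noise (low-pass filtered white noise)."""
    w = rng.standard_normal(n)
    if n > 30 and cutoff < fs / 2:
        sos = _sig.butter(4, cutoff, btype="low", fs=fs, output="sos")
        w = _sig.sosfiltfilt(sos, w)
    sd = w.std()
    return w / sd if sd > 0 else w


def _segment_dc(x: np.ndarray) -> float:
    return float(np.mean(x))


def inject_artifact(record: MultiChannelRecord, spec: ArtifactSpec) -> MultiChannelRecord:
    """Return a new record with ``spec`` applied and labels updated.

    Exactly the samples whose value changed are labeled anomalous; everything
    outside the artifact window, and every unmasked channel, is bit-identical
    to the input.
    """
    i0, i1, mask = spec.validate(record)
    out = record.copy()
    rng = np.random.default_rng(record.metadata.get("seed", 0) if spec.seed is None else spec.seed)
    n_seg = i1 - i0
    if n_seg <= 0:
        out.metadata.setdefault("artifacts", []).append(spec.manifest())
        return out

    fs = record.sample_rate
    t_seg = np.arange(i0, i1) / fs

    if spec.kind == "motion":
        # One shared band-limited fluctuation, per-channel random gains:
        # multiplicative gamma_motion = exp(sigma_c * noise).
        shared = _lowpass_noise(rng, n_seg, fs, cutoff=spec.params.get("cutoff_hz", 8.0))
        for c in mask:
            sigma = 0.05 * spec.magnitude * rng.uniform(0.5, 1.5)
            out.samples[c][i0:i1] = record.samples[c][i0:i1] * np.exp(sigma * shared)
    elif spec.kind == "contact_force":
        factor = float(np.clip(1.0 - spec.magnitude, 0.0, 1.0))
        for c in mask:
            seg = record.samples[c][i0:i1]
            dc = _segment_dc(seg)
            out.samples[c][i0:i1] = dc + (seg - dc) * factor
    elif spec.kind == "sensor_dropout":
        p = float(spec.params.get("probability", 1.0))
        if not 0.0 <= p <= 1.0:
            raise ValueError("dropout probability must lie in [0, 1]")
        fill = spec.params.get("fill", 0.0)
        for c in mask:
            hit = rng.random(n_seg) < p
            seg = out.samples[c][i0:i1]
            if fill == "hold":
                idx = np.where(~hit, np.arange(n_seg), 0)
                np.maximum.accumulate(idx, out=idx)
                held = seg[idx]
                if hit[0]:
                    held[: np.argmin(hit) if not hit.all() else n_seg] = seg[0]
                seg[hit] = held[hit]
            else:
                seg[hit] = float(fill)
            out.samples[c][i0:i1] = seg
    elif spec.kind == "sensor_clipping":
        default_level = record.metadata.get("full_scale", np.inf)
        level = float(spec.params.get("clip_level", default_level))
        for c in mask:
            out.samples[c][i0:i1] = np.minimum(record.samples[c][i0:i1], level)
    elif spec.kind == "ambient_light":
        drift_freq = float(spec.params.get("drift_freq", 0.15))
        for c in mask:
            seg = record.samples[c][i0:i1]
            amp = spec.params.get("drift_amplitude")
            if amp is None:
                amp = 0.05 * spec.magnitude * _segment_dc(seg) * rng.uniform(0.5, 1.5)
            phase = rng.uniform(0.0, 2.0 * np.pi)
            drift = amp * (0.6 + 0.4 * np.sin(2.0 * np.pi * drift_freq * t_seg + phase))
            out.samples[c][i0:i1] = seg + drift
    elif spec.kind == "low_temperature":
        factor = float(np.clip(1.0 - spec.params.get("attenuation", spec.magnitude), 0.0, 1.0))
        for c in mask:
            seg = record.samples[c][i0:i1]
            dc = _segment_dc(seg)
            out.samples[c][i0:i1] = dc + (seg - dc) * factor
    else:  # pragma: no cover - guarded by validate()
        raise UnsupportedArtifactError(spec.kind)

    for c in mask:
        changed = out.samples[c][i0:i1] != record.samples[c][i0:i1]
        out.labels[c][i0:i1] = np.where(changed, 1, out.labels[c][i0:i1]).astype(np.int8)

    out.metadata.setdefault("artifacts", []).append(spec.manifest())
    return out


# ---------------------------------------------------------------------------
# Dataset composition
# ---------------------------------------------------------------------------

#: Measured per-category durations (minutes) of the dataset being emulated.
TABLE_COMPOSITION_MINUTES: Mapping[str, float] = {
    "clean": 150.0,
    "motion": 50.0,
    "contact_force": 30.0,
    "sensor": 10.0,
    "environment": 20.0,
}

CATEGORIES = tuple(TABLE_COMPOSITION_MINUTES)


def table_composition(total_seconds: float) -> Dict[str, float]:
    """Per-category durations (seconds) proportional to the reference mix."""
    total_ref = sum(TABLE_COMPOSITION_MINUTES.values())
    return {
        k: total_seconds * v / total_ref for k, v in TABLE_COMPOSITION_MINUTES.items()
    }


def _artifact_events(
    category: str,
    record: MultiChannelRecord,
    rng: np.random.Generator,
    density: float,
) -> List[ArtifactSpec]:
    """Plan artifact events covering roughly ``density`` of the record."""
    events: List[ArtifactSpec] = []
    dur = record.duration
    t = 0.0
    toggle = 0
    while t < dur - 2.0:
        ev_dur = float(rng.uniform(1.5, 4.0))
        gap = ev_dur * (1.0 - density) / max(density, 1e-6)
        onset = t + float(rng.uniform(0.3, 1.0))
        if onset + ev_dur > dur:
            break
        seed = int(rng.integers(0, 2**31 - 1))
        if category == "motion":
            events.append(ArtifactSpec("motion", onset, ev_dur,
                                       magnitude=float(rng.uniform(0.25, 1.0)), seed=seed))
        elif category == "contact_force":
            events.append(ArtifactSpec("contact_force", onset, ev_dur,
                                       magnitude=float(rng.uniform(0.35, 0.85)),
                                       channels=record.channel_names, seed=seed))
        elif category == "sensor":
            if toggle % 2 == 0:
                events.append(ArtifactSpec(
                    "sensor_dropout", onset, ev_dur,
                    params={"probability": float(rng.uniform(0.2, 0.9))}, seed=seed))
            else:
                i0 = int(onset * record.sample_rate)
                i1 = int((onset + ev_dur) * record.sample_rate)
                level = float(np.quantile(record.samples["green"][i0:i1],
                                          rng.uniform(0.4, 0.7)))
                events.append(ArtifactSpec(
                    "sensor_clipping", onset, ev_dur,
                    params={"clip_level": level}, seed=seed))
        elif category == "environment":
            if toggle % 2 == 0:
                events.append(ArtifactSpec("ambient_light", onset, ev_dur,
                                           magnitude=float(rng.uniform(0.3, 1.0)), seed=seed))
            else:
                events.append(ArtifactSpec("low_temperature", onset, ev_dur,
                                           magnitude=float(rng.uniform(0.5, 0.9)), seed=seed))
        toggle += 1
        t = onset + ev_dur + gap
    return events


def synth_dataset(
    composition: Optional[Mapping[str, float]] = None,
    config: Optional[SynthConfig] = None,
    record_seconds: float = 60.0,
    artifact_density: float = 0.45,
) -> List[MultiChannelRecord]:
    """Emit records whose per-category durations match ``composition``.

    ``composition`` maps category name (clean, motion, contact_force, sensor,
    environment) to a duration in seconds.  Artifact categories receive a
    clean base record plus injected events of the matching kinds covering
    roughly ``artifact_density`` of each record.  Deterministic for a fixed
    ``config.seed``.
    """
    if config is None:
        config = SynthConfig()
    if composition is None:
        composition = table_composition(config.duration)
    unknown = set(composition) - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown categories: {sorted(unknown)}")
    if any(v < 0 for v in composition.values()):
        raise ValueError("durations must be non-negative")

    master = np.random.SeedSequence(config.seed)
    records: List[MultiChannelRecord] = []
    idx = 0
    for category in CATEGORIES:
        remaining = float(composition.get(category, 0.0))
        while remaining > 1e-9:
            rec_dur = min(record_seconds, remaining)
            remaining -= rec_dur
            child = master.spawn(1)[0]
            rec_seed = int(child.generate_state(1)[0] % (2**31 - 1))
            cfg = _replace(config, duration=rec_dur, seed=rec_seed)
            rec = generate_clean_record(cfg)
            rec.record_id = f"rec{idx:04d}_{category}"
            rec.metadata["category"] = category
            if category != "clean":
                rng = np.random.default_rng(rec_seed + 1)
                for spec in _artifact_events(category, rec, rng, artifact_density):
                    rec = inject_artifact(rec, spec)
            records.append(rec)
            idx += 1
    return records
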