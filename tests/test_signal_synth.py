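import numpy as np
import pytest
from scipy.signal import find_peaks, welch

from mwppg.signal_synth import (
    ArtifactSpec,
    InvalidConfigError,
    MultiChannelRecord,
    SynthConfig,
    UnsupportedArtifactError,
    cardiac_waveform,
    generate_clean_record,
    inject_artifact,
    synth_dataset,
    table_composition,
)


class TestSynthConfig:
    def test_defaults_match_reference_vitals(self):
        cfg = SynthConfig()
        assert cfg.heart_rate_mean == 91.6
        assert cfg.heart_rate_sd == 8.9
        assert cfg.respiration_mean == 0.172
        assert cfg.respiration_sd == 0.08
        assert cfg.sample_rate == 125.0
        assert cfg.adc_bits == 18

    def test_invalid_sample_rate(self):
        with pytest.raises(InvalidConfigError):
            generate_clean_record(SynthConfig(duration=1.0, sample_rate=0.0))

    def test_ac_must_stay_below_dc(self):
        from mwppg.signal_synth import ChannelGain

        cfg = SynthConfig(channel_gains={"green": ChannelGain(dc=1.0, ac=2.0)})
        with pytest.raises(InvalidConfigError):
            cfg.validate()


class TestGenerateCleanRecord:
    def test_sample_count(self, clean_record_60s):
        assert clean_record_60s.n_samples == 7500
        for c in clean_record_60s.channel_names:
            assert len(clean_record_60s.samples[c]) == 7500
            assert not clean_record_60s.labels[c].any()

    def test_zero_duration_yields_empty_record(self):
        rec = generate_clean_record(SynthConfig(duration=0.0))
        assert rec.n_samples == 0
        assert all(rec.labels[c].size == 0 for c in rec.channel_names)

    def test_beat_count_matches_heart_rate(self):
        # oracle: strict local maxima of the noise-free cardiac component
        # above the diastolic bump amplitude
        cfg = SynthConfig(duration=60.0, heart_rate_mean=90.0, heart_rate_sd=0.0, seed=7)
        cardiac, hr, _, _ = cardiac_waveform(cfg)
        assert hr == 90.0
        peaks, _ = find_peaks(cardiac, height=cfg.dicrotic_amplitude + 0.05)
        assert abs(len(peaks) - 90) <= 1

    def test_spectral_peak_tracks_heart_rate(self):
        for seed in range(5):
            rec = generate_clean_record(SynthConfig(duration=60.0, seed=seed))
            hr_hz = rec.metadata["heart_rate_bpm"] / 60.0
            x = rec.samples["green"]
            f, p = welch(x - x.mean(), fs=rec.sample_rate, nperseg=4096)
            assert abs(f[np.argmax(p)] - hr_hz) <= 0.2

    def test_determinism(self):
        cfg = SynthConfig(duration=5.0, seed=11)
        a, b = generate_clean_record(cfg), generate_clean_record(cfg)
        for c in a.channel_names:
            np.testing.assert_array_equal(a.samples[c], b.samples[c])

    def test_green_has_largest_relative_modulation(self, clean_record_60s):
        rel = {
            c: np.ptp(clean_record_60s.samples[c]) / clean_record_60s.samples[c].mean()
            for c in clean_record_60s.channel_names
        }
        assert rel["green"] > rel["ir"] > rel["red"]

    def test_quantization_produces_integers_within_full_scale(self):
        rec = generate_clean_record(SynthConfig(duration=2.0, quantize=True, seed=0))
        x = rec.samples["green"]
        np.testing.assert_array_equal(x, np.round(x))
        assert x.max() <= 2**18 - 1


def _labeled_equals_modified(before, after):
    for c in before.channel_names:
        changed = before.samples[c] != after.samples[c]
        np.testing.assert_array_equal(after.labels[c].astype(bool), changed)


class TestInjectArtifact:
    @pytest.mark.parametrize(
        "spec",
        [
            ArtifactSpec("motion", onset=1.0, duration=3.0, magnitude=0.8, seed=5),
            ArtifactSpec("contact_force", onset=2.0, duration=2.0, magnitude=0.6),
            ArtifactSpec("sensor_dropout", onset=0.5, duration=2.0,
                         params={"probability": 0.5}, seed=5),
            ArtifactSpec("sensor_clipping", onset=1.0, duration=4.0,
                         params={"clip_level": 60_500.0}),
            ArtifactSpec("ambient_light", onset=0.0, duration=5.0, magnitude=0.9, seed=5),
            ArtifactSpec("low_temperature", onset=3.0, duration=2.0, magnitude=0.7),
        ],
        ids=lambda s: s.kind,
    )
    def test_label_bookkeeping_exact(self, short_record, spec):
        out = inject_artifact(short_record, spec)
        _labeled_equals_modified(short_record, out)

    def test_dropout_probability_one_masks_span(self, short_record):
        spec = ArtifactSpec("sensor_dropout", onset=2.0, duration=2.0,
                            channels=("green",), params={"probability": 1.0})
        out = inject_artifact(short_record, spec)
        fs = short_record.sample_rate
        i0, i1 = int(2 * fs), int(4 * fs)
        assert (out.samples["green"][i0:i1] == 0.0).all()
        assert out.labels["green"][i0:i1].all()
        np.testing.assert_array_equal(out.samples["red"], short_record.samples["red"])
        np.testing.assert_array_equal(out.samples["ir"], short_record.samples["ir"])
        assert not out.labels["red"].any() and not out.labels["ir"].any()

    def test_outside_window_bit_identical(self, short_record):
        spec = ArtifactSpec("motion", onset=4.0, duration=2.0, magnitude=1.0, seed=1)
        out = inject_artifact(short_record, spec)
        fs = short_record.sample_rate
        i0, i1 = int(4 * fs), int(6 * fs)
        for c in short_record.channel_names:
            np.testing.assert_array_equal(out.samples[c][:i0], short_record.samples[c][:i0])
            np.testing.assert_array_equal(out.samples[c][i1:], short_record.samples[c][i1:])

    def test_zero_magnitude_motion_is_identity(self, short_record):
        spec = ArtifactSpec("motion", onset=1.0, duration=2.0, magnitude=0.0, seed=2)
        out = inject_artifact(short_record, spec)
        for c in short_record.channel_names:
            np.testing.assert_array_equal(out.samples[c], short_record.samples[c])
            assert not out.labels[c].any()

    def test_clipping_idempotent(self, short_record):
        spec = ArtifactSpec("sensor_clipping", onset=1.0, duration=4.0,
                            channels=("green",), params={"clip_level": 60_200.0})
        once = inject_artifact(short_record, spec)
        twice = inject_artifact(once, spec)
        np.testing.assert_array_equal(once.samples["green"], twice.samples["green"])

    def test_clipping_creates_plateau_at_level(self, short_record):
        level = float(np.quantile(short_record.samples["green"], 0.5))
        spec = ArtifactSpec("sensor_clipping", onset=0.0, duration=10.0,
                            channels=("green",), params={"clip_level": level})
        out = inject_artifact(short_record, spec)
        assert out.samples["green"].max() == level
        # other channels keep their pulsatile excursions
        assert np.ptp(out.samples["red"]) == np.ptp(short_record.samples["red"])

    def test_window_outside_record_raises(self, short_record):
        with pytest.raises(ValueError):
            inject_artifact(short_record, ArtifactSpec("motion", onset=9.0, duration=2.0))

    def test_unknown_kind_raises(self, short_record):
        with pytest.raises(UnsupportedArtifactError):
            inject_artifact(short_record, ArtifactSpec("gremlins", onset=0.0, duration=1.0))

    def test_unknown_channel_raises(self, short_record):
        with pytest.raises(ValueError):
            inject_artifact(
                short_record,
                ArtifactSpec("motion", onset=0.0, duration=1.0, channels=("uv",)),
            )


class TestSynthDataset:
    def test_table_proportions(self):
        comp = table_composition(600.0)
        assert comp["clean"] == pytest.approx(600 * 150 / 260)
        assert comp["motion"] == pytest.approx(600 * 50 / 260)
        assert comp["sensor"] == pytest.approx(600 * 10 / 260)

    def test_category_durations_match_composition(self):
        comp = table_composition(600.0)
        records = synth_dataset(comp, SynthConfig(seed=4))
        got = {}
        for r in records:
            got[r.metadata["category"]] = got.get(r.metadata["category"], 0.0) + r.duration
        for cat, want in comp.items():
            assert got[cat] == pytest.approx(want, abs=1.0)

    def test_single_clean_record(self):
        records = synth_dataset({"clean": 60.0}, SynthConfig(seed=0))
        assert len(records) == 1
        rec = records[0]
        assert rec.metadata["category"] == "clean"
        assert all(not rec.labels[c].any() for c in rec.channel_names)

    def test_sensor_artifacts_on_green_only(self):
        records = synth_dataset({"sensor": 120.0}, SynthConfig(seed=9))
        assert any(r.labels["green"].any() for r in records)
        for r in records:
            assert not r.labels["red"].any()
            assert not r.labels["ir"].any()

    def test_empty_composition(self):
        assert synth_dataset({}, SynthConfig(seed=0)) == []

    def test_determinism(self):
        a = synth_dataset({"motion": 90.0}, SynthConfig(seed=21))
        b = synth_dataset({"motion": 90.0}, SynthConfig(seed=21))
        for ra, rb in zip(a, b):
            for c in ra.channel_names:
                np.testing.assert_array_equal(ra.samples[c], rb.samples[c])
                np.testing.assert_array_equal(ra.labels[c], rb.labels[c])

    def test_unknown_category_raises(self):
        with pytest.raises(ValueError):
            synth_dataset({"cosmic_rays": 10.0}, SynthConfig(seed=0))


class TestMultiChannelRecord:
    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            MultiChannelRecord(
                samples={"green": np.zeros(5), "red": np.zeros(4), "ir": np.zeros(5)},
                labels={c: np.zeros(5, dtype=np.int8) for c in ("green", "red", "ir")},
                sample_rate=125.0,
            )

    def test_nonbinary_labels_rejected(self):
        labels = {c: np.zeros(5, dtype=np.int8) for c in ("green", "red", "ir")}
        labels["green"] = np.array([0, 1, 2, 0, 0])
        with pytest.raises(ValueError):
            MultiChannelRecord(
                samples={c: np.zeros(5) for c in ("green", "red", "ir")},
                labels=labels,
                sample_rate=125.0,
            )
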