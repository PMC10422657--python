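import numpy as np
import pytest

from mwppg.features import (
    FeatureDef,
    FeatureSetSpec,
    UnknownFeatureError,
    compute_feature,
    custom_feature_set,
    detect_peaks,
    extract_features,
    feat_binned_entropy,
    feat_frequency_bands_slope,
    feat_median_diff,
    feat_neg_turning_points,
    feat_pos_turning_points,
    feat_wavelet_entropy,
    register_feature,
    tsfel_feature_set,
    tsfresh_feature_set,
)
from mwppg.signal_synth import SynthConfig, generate_clean_record
from mwppg.windowing import assign_split, lowpass_filter, segment_windows

FS = 125.0
ALL_FEATURES = tuple(custom_feature_set().feature_names)


def _bumps(amplitudes, spacing_s=0.6, fs=FS, width_s=0.05):
    """Signal of Gaussian bumps with the given peak amplitudes."""
    n = int((len(amplitudes) + 1) * spacing_s * fs)
    t = np.arange(n) / fs
    x = np.zeros(n)
    for i, a in enumerate(amplitudes):
        mu = (i + 1) * spacing_s
        x += a * np.exp(-0.5 * ((t - mu) / width_s) ** 2)
    return x


class TestDetectPeaks:
    def test_constant_window(self):
        idx, amps, widths = detect_peaks(np.full(500, 2.0), FS)
        assert idx.size == 0

    def test_sinusoid_peak_count(self):
        t = np.arange(int(6 * FS)) / FS
        idx, _, _ = detect_peaks(np.sin(2 * np.pi * 1.5 * t), FS)
        assert idx.size == 9  # 1.5 peaks/s x 6 s, boundary-checked

    def test_close_peaks_suppressed(self):
        # 0.2 s apart < min distance 60/180 = 0.333 s: keep the larger only
        t = np.arange(int(2.5 * FS)) / FS
        x = np.exp(-0.5 * ((t - 1.0) / 0.05) ** 2)
        x += 0.6 * np.exp(-0.5 * ((t - 1.2) / 0.05) ** 2)
        idx, amps, _ = detect_peaks(x, FS, hr_max_bpm=180.0)
        assert idx.size == 1
        assert amps[0] == pytest.approx(1.0, rel=0.05)

    def test_prominence_gate(self):
        t = np.arange(int(4 * FS)) / FS
        x = np.sin(2 * np.pi * 1.0 * t) + 0.01 * np.sin(2 * np.pi * 20.0 * t)
        idx, _, _ = detect_peaks(x, FS, prominence_frac=0.1)
        assert idx.size == 4


class TestProposedFeatures:
    def test_peak_var_of_1_2_3(self):
        x = _bumps([1.0, 2.0, 3.0])
        assert compute_feature("peak_var", x, FS) == pytest.approx(1.0, rel=0.02)

    def test_identical_peaks_zero_variances(self):
        t = np.arange(int(6 * FS)) / FS
        x = np.sin(2 * np.pi * 1.5 * t)
        # off-grid sampling of the peak leaves residual variance ~1e-3
        assert compute_feature("peak_var", x, FS) == pytest.approx(0.0, abs=1e-2)
        assert compute_feature("peak_width_var", x, FS) == pytest.approx(0.0, abs=1e-2)

    def test_fewer_than_two_peaks_zero_variance(self):
        x = _bumps([1.0])
        assert compute_feature("peak_var", x, FS) == 0.0
        assert compute_feature("peak_width_var", x, FS) == 0.0

    def test_slope_separates_clean_from_noise(self):
        t = np.arange(int(6 * FS)) / FS
        clean = np.sin(2 * np.pi * 1.5 * t)
        noise = np.random.default_rng(5).standard_normal(t.size)
        noise *= clean.std() / noise.std()
        assert feat_frequency_bands_slope(clean, FS) > feat_frequency_bands_slope(noise, FS)

    def test_psd_mean_nonnegative(self):
        x = np.random.default_rng(0).standard_normal(750)
        assert compute_feature("PSD_mean", x, FS) >= 0.0


class TestLibraryFeatures:
    def test_monotone_ramp(self):
        x = np.arange(0.0, 10.0, 0.25)
        assert feat_pos_turning_points(x) == 0
        assert feat_neg_turning_points(x) == 0
        assert feat_median_diff(x) == pytest.approx(0.25)

    def test_alternating_turning_points(self):
        n = 100
        x = np.tile([0.0, 1.0], n // 2)
        total = feat_pos_turning_points(x) + feat_neg_turning_points(x)
        assert total == n - 2

    def test_binned_entropy_uniform_fill(self):
        x = np.arange(100.0)  # 10 samples in each of 10 equal-width bins
        assert feat_binned_entropy(x, bins=10) == pytest.approx(np.log(10), abs=1e-6)

    def test_degenerate_window(self):
        x = np.full(100, 3.0)
        assert feat_binned_entropy(x) == 0.0
        assert feat_wavelet_entropy(x) == 0.0
        assert feat_median_diff(x) == 0.0

    def test_wavelet_entropy_bounded_by_log_scales(self):
        x = np.random.default_rng(1).standard_normal(750)
        assert 0.0 < feat_wavelet_entropy(x) <= np.log(9) + 1e-9


class TestFeatureInvariances:
    @pytest.mark.parametrize("name", ALL_FEATURES)
    def test_offset_invariance(self, name):
        x = generate_clean_record(SynthConfig(duration=6.0, seed=2)).samples["green"]
        x = (x - x.mean()) / x.std()
        a = compute_feature(name, x, FS)
        b = compute_feature(name, x + 100.0, FS)
        assert a == pytest.approx(b, rel=1e-6, abs=1e-9)

    def test_scaling_laws(self):
        x = generate_clean_record(SynthConfig(duration=6.0, seed=4)).samples["green"]
        c = 3.0
        assert compute_feature("peak_var", c * x, FS) == pytest.approx(
            c**2 * compute_feature("peak_var", x, FS), rel=1e-9
        )
        for name in ("pos_turning_points", "neg_turning_points", "num_of_peaks",
                     "binned_entropy"):
            assert compute_feature(name, c * x, FS) == pytest.approx(
                compute_feature(name, x, FS)
            )


class TestFeatureSetSpecs:
    def test_custom_counts(self):
        spec = custom_feature_set()
        assert spec.n_features == 10
        assert spec.n_attributes == 16

    def test_tsfel_counts(self):
        spec = tsfel_feature_set()
        assert spec.n_features == 15
        assert spec.n_attributes == 21

    def test_tsfresh_counts(self):
        spec = tsfresh_feature_set()
        assert spec.n_features == 13
        assert spec.n_attributes == 21

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError):
            FeatureSetSpec(
                "bad",
                (FeatureDef("a", ("green",)), FeatureDef("a", ("red",))),
            )

    def test_empty_assignment_rejected(self):
        with pytest.raises(ValueError):
            FeatureSetSpec("bad", (FeatureDef("a", ()),))

    def test_attribute_names_channel_qualified(self):
        spec = custom_feature_set()
        assert "peak_var__red" in spec.attribute_names
        assert "wavelet_entropy__green" in spec.attribute_names


@pytest.fixture(scope="module")
def windows():
    rec = lowpass_filter(generate_clean_record(SynthConfig(duration=20.0, seed=6)))
    rec.record_id = "r0"
    ws = assign_split(segment_windows(rec, 2.0), seed=0)
    return ws, rec


class TestExtractFeatures:

    def test_sensor_mode_16_columns(self, windows):
        ws, rec = windows
        fm = extract_features(ws, rec, custom_feature_set(), mode="sensor")
        assert fm.X.shape == (ws.n_windows, 16)
        assert fm.columns == custom_feature_set().attribute_names

    def test_channel_mode_10_columns(self, windows):
        ws, rec = windows
        fm = extract_features(ws, rec, custom_feature_set(), mode="channel")
        assert fm.X.shape == (3 * ws.n_windows, 10)
        assert fm.columns == custom_feature_set().feature_names

    def test_empty_window_set_keeps_schema(self, windows):
        ws, rec = windows
        empty = ws.subset(np.array([], dtype=int))
        fm = extract_features(empty, rec, custom_feature_set(), mode="sensor")
        assert fm.X.shape == (0, 16)
        assert fm.columns == custom_feature_set().attribute_names

    def test_column_count_follows_assignments(self, windows):
        ws, rec = windows
        spec = FeatureSetSpec(
            "tiny",
            (
                FeatureDef("median_diff", ("green", "ir")),
                FeatureDef("binned_entropy", ("red",)),
            ),
        )
        fm = extract_features(ws, rec, spec, mode="sensor")
        assert fm.X.shape[1] == spec.n_attributes == 3

    def test_standardized_train_stats(self, windows):
        ws, rec = windows
        fm = extract_features(ws, rec, custom_feature_set(), mode="sensor")
        train = fm.X[fm.split == "train"]
        varying = train.std(axis=0) > 1e-12
        np.testing.assert_allclose(train.mean(axis=0)[varying], 0.0, atol=1e-9)

    def test_unknown_feature_raises(self, windows):
        ws, rec = windows
        with pytest.raises(UnknownFeatureError):
            extract_features(ws, rec, tsfel_feature_set(), mode="sensor")

    def test_plugin_registration(self, windows):
        ws, rec = windows
        register_feature("row_mean", lambda x, fs, **kw: float(np.mean(x)))
        spec = FeatureSetSpec("plug", (FeatureDef("row_mean", ("green",)),))
        fm = extract_features(ws, rec, spec, mode="sensor", standardize=False)
        assert fm.X.shape == (ws.n_windows, 1)
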