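# mwppg

Synthetic multi-wavelength photoplethysmography (MW-PPG) generation and
lightweight anomaly detection.

The package implements a complete, self-contained pipeline for artifact
detection in three-channel (green/red/infrared) PPG time series sampled at
125 Hz:

- **`mwppg.signal_synth`** — clean MW-PPG generation (systolic peak, dicrotic
  notch, diastolic bump, respiratory baseline; heart rate 91.6 ± 8.9 BPM,
  respiration 0.172 ± 0.08 Hz by default) and injection of six artifact kinds
  (motion, contact force, sensor dropout, sensor clipping, ambient light,
  low temperature) with exact per-sample ground-truth labels.
- **`mwppg.augmentation`** — the six channel-level augmenters (shift, scale,
  warp, 4th-degree polynomial drift, Gaussian noise, Bernoulli dropout), all
  length-preserving, with per-sample modified masks.
- **`mwppg.windowing`** — zero-phase 5th-order Butterworth low-pass
  pre-filtering (10 Hz cutoff), fixed-length window segmentation with
  configurable overlap (50 % default), weighted-vote window labeling, and
  train/validation/test splitting (80/10/10; whole-record grouping by default
  with a paper-style per-window mode).
- **`mwppg.features`** — the ten-feature custom set (peak count/variance/width
  variance, mean PSD band power, frequency-bands slope, turning points,
  binned entropy, Ricker-CWT wavelet entropy, median difference), plus
  encodings of the retained TSFEL/tsfresh sets with their per-feature channel
  assignments; channel-level (10 columns) and sensor-level (16 columns)
  matrix assembly with train-statistic standardization.
- **`mwppg.selection`** — information-gain ranking (equal-frequency
  discretization, bits), per-feature channel aggregation, random-forest-based
  backward RFE with a 2.5 % F1 tolerance, and greedy best-first forward
  selection.
- **`mwppg.detect_eval`** — decision tree, random forest, SVM and a
  reconstruction autoencoder (four dense layers, 5-neuron hidden width,
  normal-only training, validation-calibrated MSE threshold), evaluated at
  channel and sensor level across window sizes of 2–10 s, including the
  sensor-minus-channel gain tables.

## Tests

```bash
python -m pytest -q tests/
```

The suite includes unit tests per module, hypothesis property tests for the
core invariants, and `tests/test_acceptance.py`, which runs the acceptance
criteria (conformance counts, oracle equivalences, closed-form checks,
generator/augmenter fidelity, and a ~30-minute end-to-end synthetic recovery
experiment; the whole suite takes a couple of minutes on one CPU).

## CLI

```bash
# synthesize a labeled dataset (CSV records + JSON sidecars)
mwppg synth --duration 600 --seed 1 --out data/

# per-channel augmentation
mwppg augment --in data/rec0000_clean.csv --specs specs.json --out out.csv

# windowing manifest
mwppg windows --in data/ --size 6 --overlap 0.5 --alpha 0.2 --out windows.csv

# feature extraction (custom set, sensor-level)
mwppg extract --in data/ --set custom --mode sensor --out features.csv

# information-gain ranking + RFE
mwppg select --features features.csv --tol 0.025 --out ranked.csv

# full detector sweep
mwppg experiment --in data/ --windows 2,4,6,8,10 --modes channel,sensor \
    --detectors dt,rf,svm,ae --out report.json
```

## File formats

- Record CSV: `time,green,red,ir,label_green,label_red,label_ir`, one row per
  sample, with a `<name>.csv.json` sidecar carrying sample rate, seed and the
  artifact manifest.
- Window manifest CSV: `record_id,start_sample,window_samples,label_green,
  label_red,label_ir,label_sensor,split`.
- Feature matrix CSV: `feature__channel` columns plus `label` and `split`.
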