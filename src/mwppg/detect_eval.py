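"""Lightweight detectors (DT, RF, SVM, reconstruction autoencoder) and the
window-size / detection-mode evaluation sweep."""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace as _replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from mwppg.features import FeatureMatrix, FeatureSetSpec, custom_feature_set, extract_features, feature_table
from mwppg.signal_synth import MultiChannelRecord
from mwppg.windowing import concat_window_sets, lowpass_filter, segment_windows, split_windows

DETECTOR_KINDS = ("decision_tree", "random_forest", "svm", "autoencoder")

_KIND_ALIASES = {
    "dt": "decision_tree",
    "rf": "random_forest",
    "svm": "svm",
    "ae": "autoencoder",
}

#: Default hyperparameters of the four detectors.
DEFAULT_HYPERPARAMETERS: Mapping[str, Mapping[str, object]] = {
    "decision_tree": {"criterion": "gini", "max_depth": 15},
    "random_forest": {"criterion": "gini", "max_depth": 10, "n_estimators": 10},
    # feature_scale maps z-scored features onto the intensity-like scale the
    # stated gamma presupposes (effective RBF width gamma * scale**2).
    "svm": {"kernel": "rbf", "gamma": 1e-4, "C": 1.0, "probability": True,
            "feature_scale": 50.0},
    # full-batch (lbfgs) training to a fixed iteration budget; a few random
    # restarts are scored on validation F1 and the best kept.
    "autoencoder": {"hidden_layer_sizes": (5, 5, 5), "activation": "relu",
                    "epochs": 500, "solver": "lbfgs", "restarts": 3},
}


@dataclass
class DetectorConfig:
    """Detector kind plus hyperparameter overrides."""

    kind: str
    params: Dict[str, object] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        self.kind = _KIND_ALIASES.get(self.kind, self.kind)
        if self.kind not in DETECTOR_KINDS:
            raise ValueError(f"unknown detector kind {self.kind!r}")

    def resolved_params(self) -> Dict[str, object]:
        merged = dict(DEFAULT_HYPERPARAMETERS[self.kind])
        merged.update(self.params)
        return merged


@dataclass
class DetectorModel:
    kind: str
    columns: Tuple[str, ...]
    estimator: object
    threshold: Optional[float] = None  # autoencoder only
    feature_scale: float = 1.0  # svm only


def _reconstruction_errors(est: MLPRegressor, X: np.ndarray) -> np.ndarray:
    recon = est.predict(X)
    if recon.ndim == 1:
        recon = recon[:, None]
    return np.mean((recon - X) ** 2, axis=1)


def _best_threshold(errors: np.ndarray, labels: np.ndarray) -> float:
    """Threshold on reconstruction error maximizing F1 on validation."""
    if errors.size == 0 or labels.max(initial=0) == 0:
        return float(errors.max() + 1e-9) if errors.size else np.inf
    order = np.argsort(errors)
    e, y = errors[order], labels[order]
    # predicting 1 for error >= threshold; candidate thresholds between points
    candidates = np.concatenate(([e[0] - 1e-12], (e[:-1] + e[1:]) / 2, [e[-1] + 1e-12]))
    total_pos = y.sum()
    best_f1, best_thr = -1.0, candidates[-1]
    for thr in candidates:
        pred = e >= thr
        tp = int(np.sum(pred & (y == 1)))
        fp = int(np.sum(pred & (y == 0)))
        fn = int(total_pos - tp)
        f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
        if f1 > best_f1:
            best_f1, best_thr = f1, float(thr)
    return best_thr


def train_detector(
    cfg: DetectorConfig,
    train: FeatureMatrix,
    val: Optional[FeatureMatrix] = None,
) -> DetectorModel:
    """Fit one detector.

    Supervised kinds fit on the train labels and require both classes.  The
    autoencoder fits its reconstruction on normal-labeled train rows only and
    calibrates a mean-squared-error threshold on the validation split to
    maximize F1.
    """
    if train.n_rows == 0:
        raise ValueError("empty training matrix")
    params = cfg.resolved_params()
    if cfg.kind == "autoencoder":
        normal = train.X[train.labels == 0]
        if normal.shape[0] == 0:
            raise ValueError("autoencoder requires normal-labeled training rows")
        have_val = val is not None and val.n_rows > 0
        restarts = int(params["restarts"]) if have_val else 1
        best: Optional[Tuple[float, MLPRegressor, float]] = None
        for k in range(restarts):
            est = MLPRegressor(
                hidden_layer_sizes=params["hidden_layer_sizes"],
                activation=params["activation"],
                solver=params["solver"],
                max_iter=int(params["epochs"]),
                random_state=cfg.seed + 1000 * k,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est.fit(normal, normal)
            if have_val:
                errs = _reconstruction_errors(est, val.X)
                thr = _best_threshold(errs, val.labels)
                f1 = evaluate((errs >= thr).astype(int), val.labels)["f1"]
            else:
                errs = _reconstruction_errors(est, normal)
                thr = float(np.quantile(errs, 0.99)) + 1e-12
                f1 = 0.0
            if best is None or f1 > best[0]:
                best = (f1, est, thr)
        _, est, thr = best
        return DetectorModel(cfg.kind, train.columns, est, threshold=thr)

    if np.unique(train.labels).size < 2:
        raise ValueError("supervised detectors need both classes in training data")
    if cfg.kind == "decision_tree":
        est = DecisionTreeClassifier(
            criterion=params["criterion"], max_depth=params["max_depth"],
            random_state=cfg.seed,
        )
    elif cfg.kind == "random_forest":
        est = RandomForestClassifier(
            criterion=params["criterion"], max_depth=params["max_depth"],
            n_estimators=params["n_estimators"], random_state=cfg.seed,
        )
    else:
        est = SVC(
            kernel=params["kernel"], gamma=params["gamma"], C=params["C"],
            probability=params["probability"], random_state=cfg.seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            est.fit(train.X * float(params["feature_scale"]), train.labels)
        return DetectorModel(cfg.kind, train.columns, est,
                             feature_scale=float(params["feature_scale"]))
    est.fit(train.X, train.labels)
    return DetectorModel(cfg.kind, train.columns, est)


def predict(model: DetectorModel, fm: FeatureMatrix) -> np.ndarray:
    """Binary predictions; the matrix schema must match training."""
    if tuple(fm.columns) != tuple(model.columns):
        raise ValueError(
            f"schema mismatch: model trained on {len(model.columns)} columns, "
            f"got {len(fm.columns)}"
        )
    if fm.n_rows == 0:
        return np.zeros(0, dtype=np.int8)
    if model.kind == "autoencoder":
        errs = _reconstruction_errors(model.estimator, fm.X)
        return (errs >= model.threshold).astype(np.int8)
    return np.asarray(
        model.estimator.predict(fm.X * model.feature_scale), dtype=np.int8
    )


def evaluate(pred: Sequence[int], truth: Sequence[int]) -> Dict[str, float]:
    """Accuracy and F1 (anomaly = positive class) from raw predictions."""
    p = np.asarray(pred, dtype=int)
    t = np.asarray(truth, dtype=int)
    if p.size != t.size:
        raise ValueError("prediction and truth must have equal length")
    if p.size == 0:
        return {"accuracy": 0.0, "f1": 0.0, "precision": 0.0, "recall": 0.0}
    acc = float(np.mean(p == t))
    tp = int(np.sum((p == 1) & (t == 1)))
    fp = int(np.sum((p == 1) & (t == 0)))
    fn = int(np.sum((p == 0) & (t == 1)))
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return {"accuracy": acc, "f1": float(f1), "precision": float(prec), "recall": float(rec)}


def save_model(model: DetectorModel, path) -> None:
    """Persist a fitted detector with a schema manifest."""
    import joblib

    joblib.dump(
        {
            "format_version": 1,
            "kind": model.kind,
            "columns": list(model.columns),
            "threshold": model.threshold,
            "feature_scale": model.feature_scale,
            "estimator": model.estimator,
        },
        path,
    )


def load_model(path) -> DetectorModel:
    import joblib

    blob = joblib.load(path)
    if blob.get("format_version") != 1:
        raise ValueError("unsupported model format version")
    return DetectorModel(
        kind=blob["kind"],
        columns=tuple(blob["columns"]),
        estimator=blob["estimator"],
        threshold=blob["threshold"],
        feature_scale=blob["feature_scale"],
    )


@dataclass
class EvalReport:
    """Accuracy/F1 per (window size, mode, detector) cell plus fusion gains."""

    results: Dict[Tuple[float, str, str], Dict[str, float]]
    feature_set: str

    def cell(self, window_s: float, mode: str, detector: str) -> Dict[str, float]:
        detector = _KIND_ALIASES.get(detector, detector)
        return self.results[(window_s, mode, detector)]

    def gains(self) -> Dict[Tuple[float, str], Dict[str, float]]:
        """Sensor-level minus channel-level metric gains per (window, detector)."""
        out: Dict[Tuple[float, str], Dict[str, float]] = {}
        for (w, mode, det), metrics in self.results.items():
            if mode != "sensor":
                continue
            chan = self.results.get((w, "channel", det))
            if chan is None:
                continue
            out[(w, det)] = {
                "accuracy_gain": metrics["accuracy"] - chan["accuracy"],
                "f1_gain": metrics["f1"] - chan["f1"],
            }
        return out

    def to_dict(self) -> dict:
        return {
            "feature_set": self.feature_set,
            "results": {
                f"{w}|{mode}|{det}": metrics
                for (w, mode, det), metrics in sorted(self.results.items())
            },
            "gains": {
                f"{w}|{det}": g for (w, det), g in sorted(self.gains().items())
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"window_s": w, "mode": mode, "detector": det, **metrics}
            for (w, mode, det), metrics in sorted(self.results.items())
        ]
        return pd.DataFrame(rows)


def run_experiment(
    records: Sequence[MultiChannelRecord],
    feature_set: Optional[FeatureSetSpec] = None,
    detectors: Sequence[str] = ("dt", "rf", "svm", "ae"),
    window_sizes: Sequence[float] = (2.0, 4.0, 6.0, 8.0, 10.0),
    modes: Sequence[str] = ("channel", "sensor"),
    seed: int = 0,
    overlap: float = 0.5,
    alpha: float = 0.2,
    fractions: Tuple[float, float, float] = (0.8, 0.1, 0.1),
    by_record: bool = True,
    apply_filter: bool = True,
) -> EvalReport:
    """Full sweep over window sizes, detection modes and detectors.

    For each window size the records are filtered, segmented, split (whole
    records per split by default), featurized once per channel, and every
    detector is trained on the train split and scored on the test split.
    Deterministic for a fixed seed.
    """
    if feature_set is None:
        feature_set = custom_feature_set()
    recs = [lowpass_filter(r) for r in records] if apply_filter else list(records)
    recmap = {r.record_id: r for r in recs}
    results: Dict[Tuple[float, str, str], Dict[str, float]] = {}

    for w_s in window_sizes:
        ws = concat_window_sets([segment_windows(r, w_s, overlap, alpha) for r in recs])
        train_ws, val_ws, test_ws = split_windows(ws, fractions, seed=seed, by_record=by_record)
        full = concat_window_sets([train_ws, val_ws, test_ws])
        table = feature_table(full, recmap, feature_set)
        for mode in modes:
            fm = extract_features(full, recmap, feature_set, mode=mode, table=table)
            fm_train = fm.rows("train")
            fm_val = fm.rows("val")
            fm_test = fm.rows("test")
            for det in detectors:
                cfg = DetectorConfig(det, seed=seed)
                model = train_detector(cfg, fm_train, fm_val)
                metrics = evaluate(predict(model, fm_test), fm_test.labels)
                results[(float(w_s), mode, cfg.kind)] = metrics
    return EvalReport(results=results, feature_set=feature_set.name)
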