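"""Information-gain ranking, channel aggregation, backward RFE and greedy
forward (best-first) feature selection."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold

from mwppg.features import FeatureDef, FeatureMatrix, FeatureSetSpec


# ---------------------------------------------------------------------------
# Information gain
# ---------------------------------------------------------------------------

def _entropy_bits(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-np.sum(p * np.log2(p)))


def _discretize(values: np.ndarray, bins: int) -> np.ndarray:
    """Equal-frequency binning; values with few distinct levels keep their
    own bins so discrete inputs are preserved exactly."""
    uniq, inverse = np.unique(values, return_inverse=True)
    if uniq.size <= bins:
        return inverse
    qs = np.quantile(values, np.linspace(0, 1, bins + 1)[1:-1])
    edges = np.unique(qs)
    return np.searchsorted(edges, values, side="right")


def info_gain(values: Sequence[float], labels: Sequence[int], bins: int = 10) -> float:
    """Information gain (bits) of a discretized attribute w.r.t. the class.

    The attribute is discretized into ``bins`` equal-frequency bins and the
    gain is ``H(class) - H(class | binned attribute)``, clipped at zero.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    if v.size != y.size:
        raise ValueError("values and labels must have equal length")
    if v.size < 2:
        raise ValueError("need at least two samples")
    h_class = _entropy_bits(y)
    if h_class == 0.0:
        return 0.0
    binned = _discretize(v, bins)
    n = v.size
    cond = 0.0
    for b in np.unique(binned):
        mask = binned == b
        cond += mask.sum() / n * _entropy_bits(y[mask])
    return float(max(0.0, h_class - cond))


@dataclass
class RankedAttributes:
    """Attributes sorted by descending information gain."""

    names: Tuple[str, ...]
    gains: np.ndarray
    bins: int = 10
    mode: str = "combined"

    def __post_init__(self) -> None:
        order = np.argsort(-self.gains, kind="stable")
        self.names = tuple(np.asarray(self.names, dtype=object)[order])
        self.gains = np.asarray(self.gains, dtype=float)[order]

    def gain_of(self, name: str) -> float:
        return float(self.gains[self.names.index(name)])


def rank_attributes(fm: FeatureMatrix, bins: int = 10, mode: str = "combined") -> RankedAttributes:
    gains = np.array(
        [info_gain(fm.X[:, j], fm.labels, bins) for j in range(fm.X.shape[1])]
    )
    return RankedAttributes(names=tuple(fm.columns), gains=gains, bins=bins, mode=mode)


def aggregate_channels(fm: FeatureMatrix) -> FeatureMatrix:
    """Mean each feature's channel attributes into one column per feature."""
    if fm.mode != "sensor":
        raise ValueError("aggregation requires a sensor-level matrix")
    groups: Dict[str, List[int]] = {}
    for j, col in enumerate(fm.columns):
        feat = col.split("__")[0]
        groups.setdefault(feat, []).append(j)
    X = np.stack(
        [fm.X[:, idx].mean(axis=1) for idx in groups.values()], axis=1
    ) if fm.X.shape[0] else np.zeros((0, len(groups)))
    return FeatureMatrix(
        X=X, columns=tuple(groups), labels=fm.labels, mode="aggregated",
        split=fm.split,
    )


# ---------------------------------------------------------------------------
# Wrapper searches
# ---------------------------------------------------------------------------

def _default_rf(seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=10, criterion="gini", max_depth=10, random_state=seed
    )


def cv_f1(
    X: np.ndarray, y: np.ndarray, cv_folds: int = 5, seed: int = 0
) -> float:
    """Stratified k-fold cross-validated F1 of the default random forest."""
    y = np.asarray(y)
    if np.unique(y).size < 2:
        return 0.0
    folds = min(cv_folds, int(np.bincount(y).min()))
    if folds < 2:
        return 0.0
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = []
    for tr, te in skf.split(X, y):
        clf = _default_rf(seed)
        clf.fit(X[tr], y[tr])
        scores.append(f1_score(y[te], clf.predict(X[te]), zero_division=0))
    return float(np.mean(scores))


@dataclass
class SelectionResult:
    retained: Tuple[str, ...]
    cutoff: float
    retained_f1: float
    full_f1: float


def rfe_select(
    fm: FeatureMatrix,
    ranked: Optional[RankedAttributes] = None,
    cv_folds: int = 5,
    tol: float = 0.025,
    seed: int = 0,
) -> SelectionResult:
    """Backward elimination of the lowest-information-gain attributes.

    Repeatedly drops the weakest remaining attribute while the cross-validated
    F1 of a default random forest stays within ``tol`` of the full-set F1;
    stops before the first removal that would violate that bound.  The cutoff
    reported is the gain of the weakest retained attribute.
    """
    if ranked is None:
        ranked = rank_attributes(fm)
    col_index = {c: j for j, c in enumerate(fm.columns)}
    # order of removal: ascending gain, lexical tie-break
    order = sorted(
        zip(ranked.gains, ranked.names), key=lambda t: (t[0], t[1])
    )
    gain_of = {name: g for g, name in order}
    retained = list(fm.columns)
    full = cv_f1(fm.X, fm.labels, cv_folds, seed)
    f1_now = full
    if len(retained) >= 2:
        for g, name in order:
            if len(retained) == 1:
                break
            trial = [c for c in retained if c != name]
            idx = [col_index[c] for c in trial]
            f1_trial = cv_f1(fm.X[:, idx], fm.labels, cv_folds, seed)
            if f1_trial >= full - tol:
                retained = trial
                f1_now = f1_trial
            else:
                break
    cutoff = min((gain_of[c] for c in retained), default=0.0)
    return SelectionResult(
        retained=tuple(retained), cutoff=float(cutoff),
        retained_f1=f1_now, full_f1=full,
    )


def _spec_from_columns(columns: Sequence[str], name: str) -> FeatureSetSpec:
    groups: Dict[str, List[str]] = {}
    for col in columns:
        if "__" in col:
            feat, ch = col.split("__", 1)
            groups.setdefault(feat, []).append(ch)
        else:
            groups.setdefault(col, []).extend(["green", "red", "ir"])
    defs = tuple(
        FeatureDef(feat, tuple(dict.fromkeys(chans))) for feat, chans in groups.items()
    )
    return FeatureSetSpec(name, defs)


def best_first_select(
    fm: FeatureMatrix,
    cv_folds: int = 5,
    patience: int = 5,
    seed: int = 0,
) -> FeatureSetSpec:
    """Greedy forward (best-first) wrapper search over pooled attributes.

    Starts from the empty set, repeatedly adds the attribute that maximizes
    cross-validated F1, and stops after ``patience`` consecutive expansions
    without improving the best score seen; returns the best subset found as a
    :class:`FeatureSetSpec`.
    """
    pool = list(fm.columns)
    if not pool:
        return FeatureSetSpec("best_first", ())
    col_index = {c: j for j, c in enumerate(fm.columns)}
    current: List[str] = []
    best_subset: List[str] = []
    best_f1 = 0.0
    stale = 0
    while pool and stale < patience:
        trial_scores = []
        for cand in pool:
            idx = [col_index[c] for c in current + [cand]]
            trial_scores.append(cv_f1(fm.X[:, idx], fm.labels, cv_folds, seed))
        k = int(np.argmax(trial_scores))
        current.append(pool.pop(k))
        if trial_scores[k] > best_f1 + 1e-12:
            best_f1 = trial_scores[k]
            best_subset = list(current)
            stale = 0
        else:
            stale += 1
    return _spec_from_columns(best_subset, "best_first")
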