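"""Two-stage feature selection: mutual-information filter + SVM wrapper.

The filter stage scores each feature F_i by a mixed mutual-information
criterion

    MIME(F_i) = I(F_i, y) - alpha * (1/m) * sum_j I(F_i, F_j)
                          - beta  * (1/m) * sum_j I(F_i, F_j | y)

where y is the class label and j ranges over the other m features: the
relevance of a feature is discounted by its average redundancy with the
rest of the set, both marginal and class-conditional. Features scoring
below a threshold (lower-quartile by default) are dropped.

The wrapper stage then iteratively tests the surviving features: a
not-yet-tested feature is drawn at random, the cross-validated accuracy
of a support-vector classifier without it is measured, and the feature is
permanently deleted whenever accuracy does not decrease (ties favour the
smaller model). The procedure stops once every remaining feature has been
tested since the last deletion.

Mutual information is estimated by the plug-in (joint histogram)
estimator after equal-frequency binning of continuous inputs; the
estimator is deliberately simple so it can be verified exactly against a
brute-force summation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC

__all__ = [
    "SelectionConfig",
    "SelectionResult",
    "discretize_equal_frequency",
    "estimate_mi",
    "estimate_cmi",
    "mime_scores",
    "filter_stage",
    "rfecv_wrapper",
    "select_features",
]


@dataclass(frozen=True)
class SelectionConfig:
    """Weights, binning and wrapper settings for feature selection."""

    alpha: float = 1.0
    beta: float = 1.0
    mi_bins: int = 8
    filter_quantile: float = 0.25  # keep scores >= this quantile
    filter_threshold: float | None = None  # absolute threshold overrides quantile
    cv_folds: int = 5
    svc_kernel: str = "rbf"
    svc_c: float = 1.0
    min_features: int = 1  # wrapper never deletes below this count
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be >= 0")
        if self.mi_bins < 2:
            raise ValueError("mi_bins must be >= 2")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class SelectionResult:
    """Outcome of the two-stage selection, with a replayable wrapper log."""

    selected: list[str]
    mime_scores: pd.Series
    filter_survivors: list[str]
    wrapper_log: list[dict] = field(default_factory=list)


def discretize_equal_frequency(values: np.ndarray, bins: int) -> np.ndarray:
    """Equal-frequency binning of a 1-D array into integer codes.

    Already-discrete inputs with <= ``bins`` distinct values are passed
    through as integer codes unchanged.
    """
    values = np.asarray(values)
    uniq = np.unique(values)
    if uniq.size <= bins:
        return np.searchsorted(uniq, values)
    qs = np.quantile(values, np.linspace(0, 1, bins + 1)[1:-1])
    return np.searchsorted(qs, values, side="right")


def _joint_counts(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    counts = np.zeros((ai.max() + 1, bi.max() + 1))
    np.add.at(counts, (ai, bi), 1.0)
    return counts


def _mi_from_counts(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    pa = p.sum(axis=1, keepdims=True)
    pb = p.sum(axis=0, keepdims=True)
    mask = p > 0
    return float(np.sum(p[mask] * np.log2(p[mask] / (pa @ pb)[mask])))


def estimate_mi(a: np.ndarray, b: np.ndarray, bins: int = 8) -> float:
    """Plug-in mutual information I(a, b) in bits.

    Continuous inputs are equal-frequency binned into ``bins`` bins first.
    """
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    if a.size < 2:
        raise ValueError("need at least 2 observations")
    return _mi_from_counts(
        _joint_counts(discretize_equal_frequency(a, bins),
                      discretize_equal_frequency(b, bins))
    )


def estimate_cmi(a: np.ndarray, b: np.ndarray, c: np.ndarray, bins: int = 8) -> float:
    """Conditional mutual information I(a, b | c) in bits.

    Computed as sum_y p(c=y) * I(a, b | c=y); binning of a and b is done
    globally so codes are comparable across classes. Classes with fewer
    than 2 samples contribute 0 with a warning.
    """
    a, b, c = np.asarray(a), np.asarray(b), np.asarray(c)
    if not (a.shape == b.shape == c.shape):
        raise ValueError("length mismatch")
    ad = discretize_equal_frequency(a, bins)
    bd = discretize_equal_frequency(b, bins)
    total = 0.0
    n = len(c)
    for y in np.unique(c):
        sel = c == y
        if sel.sum() < 2:
            warnings.warn(f"class {y!r} has < 2 samples; its term contributes 0",
                          stacklevel=2)
            continue
        total += (sel.sum() / n) * _mi_from_counts(_joint_counts(ad[sel], bd[sel]))
    return float(total)


def mime_scores(table: pd.DataFrame, labels: np.ndarray,
                cfg: SelectionConfig = SelectionConfig()) -> pd.Series:
    """Mixed mutual-information score of every feature column.

    relevance minus alpha * mean pairwise MI minus beta * mean pairwise
    class-conditional MI, each mean over the other features.
    """
    cols = [c for c in table.columns if c not in ("sample_id", "label", "environment")]
    if len(cols) < 2:
        raise ValueError("need at least 2 features")
    labels = np.asarray(labels)
    binned = {c: discretize_equal_frequency(table[c].to_numpy(), cfg.mi_bins)
              for c in cols}
    m = len(cols) - 1
    scores = {}
    for ci in cols:
        a = binned[ci]
        rel = _mi_from_counts(_joint_counts(a, labels))
        red = cred = 0.0
        if cfg.alpha > 0 or cfg.beta > 0:
            for cj in cols:
                if cj == ci:
                    continue
                b = binned[cj]
                if cfg.alpha > 0:
                    red += _mi_from_counts(_joint_counts(a, b))
                if cfg.beta > 0:
                    n = len(labels)
                    for y in np.unique(labels):
                        sel = labels == y
                        if sel.sum() >= 2:
                            cred += (sel.sum() / n) * _mi_from_counts(
                                _joint_counts(a[sel], b[sel]))
        scores[ci] = rel - cfg.alpha * red / m - cfg.beta * cred / m
    return pd.Series(scores)


def filter_stage(scores: pd.Series, cfg: SelectionConfig = SelectionConfig()) -> list[str]:
    """Keep features scoring at or above the threshold; never empties the set."""
    if cfg.filter_threshold is not None:
        thr = cfg.filter_threshold
    else:
        thr = float(np.quantile(scores.to_numpy(), cfg.filter_quantile))
    kept = [name for name, s in scores.items() if s >= thr]
    if not kept:
        kept = [scores.idxmax()]
    return kept


def _make_svc(cfg: SelectionConfig) -> SVC:
    return SVC(kernel=cfg.svc_kernel, C=cfg.svc_c)


def _cv_accuracy(X: np.ndarray, y: np.ndarray, cfg: SelectionConfig) -> float:
    cv = StratifiedKFold(n_splits=cfg.cv_folds, shuffle=True, random_state=cfg.seed)
    return float(cross_val_score(_make_svc(cfg), X, y, cv=cv).mean())


def rfecv_wrapper(table: pd.DataFrame, labels: np.ndarray,
                  cfg: SelectionConfig = SelectionConfig(),
                  features: list[str] | None = None) -> SelectionResult:
    """Iterative randomized backward elimination with a cross-validated SVM.

    At each step an untested feature is drawn uniformly at random (seeded);
    if the cross-validated accuracy without it does not decrease, it is
    permanently deleted and the incumbent accuracy updated. Terminates when
    every remaining feature has been tested since the last deletion.
    """
    if features is None:
        features = [c for c in table.columns
                    if c not in ("sample_id", "label", "environment")]
    if len(features) < 2:
        raise ValueError("need at least 2 surviving features")
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("labels are single-class")

    rng = np.random.default_rng(cfg.seed)
    current = list(features)
    incumbent = _cv_accuracy(table[current].to_numpy(), labels, cfg)
    log: list[dict] = []
    untested = list(current)
    while untested and len(current) > max(1, cfg.min_features):
        feat = untested.pop(int(rng.integers(len(untested))))
        trial = [f for f in current if f != feat]
        acc = _cv_accuracy(table[trial].to_numpy(), labels, cfg)
        deleted = acc >= incumbent  # ties favour the smaller model
        if deleted:
            current = trial
            incumbent = acc
            untested = list(current)  # re-test everything since the set changed
        log.append({"feature": feat, "cv_accuracy": acc, "deleted": bool(deleted)})
    return SelectionResult(selected=current, mime_scores=pd.Series(dtype=float),
                           filter_survivors=list(features), wrapper_log=log)


def select_features(table: pd.DataFrame, labels: np.ndarray,
                    cfg: SelectionConfig = SelectionConfig()) -> SelectionResult:
    """Full two-stage selection: MIME filter then SVM wrapper."""
    scores = mime_scores(table, labels, cfg)
    survivors = filter_stage(scores, cfg)
    if len(survivors) < 2:
        return SelectionResult(survivors, scores, survivors, [])
    result = rfecv_wrapper(table, labels, cfg, features=survivors)
    result.mime_scores = scores
    return result
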