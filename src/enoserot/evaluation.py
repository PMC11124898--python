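"""Experiment harness: stratified splits, baselines, repeated runs.

The protocol mirrors a standard small-sample e-nose study: each dataset is
split 60/10/30% (train/validation/test, class-stratified) and every model
is trained on five different seeded splits; accuracies are reported as
mean +/- std with a confusion matrix for the best run. Baseline
classifiers (RBF SVM, L2 logistic regression, 5-NN) and a single CNN are
compared against the CNN ensemble, each with and without class-overlap
discretization of the selected features.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn import metrics as _skmetrics

from .synthdata import CLASS_LABELS
from .preprocess import fit_normalizer, apply_normalizer
from .selection import SelectionConfig, select_features
from .discretization import fit_discretizer, transform, one_hot_encode
from . import ecnn

__all__ = [
    "SplitSpec",
    "EvalConfig",
    "EvalReport",
    "stratified_split",
    "confusion_matrix",
    "run_experiment",
]

_META = ("sample_id", "label", "environment")
LABEL_TO_INT = {c: i for i, c in enumerate(CLASS_LABELS)}


@dataclass(frozen=True)
class SplitSpec:
    """Disjoint, exhaustive, class-stratified index sets (60/10/30%)."""

    train: np.ndarray
    val: np.ndarray
    test: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        all_idx = np.concatenate([self.train, self.val, self.test])
        if len(np.unique(all_idx)) != len(all_idx):
            raise ValueError("split index sets overlap")


def stratified_split(n_samples: int, labels: np.ndarray, seed: int) -> SplitSpec:
    """60% train / 10% validation / 30% test, stratified by class."""
    labels = np.asarray(labels)
    if len(labels) != n_samples:
        raise ValueError("labels length mismatch")
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < 10:
        raise ValueError("a class has too few samples for a 60/10/30 stratified split")
    idx = np.arange(n_samples)
    train, rest = train_test_split(idx, test_size=0.4, stratify=labels,
                                   random_state=seed)
    val, test = train_test_split(rest, test_size=0.75, stratify=labels[rest],
                                 random_state=seed)
    return SplitSpec(np.sort(train), np.sort(val), np.sort(test), seed)


def confusion_matrix(truth: np.ndarray, predicted: np.ndarray) -> np.ndarray:
    """3x3 count matrix, rows = truth, columns = predicted."""
    truth, predicted = np.asarray(truth), np.asarray(predicted)
    if truth.shape != predicted.shape:
        raise ValueError("length mismatch")
    for arr in (truth, predicted):
        if np.any((arr < 0) | (arr >= len(CLASS_LABELS))):
            raise ValueError("unseen label code")
    return _skmetrics.confusion_matrix(
        truth, predicted, labels=list(range(len(CLASS_LABELS))))


@dataclass(frozen=True)
class EvalConfig:
    """Settings of one full experiment."""

    n_repeats: int = 5
    seed: int = 0
    # the harness keeps >= 10 features so every CNN spec retains a workable
    # receptive field after the wrapper prunes
    selection: SelectionConfig = SelectionConfig(min_features=10)
    ensemble: ecnn.EnsembleConfig = ecnn.EnsembleConfig()
    models: tuple[str, ...] = ("SVM", "LR", "KNN", "CNN", "ECNN")
    conditions: tuple[str, ...] = ("raw", "discretized")
    run_selection: bool = True
    resplit_each_repeat: bool = True


@dataclass
class CellResult:
    """One model x condition cell: per-repeat accuracies and best-run matrix."""

    model: str
    condition: str
    train_accuracies: list[float] = field(default_factory=list)
    test_accuracies: list[float] = field(default_factory=list)
    best_confusion: np.ndarray | None = None
    best_seed: int | None = None
    error: str | None = None

    @property
    def mean(self) -> float:
        return float(np.mean(self.test_accuracies))

    @property
    def std(self) -> float:
        return float(np.std(self.test_accuracies))


@dataclass
class EvalReport:
    """All cells of an experiment plus bookkeeping for the delta column."""

    cells: dict[tuple[str, str], CellResult]
    base_test_accuracies: list[list[float]] = field(default_factory=list)
    selected_counts: list[int] = field(default_factory=list)
    seeds: list[int] = field(default_factory=list)

    def delta(self, model: str) -> float:
        """Discretized minus raw mean test accuracy, in accuracy fraction."""
        return self.cells[(model, "discretized")].mean - self.cells[(model, "raw")].mean

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (model, cond), cell in self.cells.items():
            rows.append({
                "model": model, "condition": cond,
                "train_acc_mean": float(np.mean(cell.train_accuracies)),
                "test_acc_mean": cell.mean, "test_acc_std": cell.std,
            })
        return pd.DataFrame(rows)


def _make_baseline(name: str, seed: int):
    if name == "SVM":
        return SVC(kernel="rbf", C=1.0)
    if name == "LR":
        return LogisticRegression(max_iter=2000, random_state=seed)
    if name == "KNN":
        return KNeighborsClassifier(n_neighbors=5)
    raise ValueError(f"unknown baseline {name!r}")


def _prepare_matrices(table: pd.DataFrame, split: SplitSpec, cfg: EvalConfig):
    """Normalize, select and (optionally) discretize for one split.

    Returns dict: condition -> (X_train, X_val, X_test) plus label arrays
    and the per-base-classifier bookkeeping needed by the report.
    """
    y = table["label"].map(LABEL_TO_INT).to_numpy()
    stats = fit_normalizer(table.iloc[split.train])
    norm = apply_normalizer(table, stats)

    feature_cols = [c for c in norm.columns if c not in _META]
    if cfg.run_selection:
        sel = select_features(norm.iloc[split.train][["label", *feature_cols]],
                              y[split.train], cfg.selection)
        feature_cols = sel.selected
    n_selected = len(feature_cols)

    out = {}
    for cond in cfg.conditions:
        if cond == "raw":
            X = norm[feature_cols].to_numpy(dtype=float)
        elif cond == "discretized":
            sub = norm[["label", *feature_cols]]
            model = fit_discretizer(sub.iloc[split.train])
            encoded = one_hot_encode(transform(model, sub), model)
            enc_cols = [c for c in encoded.columns if c not in _META]
            X = encoded[enc_cols].to_numpy(dtype=float)
        else:
            raise ValueError(f"unknown condition {cond!r}")
        out[cond] = (X[split.train], X[split.val], X[split.test])
    return out, y, n_selected


def run_experiment(table: pd.DataFrame, cfg: EvalConfig = EvalConfig()) -> EvalReport:
    """Run every model x condition cell over ``n_repeats`` seeded splits.

    A failure inside one cell is recorded on that cell and does not abort
    the rest of the experiment.
    """
    labels = table["label"].to_numpy()
    cells = {(m, c): CellResult(m, c) for m in cfg.models for c in cfg.conditions}
    report = EvalReport(cells=cells)

    for rep in range(cfg.n_repeats):
        seed = cfg.seed + rep if cfg.resplit_each_repeat else cfg.seed
        report.seeds.append(seed)
        split = stratified_split(len(table), labels, seed)
        mats, y, n_selected = _prepare_matrices(table, split, cfg)
        report.selected_counts.append(n_selected)
        y_tr, y_te = y[split.train], y[split.test]

        for cond in cfg.conditions:
            X_tr, X_val, X_te = mats[cond]
            for model_name in cfg.models:
                cell = cells[(model_name, cond)]
                try:
                    if model_name in ("SVM", "LR", "KNN"):
                        clf = _make_baseline(model_name, seed)
                        clf.fit(X_tr, y_tr)
                        pred_tr, pred_te = clf.predict(X_tr), clf.predict(X_te)
                    elif model_name == "CNN":
                        tcfg = replace(cfg.ensemble.train, seed=seed)
                        single = ecnn.train_base(cfg.ensemble.optimal_spec,
                                                 X_tr, y_tr, tcfg)
                        pred_tr, pred_te = single.predict(X_tr), single.predict(X_te)
                    elif model_name == "ECNN":
                        ecfg = replace(cfg.ensemble,
                                       train=replace(cfg.ensemble.train, seed=seed))
                        ens = ecnn.train_ensemble(X_tr, y_tr, ecfg)
                        pred_tr, pred_te = ens.predict(X_tr), ens.predict(X_te)
                        if cond == "raw":
                            report.base_test_accuracies.append(
                                [float((b.predict(X_te) == y_te).mean())
                                 for b in ens.bases])
                    else:
                        raise ValueError(f"unknown model {model_name!r}")
                except Exception as exc:  # noqa: BLE001 - cell isolation
                    cell.error = f"repeat {rep}: {exc}"
                    continue
                train_acc = float((pred_tr == y_tr).mean())
                test_acc = float((pred_te == y_te).mean())
                cell.train_accuracies.append(train_acc)
                cell.test_accuracies.append(test_acc)
                if cell.best_confusion is None or \
                        test_acc > max(cell.test_accuracies[:-1], default=-1.0):
                    cell.best_confusion = confusion_matrix(y_te, pred_te)
                    cell.best_seed = seed
    return report
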