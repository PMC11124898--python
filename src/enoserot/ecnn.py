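"""Ensemble of 1-D convolutional networks with a convolutional meta-learner.

A base classifier is a small 1-D CNN — two strided convolutions (stride 2,
valid padding, ReLU) followed by a perceptron (n -> 200 -> 3) — applied to
the feature vector treated as a single-channel sequence. The hyperparameter
grid varies kernel size and kernel count of both conv layers:
[3,5,7,9] x [8,16,32,64] for the first layer and [3,5,7] x [32,64,128] for
the second, 144 combinations. The best grid point by validation accuracy
is the "optimal" spec; the ensemble consists of the optimal spec plus its
9 nearest grid neighbours (L1 distance on grid-index coordinates), giving
10 base classifiers with diverse receptive fields.

The meta-learner is a single-conv CNN (default kernel 3, 16 kernels) that
reads the concatenated 10 x 3 class-probability outputs of the bases as a
length-30 sequence and emits the final 3-class decision. It is trained on
out-of-fold base outputs (stacking) to avoid fitting the bases' in-sample
optimism; in-sample stacking is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import itertools

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import nn

__all__ = [
    "BaseCnnSpec",
    "MetaCnnSpec",
    "TrainConfig",
    "EnsembleConfig",
    "TrainedCnn",
    "EnsembleModel",
    "GRID_AXES",
    "META_GRID_AXES",
    "DEFAULT_OPTIMAL_SPEC",
    "enumerate_grid",
    "enumerate_meta_grid",
    "grid_search",
    "neighbor_specs",
    "train_base",
    "train_ensemble",
]

GRID_AXES = {
    "k1": (3, 5, 7, 9),
    "c1": (8, 16, 32, 64),
    "k2": (3, 5, 7),
    "c2": (32, 64, 128),
}
META_GRID_AXES = {"k": (3, 5, 7), "c": (4, 8, 16, 32, 64)}

N_CLASSES = 3
HIDDEN = 200
STRIDE = 2


@dataclass(frozen=True, order=True)
class BaseCnnSpec:
    """(kernel size, kernel count) of the two conv layers of a base CNN."""

    k1: int = 5
    c1: int = 64
    k2: int = 3
    c2: int = 128

    def __post_init__(self) -> None:
        for name, axis in GRID_AXES.items():
            if getattr(self, name) not in axis:
                raise ValueError(f"{name}={getattr(self, name)} not in grid axis {axis}")

    def grid_index(self) -> tuple[int, int, int, int]:
        return tuple(GRID_AXES[a].index(getattr(self, a)) for a in GRID_AXES)

    def feasible(self, input_len: int) -> bool:
        l1 = nn.conv_output_length(input_len, self.k1, STRIDE)
        return l1 >= 1 and nn.conv_output_length(l1, self.k2, STRIDE) >= 1

    def flat_width(self, input_len: int) -> int:
        l1 = nn.conv_output_length(input_len, self.k1, STRIDE)
        return self.c2 * nn.conv_output_length(l1, self.k2, STRIDE)

    def n_parameters(self, input_len: int) -> int:
        n = self.flat_width(input_len)
        return (self.c1 * self.k1 + self.c1
                + self.c2 * self.c1 * self.k2 + self.c2
                + n * HIDDEN + HIDDEN + HIDDEN * N_CLASSES + N_CLASSES)


@dataclass(frozen=True, order=True)
class MetaCnnSpec:
    """Single conv layer (kernel size, kernel count) of the meta-CNN."""

    k: int = 3
    c: int = 16

    def __post_init__(self) -> None:
        if self.k not in META_GRID_AXES["k"] or self.c not in META_GRID_AXES["c"]:
            raise ValueError("meta spec outside grid")


DEFAULT_OPTIMAL_SPEC = BaseCnnSpec(5, 64, 3, 128)
DEFAULT_META_SPEC = MetaCnnSpec(3, 16)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings shared by base and meta networks."""

    learning_rate: float = 0.001
    decay: float = 0.9  # momentum coefficient by default
    decay_mode: str = "momentum"
    epochs: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")


def enumerate_grid() -> list[BaseCnnSpec]:
    """All 144 base hyperparameter groups, lexicographic in grid order."""
    return [BaseCnnSpec(k1, c1, k2, c2)
            for k1, c1, k2, c2 in itertools.product(*GRID_AXES.values())]


def enumerate_meta_grid() -> list[MetaCnnSpec]:
    """All 15 meta hyperparameter groups."""
    return [MetaCnnSpec(k, c) for k, c in itertools.product(*META_GRID_AXES.values())]


def _build_base(spec: BaseCnnSpec, input_len: int, rng: np.random.Generator) -> nn.Sequential:
    return nn.Sequential([
        nn.Conv1d(1, spec.c1, spec.k1, STRIDE, rng),
        nn.ReLU(),
        nn.Conv1d(spec.c1, spec.c2, spec.k2, STRIDE, rng),
        nn.ReLU(),
        nn.Flatten(),
        nn.Dense(spec.flat_width(input_len), HIDDEN, rng),
        nn.ReLU(),
        nn.Dense(HIDDEN, N_CLASSES, rng),
    ])


def _build_meta(spec: MetaCnnSpec, input_len: int, rng: np.random.Generator) -> nn.Sequential:
    lo = nn.conv_output_length(input_len, spec.k, STRIDE)
    if lo < 1:
        raise ValueError("meta input too short for the conv kernel")
    return nn.Sequential([
        nn.Conv1d(1, spec.c, spec.k, STRIDE, rng),
        nn.ReLU(),
        nn.Flatten(),
        nn.Dense(spec.c * lo, N_CLASSES, rng),
    ])


@dataclass
class TrainedCnn:
    """A trained network plus its spec and loss trajectory."""

    spec: object
    net: nn.Sequential
    input_len: int
    losses: list[float] = field(default_factory=list)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.input_len:
            raise ValueError(f"expected feature width {self.input_len}, got {X.shape[1]}")
        return nn.softmax(self.net.forward(X[:, None, :]))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)


def train_base(spec: BaseCnnSpec, X: np.ndarray, y: np.ndarray,
               cfg: TrainConfig = TrainConfig()) -> TrainedCnn:
    """Train one base CNN; deterministic given the config seed."""
    X = np.asarray(X, dtype=float)
    input_len = X.shape[1]
    if not spec.feasible(input_len):
        raise ValueError(f"spec {spec} infeasible for input width {input_len}")
    rng = np.random.default_rng(cfg.seed)
    net = _build_base(spec, input_len, rng)
    losses = nn.train_network(net, X[:, None, :], np.asarray(y), cfg.epochs,
                              cfg.learning_rate, cfg.decay, cfg.decay_mode)
    return TrainedCnn(spec, net, input_len, losses)


def _train_meta(spec: MetaCnnSpec, X: np.ndarray, y: np.ndarray,
                cfg: TrainConfig) -> TrainedCnn:
    rng = np.random.default_rng(cfg.seed + 1)
    net = _build_meta(spec, X.shape[1], rng)
    losses = nn.train_network(net, X[:, None, :], np.asarray(y), cfg.epochs,
                              cfg.learning_rate, cfg.decay, cfg.decay_mode)
    return TrainedCnn(spec, net, X.shape[1], losses)


def grid_search(X_train, y_train, X_val, y_val,
                grid: list[BaseCnnSpec] | None = None,
                cfg: TrainConfig = TrainConfig()):
    """Train every grid point and return (best spec, leaderboard).

    The leaderboard holds (spec, validation accuracy) for every feasible
    grid point; ties are broken toward fewer parameters, then
    lexicographically smaller spec.
    """
    if grid is None:
        grid = enumerate_grid()
    if not grid:
        raise ValueError("empty grid")
    input_len = X_train.shape[1]
    leaderboard = []
    for spec in grid:
        if not spec.feasible(input_len):
            continue
        model = train_base(spec, X_train, y_train, cfg)
        acc = float((model.predict(X_val) == y_val).mean())
        leaderboard.append((spec, acc))
    if not leaderboard:
        raise ValueError("no feasible spec in the grid for this input width")
    best = min(leaderboard,
               key=lambda e: (-e[1], e[0].n_parameters(input_len), e[0]))[0]
    return best, leaderboard


def neighbor_specs(optimal: BaseCnnSpec, count: int = 10,
                   input_len: int | None = None) -> list[BaseCnnSpec]:
    """The optimal spec plus its nearest grid points under L1 index distance.

    Distance is measured on the grid-index coordinates of the four axes;
    ties break lexicographically. With ``input_len`` given, infeasible
    specs are excluded.
    """
    grid = enumerate_grid()
    if input_len is not None:
        grid = [s for s in grid if s.feasible(input_len)]
    if count > len(grid):
        raise ValueError(f"grid has only {len(grid)} feasible specs, need {count}")
    ref = np.array(optimal.grid_index())
    ranked = sorted(grid, key=lambda s: (int(np.abs(np.array(s.grid_index()) - ref).sum()), s))
    return ranked[:count]


@dataclass(frozen=True)
class EnsembleConfig:
    """Ensemble structure and training settings."""

    optimal_spec: BaseCnnSpec = DEFAULT_OPTIMAL_SPEC
    meta_spec: MetaCnnSpec = DEFAULT_META_SPEC
    n_bases: int = 10
    train: TrainConfig = TrainConfig()
    # the meta network is orders of magnitude smaller than the bases, so it
    # gets its own (cheap) epoch budget large enough to reach its plateau
    meta_epochs: int = 800
    oof_folds: int = 5
    stacking: str = "oof"  # or "insample"


@dataclass
class EnsembleModel:
    """10 trained base CNNs plus the trained meta-CNN."""

    bases: list[TrainedCnn]
    meta: TrainedCnn
    input_len: int

    def base_outputs(self, X: np.ndarray) -> np.ndarray:
        return np.hstack([b.predict_proba(X) for b in self.bases])

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.meta.predict_proba(self.base_outputs(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)


def train_ensemble(X_train: np.ndarray, y_train: np.ndarray,
                   cfg: EnsembleConfig = EnsembleConfig()) -> EnsembleModel:
    """Train the base classifiers and the stacking meta-CNN.

    With out-of-fold stacking, each base architecture is trained once per
    fold to produce unbiased meta-training inputs, then refit on the full
    training set for inference.
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train)
    if len(np.unique(y_train)) < 2:
        raise ValueError("need at least 2 classes")
    input_len = X_train.shape[1]
    specs = neighbor_specs(cfg.optimal_spec, cfg.n_bases, input_len)
    tcfg = cfg.train

    if cfg.stacking == "oof":
        meta_X = np.zeros((len(y_train), cfg.n_bases * N_CLASSES))
        skf = StratifiedKFold(n_splits=cfg.oof_folds, shuffle=True,
                              random_state=tcfg.seed)
        for tr_idx, te_idx in skf.split(X_train, y_train):
            for j, spec in enumerate(specs):
                model = train_base(spec, X_train[tr_idx], y_train[tr_idx],
                                   replace(tcfg, seed=tcfg.seed + j))
                meta_X[te_idx, j * N_CLASSES:(j + 1) * N_CLASSES] = \
                    model.predict_proba(X_train[te_idx])
    elif cfg.stacking != "insample":
        raise ValueError(f"unknown stacking mode {cfg.stacking!r}")

    bases = [train_base(spec, X_train, y_train, replace(tcfg, seed=tcfg.seed + j))
             for j, spec in enumerate(specs)]
    if cfg.stacking == "insample":
        meta_X = np.hstack([b.predict_proba(X_train) for b in bases])
    meta = _train_meta(cfg.meta_spec, meta_X, y_train,
                       replace(tcfg, epochs=cfg.meta_epochs))
    return EnsembleModel(bases, meta, input_len)
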