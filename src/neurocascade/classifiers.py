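"""Cost-sensitive neural classifiers for the two diagnostic stages.

Stage 1 (screener): a small fully-connected network on the 5-dimensional
input of four demographic variables plus the MMSE total score.  Stage 2
(battery): a 2D convolutional network on the Hilbert-embedded battery
sub-scores, with an optional skip connection feeding the flattened raw grid
directly into the first fully-connected layer.

Class imbalance (~9:1 controls:cases) is handled by a cost-sensitive
cross-entropy whose positive-class weight is w_c = n_positive / n_negative,
so the rare positive class is *down*-weighted to match the loss the
framework optimises; w_c = 1 recovers the standard cross-entropy.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

from neurocascade import nn
from neurocascade.embedding import HilbertMap
from neurocascade.metrics import roc_auc


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LossSpec:
    """Positive-class weight of the cost-sensitive cross-entropy."""

    w_c: float = 1.0

    def __post_init__(self) -> None:
        if self.w_c <= 0:
            raise ValueError("w_c must be positive")


@dataclass(frozen=True)
class FCNSpec:
    """Screener architecture; default is one hidden layer of 128 units."""

    n_layers: int = 1
    hidden_units: int = 128
    dropout_rate: float = 0.0
    input_dim: int = 5
    batch_norm: bool = False

    def __post_init__(self) -> None:
        if self.input_dim < 1:
            raise ValueError("input_dim must be >= 1")


@dataclass(frozen=True)
class CNNSpec:
    """Battery architecture; default is the two-conv / two-FC network with
    128 and 32 filters (kernel 2) and 64-unit dense layers, skip on."""

    conv_layers: tuple[tuple[int, int], ...] = ((128, 2), (32, 2))
    fc_layers: tuple[int, ...] = (64, 64)
    skip_connection: bool = True
    grid_side: int = 8
    dropout_rate: float = 0.1
    batch_norm: bool = True

    def __post_init__(self) -> None:
        for _, k in self.conv_layers:
            if k > self.grid_side:
                raise ValueError("kernel size exceeds grid side")


@dataclass(frozen=True)
class TrainConfig:
    max_epochs: int = 200
    patience: int = 15
    batch_size: int = 64
    learning_rate: float = 1e-3
    seed: int = 0
    val_fraction: float = 0.15

    def __post_init__(self) -> None:
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")


# ---------------------------------------------------------------------------
# loss pieces
# ---------------------------------------------------------------------------


def class_weight(labels: np.ndarray) -> float:
    """w_c = (number of positives) / (number of negatives)."""
    labels = np.asarray(labels)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("class_weight requires both classes")
    return n_pos / n_neg


def cost_sensitive_loss(y: np.ndarray, y_hat: np.ndarray, w_c: float) -> float:
    """Mean of  -w_c * y * log(y_hat) - (1 - y) * log(1 - y_hat).

    Probabilities are clipped to [eps, 1 - eps] with eps = 1e-7; values
    outside [0, 1] are rejected.
    """
    y = np.atleast_1d(np.asarray(y, dtype=float))
    y_hat = np.atleast_1d(np.asarray(y_hat, dtype=float))
    if np.any(y_hat < 0) or np.any(y_hat > 1):
        raise ValueError("predicted probabilities must lie in [0, 1]")
    p = np.clip(y_hat, nn.EPS_PROB, 1 - nn.EPS_PROB)
    return float(np.mean(-w_c * y * np.log(p) - (1 - y) * np.log(1 - p)))


# ---------------------------------------------------------------------------
# model builders
# ---------------------------------------------------------------------------


def build_screener(spec: FCNSpec = FCNSpec(), seed: int = 0) -> nn.Network:
    """Fully-connected screener mapping the 5-vector to a probability."""
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    d = spec.input_dim
    for _ in range(spec.n_layers):
        layers.append(nn.Dense(d, spec.hidden_units, rng))
        if spec.batch_norm:
            layers.append(nn.BatchNorm(spec.hidden_units))
        layers.append(nn.ReLU())
        if spec.dropout_rate > 0:
            layers.append(nn.Dropout(spec.dropout_rate, rng))
        d = spec.hidden_units
    head = [nn.Dense(d, 1, rng)]
    return nn.Network(feature_layers=layers, head_layers=head, skip=False)


def build_battery_cnn(
    spec: CNNSpec = CNNSpec(), hmap: HilbertMap | None = None, seed: int = 0
) -> nn.Network:
    """Convolutional battery classifier on a (side x side) embedded grid.

    With the skip connection on, the flattened input grid is concatenated to
    the convolutional features entering the first fully-connected layer, so
    low-level per-variable values reach the head directly.
    """
    side = hmap.side if hmap is not None else spec.grid_side
    for _, k in spec.conv_layers:
        if k > side:
            raise ValueError("kernel size exceeds grid side")
    rng = np.random.default_rng(seed)
    features: list[nn.Layer] = []
    ch = 1
    for n_filters, k in spec.conv_layers:
        features.append(nn.Conv2D(ch, n_filters, k, rng))
        if spec.batch_norm:
            features.append(nn.BatchNorm(n_filters))
        features.append(nn.ReLU())
        ch = n_filters
    features.append(nn.Flatten())
    d = ch * side * side
    if spec.skip_connection:
        d += side * side
    head: list[nn.Layer] = []
    for units in spec.fc_layers:
        head.append(nn.Dense(d, units, rng))
        head.append(nn.ReLU())
        if spec.dropout_rate > 0:
            head.append(nn.Dropout(spec.dropout_rate, rng))
        d = units
    head.append(nn.Dense(d, 1, rng))
    return nn.Network(feature_layers=features, head_layers=head, skip=spec.skip_connection)


# ---------------------------------------------------------------------------
# training / prediction
# ---------------------------------------------------------------------------


def train(
    model: nn.Network,
    X: np.ndarray,
    y: np.ndarray,
    config: TrainConfig = TrainConfig(),
    w_c: float | None = None,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
) -> dict:
    """Train with the cost-sensitive loss and early stopping.

    If no validation set is supplied, a stratified ``val_fraction`` of the
    training rows is held out for the early-stopping monitor.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    if w_c is None:
        w_c = class_weight(y)
    if X_val is None:
        idx = np.arange(len(y))
        tr, va = train_test_split(
            idx, test_size=config.val_fraction, stratify=y, random_state=config.seed
        )
        X, X_val, y, y_val = X[tr], X[va], y[tr], y[va]
    return nn.fit(
        model,
        X,
        y,
        X_val,
        y_val,
        w_c=w_c,
        max_epochs=config.max_epochs,
        patience=config.patience,
        batch_size=config.batch_size,
        learning_rate=config.learning_rate,
        seed=config.seed,
    )


def predict_scores(model: nn.Network, X: np.ndarray) -> np.ndarray:
    """Per-subject probability in [0, 1]; deterministic (inference mode)."""
    scores = model.predict_proba(np.asarray(X, dtype=float))
    if scores.shape[0] != X.shape[0]:
        raise ValueError("prediction shape mismatch")
    return scores


# ---------------------------------------------------------------------------
# hyper-parameter grid
# ---------------------------------------------------------------------------


def enumerate_grid(
    n_conv_range: tuple[int, int] = (1, 4),
    filter_choices: tuple[int, ...] = (32, 64, 128),
    kernel_range: tuple[int, int] = (2, 4),
    n_fc_range: tuple[int, int] = (1, 4),
    hidden_choices: tuple[int, ...] = (32, 64, 128),
    grid_side: int = 8,
) -> list[CNNSpec]:
    """All architecture combinations from inclusive integer ranges; the
    default ranges yield 4 x 3 x 3 x 4 x 3 = 432 candidate specs."""
    specs = []
    for n_conv, f, k, n_fc, h in itertools.product(
        range(n_conv_range[0], n_conv_range[1] + 1),
        filter_choices,
        range(kernel_range[0], kernel_range[1] + 1),
        range(n_fc_range[0], n_fc_range[1] + 1),
        hidden_choices,
    ):
        specs.append(
            CNNSpec(
                conv_layers=tuple((f, k) for _ in range(n_conv)),
                fc_layers=tuple(h for _ in range(n_fc)),
                grid_side=grid_side,
            )
        )
    return specs


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def save_model(model: nn.Network, spec, path) -> None:
    """Persist a trained network as an .npz of weights plus a JSON spec."""
    import json
    from pathlib import Path

    path = Path(path)
    state = model.get_state()
    np.savez(path.with_suffix(".npz"), *state)
    kind = "cnn" if isinstance(spec, CNNSpec) else "fcn"
    path.with_suffix(".json").write_text(json.dumps({"kind": kind, "spec": asdict(spec)}))


def load_model(path) -> tuple[nn.Network, object]:
    """Rebuild a network from its JSON spec and restore the saved weights."""
    import json
    from pathlib import Path

    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    d = meta["spec"]
    if meta["kind"] == "cnn":
        d["conv_layers"] = tuple(tuple(c) for c in d["conv_layers"])
        d["fc_layers"] = tuple(d["fc_layers"])
        spec = CNNSpec(**d)
        model = build_battery_cnn(spec)
    else:
        spec = FCNSpec(**d)
        model = build_screener(spec)
    with np.load(path.with_suffix(".npz")) as archive:
        model.set_state([archive[k] for k in archive.files])
    return model, spec


@dataclass
class GridSearchResult:
    best_spec: object
    best_auc: float
    table: list[dict] = field(default_factory=list)


def grid_search(
    grid: list,
    build: callable,
    X: np.ndarray,
    y: np.ndarray,
    cv_folds: int = 5,
    config: TrainConfig = TrainConfig(),
) -> GridSearchResult:
    """Exhaustive spec evaluation by stratified k-fold cross-validated AUC.

    ``build(spec, seed)`` must return a fresh model.  The full per-spec
    mean/std AUC table is retained; the best spec maximises the mean AUC.
    """
    if not grid:
        raise ValueError("grid must be nonempty")
    y = np.asarray(y)
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=config.seed)
    folds = list(skf.split(X, y))
    table = []
    for si, spec in enumerate(grid):
        aucs = []
        for fi, (tr, va) in enumerate(folds):
            model = build(spec, seed=config.seed + 31 * si + fi)
            train(model, X[tr], y[tr], config=config)
            aucs.append(roc_auc(predict_scores(model, X[va]), y[va]))
        table.append(
            {
                "spec": asdict(spec) if hasattr(spec, "__dataclass_fields__") else spec,
                "auc_mean": float(np.mean(aucs)),
                "auc_std": float(np.std(aucs)),
            }
        )
    best_i = int(np.argmax([row["auc_mean"] for row in table]))
    return GridSearchResult(
        best_spec=grid[best_i], best_auc=table[best_i]["auc_mean"], table=table
    )
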