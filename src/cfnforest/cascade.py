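"""The cascade of FNT Group Forests.

Each cascade layer holds three forests with distinct function sets
({+2,+3,+4}, {+2,+3,+5}, {+2,+4,+5} by default) for structural diversity.
A layer's three code-vector outputs are (a) averaged into the layer's fused
output, (b) concatenated to the running feature matrix as enhancement
features for deeper layers. Samples whose fused output lies entirely inside
the confidence region [0, low] ∪ [high, 1] exit early; the rest continue.
Depth grows until validation accuracy stops improving, and per-layer fused
outputs are combined by the weighted fusion y_f = sum_i w_i * y_i.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .evolution import GGGPConfig
from .expression import LabelSet
from .fnt import FunctionSet
from .group_forest import ClassCodec, FNTGroupForest, train_forest
from .pso import PSOConfig

__all__ = [
    "ConfidenceRegion",
    "CascadeConfig",
    "CascadeLayer",
    "CascadeModel",
    "CascadeFitInfo",
    "DEFAULT_FUNCTION_SETS",
    "augment",
    "fuse_outputs",
    "confidence_split",
    "layer_weight",
    "fit_cascade",
]

logger = logging.getLogger(__name__)

DEFAULT_FUNCTION_SETS: tuple[FunctionSet, ...] = (
    FunctionSet((2, 3, 4)),
    FunctionSet((2, 3, 5)),
    FunctionSet((2, 4, 5)),
)


@dataclass(frozen=True)
class ConfidenceRegion:
    """The union of closed intervals [0, low] ∪ [high, 1].

    ``low == high`` is the degenerate region covering all of [0, 1], which
    disables the gate: every sample is then confident at the first layer.
    """

    low: float = 0.2
    high: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 <= self.low <= self.high <= 1.0:
            raise ValueError("require 0 <= low <= high <= 1")

    def contains(self, values: np.ndarray) -> np.ndarray:
        """Elementwise membership (closed at low and high)."""
        values = np.asarray(values, dtype=float)
        return (values <= self.low) | (values >= self.high)


@dataclass
class CascadeConfig:
    """Everything the cascade trainer needs, with library defaults."""

    K: int = 5
    function_sets: tuple[FunctionSet, ...] = DEFAULT_FUNCTION_SETS
    gggp: GGGPConfig = field(default_factory=GGGPConfig)
    pso: PSOConfig = field(default_factory=PSOConfig)
    outer_rounds: int = 3
    max_layers: int = 5
    min_gain: float = 0.005
    patience: int = 1
    validation_fraction: float = 0.25
    region: ConfidenceRegion = field(default_factory=ConfidenceRegion)
    weights: str = "normalized"  # or "literal"
    train_on: str = "uncertain"  # or "all"

    def __post_init__(self) -> None:
        if len(self.function_sets) != 3:
            raise ValueError("a cascade layer uses exactly three function sets")
        if len(set(self.function_sets)) != 3:
            raise ValueError("the three function sets must be pairwise distinct")
        if self.weights not in ("normalized", "literal"):
            raise ValueError("weights must be 'normalized' or 'literal'")
        if self.train_on not in ("uncertain", "all"):
            raise ValueError("train_on must be 'uncertain' or 'all'")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must lie in (0, 1)")
        if self.max_layers < 1 or self.K < 1 or self.patience < 1:
            raise ValueError("max_layers, K and patience must be >= 1")


def augment(X_base: np.ndarray, layer_outputs: list[np.ndarray]) -> np.ndarray:
    """Append the three forests' outputs (in forest order) to the features."""
    X_base = np.asarray(X_base, dtype=float)
    if len(layer_outputs) != 3:
        raise ValueError("expected exactly three layer output matrices")
    outs = [np.asarray(o, dtype=float) for o in layer_outputs]
    for o in outs:
        if o.ndim != 2 or o.shape[1] < 1:
            raise ValueError("each enhancement matrix must have >= 1 column")
        if o.shape[0] != X_base.shape[0]:
            raise ValueError("row counts of base features and outputs differ")
    return np.hstack([X_base, *outs])


def fuse_outputs(layer_outputs: list[np.ndarray]) -> np.ndarray:
    """Componentwise mean of the three forests' outputs (the layer's y_i)."""
    outs = [np.asarray(o, dtype=float) for o in layer_outputs]
    if len({o.shape for o in outs}) != 1:
        raise ValueError("forest outputs must share a shape")
    return np.mean(outs, axis=0)


def confidence_split(
    layer_output: np.ndarray, region: ConfidenceRegion
) -> tuple[np.ndarray, np.ndarray]:
    """Partition sample indices into (confident, uncertain).

    A sample is confident iff *every* component of its fused output lies in
    the closed region [0, low] ∪ [high, 1]; order is preserved in each part.
    """
    layer_output = np.asarray(layer_output, dtype=float)
    conf = region.contains(layer_output).all(axis=1)
    idx = np.arange(layer_output.shape[0])
    return idx[conf], idx[~conf]


def layer_weight(i: int, N: int, mode: str = "normalized") -> float:
    """Weight of layer i's fused output in the final combination.

    ``normalized``: w_i = i / (1 + 2 + ... + N), increasing and summing to 1.
    ``literal``:    w_i = i / (1 + 2 + ... + i) = 2 / (i + 1), the printed
    form (decreasing; does not sum to 1 — fusion renormalizes it).
    """
    if not 1 <= i <= N:
        raise ValueError(f"layer index {i} outside 1..{N}")
    if mode == "normalized":
        return i / (N * (N + 1) / 2)
    if mode == "literal":
        return i / (i * (i + 1) / 2)
    raise ValueError("mode must be 'normalized' or 'literal'")


@dataclass
class CascadeLayer:
    """Three function-set-diverse forests reading the same augmented input."""

    forests: list[FNTGroupForest]

    def __post_init__(self) -> None:
        if len(self.forests) != 3:
            raise ValueError("a cascade layer holds exactly three forests")
        sets = {f.function_set for f in self.forests}
        if len(sets) != 3:
            raise ValueError("the three forests must use pairwise distinct function sets")
        if len({f.input_dim for f in self.forests}) != 1:
            raise ValueError("forests of one layer must share input width")

    @property
    def input_width(self) -> int:
        return self.forests[0].input_dim

    def predict(self, X_aug: np.ndarray) -> list[np.ndarray]:
        return [f.predict(X_aug) for f in self.forests]

    def to_dict(self) -> dict:
        return {"forests": [f.to_dict() for f in self.forests]}

    @classmethod
    def from_dict(cls, d: dict) -> "CascadeLayer":
        return cls([FNTGroupForest.from_dict(f) for f in d["forests"]])


@dataclass
class CascadeModel:
    layers: list[CascadeLayer]
    codec: ClassCodec
    region: ConfidenceRegion
    base_input_dim: int
    weights_mode: str = "normalized"

    def __post_init__(self) -> None:
        L = self.codec.code_length
        for ell, layer in enumerate(self.layers, start=1):
            expected = self.base_input_dim + (ell - 1) * 3 * L
            if layer.input_width != expected:
                raise ValueError(
                    f"layer {ell} input width {layer.input_width}, expected {expected}"
                )

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def layer_weights(self) -> np.ndarray:
        N = self.n_layers
        return np.array([layer_weight(i, N, self.weights_mode) for i in range(1, N + 1)])

    def _forward(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """All layers' fused outputs (n, N, L) and per-sample exit layers."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.base_input_dim:
            raise ValueError(
                f"expected {self.base_input_dim} columns, got shape {X.shape}"
            )
        n = X.shape[0]
        fused_all = np.empty((n, self.n_layers, self.codec.code_length))
        X_aug = X
        for ell, layer in enumerate(self.layers):
            outs = layer.predict(X_aug)
            fused_all[:, ell, :] = fuse_outputs(outs)
            if ell + 1 < self.n_layers:
                X_aug = augment(X_aug, outs)
        in_region = self.region.contains(fused_all).all(axis=2)  # (n, N)
        exit_layers = np.where(
            in_region.any(axis=1), in_region.argmax(axis=1) + 1, self.n_layers
        )
        return fused_all, exit_layers

    def predict_scores(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Final fused score vectors y_f in [0,1]^L and the exit layer used.

        A sample exiting at layer j combines layers 1..j with the configured
        weights renormalized to sum 1 over that prefix.
        """
        fused_all, exit_layers = self._forward(X)
        w = self.layer_weights()
        yf = np.empty((X.shape[0], self.codec.code_length))
        for j in np.unique(exit_layers):
            rows = exit_layers == j
            wj = w[:j] / w[:j].sum()
            yf[rows] = np.einsum("i,nil->nl", wj, fused_all[rows, :j, :])
        return yf, exit_layers

    def predict(self, X: np.ndarray) -> tuple[list[str], np.ndarray]:
        """Class labels (via nearest-code decoding of y_f) and the scores."""
        yf, _ = self.predict_scores(X)
        labels, _ = self.codec.decode_all(np.clip(yf, 0.0, 1.0))
        return labels, yf

    def to_dict(self) -> dict:
        return {
            "class_list": list(self.codec.class_list),
            "region": {"low": self.region.low, "high": self.region.high},
            "base_input_dim": self.base_input_dim,
            "weights_mode": self.weights_mode,
            "layers": [l.to_dict() for l in self.layers],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CascadeModel":
        return cls(
            [CascadeLayer.from_dict(l) for l in d["layers"]],
            ClassCodec(tuple(d["class_list"])),
            ConfidenceRegion(d["region"]["low"], d["region"]["high"]),
            int(d["base_input_dim"]),
            d["weights_mode"],
        )


@dataclass
class CascadeFitInfo:
    """Training diagnostics recorded while the cascade grows."""

    layer_val_accuracy: list[float]
    uncertain_counts: list[int]
    exit_counts: dict[int, int]
    n_train: int
    n_validation: int
    stopped_reason: str


def _stratified_split(
    n: int, class_idx: np.ndarray, fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class shuffled split; raises if either part would empty a class."""
    train, val = [], []
    for c in np.unique(class_idx):
        members = np.flatnonzero(class_idx == c)
        members = rng.permutation(members)
        n_val = int(round(fraction * members.size))
        if n_val == 0 or n_val == members.size:
            raise ValueError(
                f"validation split would empty class index {int(c)}; "
                "use a larger dataset or adjust validation_fraction"
            )
        val.extend(members[:n_val])
        train.extend(members[n_val:])
    return np.sort(np.array(train, dtype=int)), np.sort(np.array(val, dtype=int))


def fit_cascade(
    X: np.ndarray,
    y: LabelSet,
    cfg: CascadeConfig | None = None,
    seed: int = 0,
) -> tuple[CascadeModel, CascadeFitInfo]:
    """Grow, validate and trim a cascade on preprocessed features.

    The training set is split into a training and a validation part; layers
    are added while whole-cascade validation accuracy keeps improving by at
    least ``min_gain`` (with ``patience``); the returned model is trimmed to
    the best validated depth. By default each new layer trains only on the
    training samples still uncertain after the previous layers.
    """
    cfg = cfg or CascadeConfig()
    X = np.asarray(X, dtype=float)
    if X.shape[0] != len(y.sample_ids):
        raise ValueError("X rows and label count differ")
    codec = ClassCodec(tuple(y.class_list))
    L = codec.code_length
    ss = np.random.SeedSequence(seed)
    split_rng = np.random.default_rng(ss.spawn(1)[0])
    tr_idx, va_idx = _stratified_split(
        X.shape[0], y.class_indices(), cfg.validation_fraction, split_rng
    )
    X_tr, y_tr = X[tr_idx], y.subset(tr_idx)
    X_va = X[va_idx]
    va_labels = [y.labels[i] for i in va_idx]

    layers: list[CascadeLayer] = []
    val_accs: list[float] = []
    uncertain_counts: list[int] = []
    exit_layer_of = np.zeros(X_tr.shape[0], dtype=int)  # 0 = never exited
    pool = np.arange(X_tr.shape[0])  # indices into X_tr still uncertain
    X_aug_all = X_tr  # accumulated enhancement features for ALL train rows
    best_acc, best_depth, stale = -np.inf, 0, 0
    stopped = "max_layers"
    for ell in range(1, cfg.max_layers + 1):
        if cfg.train_on == "uncertain":
            fit_rows = pool
        else:
            fit_rows = np.arange(X_tr.shape[0])
        y_fit = y_tr.subset(fit_rows)
        if len(set(y_fit.labels)) < codec.n_classes:
            stopped = "uncertain pool lost a class"
            break
        uncertain_counts.append(int(pool.size))
        layer_seed = ss.spawn(1)[0]
        forest_seeds = layer_seed.spawn(3)
        forests = [
            train_forest(
                X_aug_all[fit_rows], y_fit, cfg.K, fset, cfg.gggp, cfg.pso,
                outer_rounds=cfg.outer_rounds, seed=fseed, codec=codec,
            )
            for fset, fseed in zip(cfg.function_sets, forest_seeds)
        ]
        layer = CascadeLayer(forests)
        # Enhancement features + confidence gate on the training rows.
        # Rows a forest was trained on get out-of-bag scores so deeper
        # layers are not fed in-sample (optimistic) estimates.
        outs_all = []
        for f in forests:
            out = f.predict(X_aug_all)
            out[fit_rows] = f.predict_oob(X_aug_all[fit_rows])
            outs_all.append(out)
        fused = fuse_outputs(outs_all)
        conf_idx, _ = confidence_split(fused[pool], cfg.region)
        newly_confident = pool[conf_idx]
        exit_layer_of[newly_confident] = ell
        pool = pool[~np.isin(pool, newly_confident)]
        X_aug_all = augment(X_aug_all, outs_all)
        layers.append(layer)

        interim = CascadeModel(list(layers), codec, cfg.region, X.shape[1],
                               cfg.weights)
        pred, _ = interim.predict(X_va)
        acc = float(np.mean([p == t for p, t in zip(pred, va_labels)]))
        val_accs.append(acc)
        logger.info(
            "layer %d: validation accuracy %.4f, uncertain train samples %d",
            ell, acc, pool.size,
        )
        if acc > best_acc + (cfg.min_gain if layers[:-1] else -np.inf):
            best_acc, best_depth, stale = acc, ell, 0
        else:
            if acc > best_acc:
                best_acc, best_depth = acc, ell
            stale += 1
            if stale >= cfg.patience:
                stopped = "no significant validation gain"
                break
        if pool.size == 0:
            stopped = "all training samples confident"
            break
    best_depth = max(best_depth, 1)
    model = CascadeModel(layers[:best_depth], codec, cfg.region, X.shape[1],
                         cfg.weights)
    exits = np.minimum(np.where(exit_layer_of == 0, best_depth, exit_layer_of),
                       best_depth)
    info = CascadeFitInfo(
        layer_val_accuracy=val_accs,
        uncertain_counts=uncertain_counts,
        exit_counts={int(k): int(v) for k, v in
                     zip(*np.unique(exits, return_counts=True))},
        n_train=int(tr_idx.size),
        n_validation=int(va_idx.size),
        stopped_reason=stopped,
    )
    return model, info
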