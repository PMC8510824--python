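"""M-ary class decomposition and bagged FNT Group Forests.

An M-class problem is recoded as L = ceil(log2 M) binary problems; one FNT
per code bit forms an *FNT Group*, and K groups trained on bootstrap
resamples form an *FNT Group Forest* whose per-bit outputs are averaged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .evolution import GGGPConfig, train_fnt
from .expression import LabelSet
from .fnt import FlexibleNeuralTree, FunctionSet, GrammarSpec
from .pso import PSOConfig

__all__ = ["ClassCodec", "FNTGroup", "FNTGroupForest", "train_forest"]

logger = logging.getLogger(__name__)

_MAX_BOOTSTRAP_RETRIES = 25


@dataclass(frozen=True)
class ClassCodec:
    """Bijection between M class labels and length-ceil(log2 M) bit codes.

    Class i maps to the big-endian binary representation of i; for M not a
    power of two the remaining codes are unused and never decoded to.
    """

    class_list: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.class_list) < 2:
            raise ValueError("need at least two classes")
        if len(set(self.class_list)) != len(self.class_list):
            raise ValueError("duplicate class labels")

    @property
    def n_classes(self) -> int:
        return len(self.class_list)

    @property
    def code_length(self) -> int:
        return max(1, math.ceil(math.log2(self.n_classes)))

    def code_table(self) -> np.ndarray:
        """(M, L) array of the valid codes, row i = code of class i."""
        L = self.code_length
        return np.array(
            [[(i >> (L - 1 - b)) & 1 for b in range(L)] for i in range(self.n_classes)],
            dtype=float,
        )

    def encode(self, label: str) -> np.ndarray:
        """The class's L-bit code as a {0,1} float vector."""
        try:
            i = self.class_list.index(label)
        except ValueError:
            raise ValueError(f"unknown label {label!r}") from None
        return self.code_table()[i]

    def encode_all(self, labels: list[str]) -> np.ndarray:
        table = self.code_table()
        lookup = {c: i for i, c in enumerate(self.class_list)}
        try:
            idx = [lookup[lab] for lab in labels]
        except KeyError as e:
            raise ValueError(f"unknown label {e.args[0]!r}") from None
        return table[idx]

    def decode(self, output: np.ndarray) -> tuple[str, float]:
        """Nearest valid code by Euclidean distance; ties → smallest index."""
        output = np.asarray(output, dtype=float)
        if output.shape != (self.code_length,):
            raise ValueError(
                f"expected output of length {self.code_length}, got shape {output.shape}"
            )
        if np.any(output < 0) or np.any(output > 1):
            raise ValueError("output components must lie in [0, 1]")
        d = np.linalg.norm(self.code_table() - output[None, :], axis=1)
        i = int(np.argmin(d))  # argmin takes the first minimum: smallest index
        return self.class_list[i], float(d[i])

    def decode_all(self, outputs: np.ndarray) -> tuple[list[str], np.ndarray]:
        outputs = np.asarray(outputs, dtype=float)
        if np.any(outputs < 0) or np.any(outputs > 1):
            raise ValueError("output components must lie in [0, 1]")
        d = np.linalg.norm(
            self.code_table()[None, :, :] - outputs[:, None, :], axis=2
        )
        idx = np.argmin(d, axis=1)
        return [self.class_list[i] for i in idx], d[np.arange(len(idx)), idx]


@dataclass
class FNTGroup:
    """One FNT per code bit; predicts a length-L vector in (0,1)^L."""

    trees: list[FlexibleNeuralTree]

    def __post_init__(self) -> None:
        if not self.trees:
            raise ValueError("group must contain at least one tree")
        dims = {t.input_dim for t in self.trees}
        if len(dims) != 1:
            raise ValueError("all trees in a group must share input_dim")

    @property
    def input_dim(self) -> int:
        return self.trees[0].input_dim

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.column_stack([t.evaluate_batch(X) for t in self.trees])

    def to_dict(self) -> dict:
        return {"trees": [t.to_dict() for t in self.trees]}

    @classmethod
    def from_dict(cls, d: dict) -> "FNTGroup":
        return cls([FlexibleNeuralTree.from_dict(t) for t in d["trees"]])


@dataclass
class FNTGroupForest:
    """K bagged FNT Groups sharing one function set; outputs are averaged.

    ``bootstrap_indices`` (training metadata, not serialized) records each
    group's resample so out-of-bag predictions are available for the rows
    the forest was trained on.
    """

    groups: list[FNTGroup]
    function_set: FunctionSet
    codec: ClassCodec
    bootstrap_indices: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("forest must contain at least one group")
        L = self.codec.code_length
        for g in self.groups:
            if len(g.trees) != L:
                raise ValueError(
                    f"group holds {len(g.trees)} trees, codec requires {L}"
                )
        if len({g.input_dim for g in self.groups}) != 1:
            raise ValueError("groups must share input_dim")

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def input_dim(self) -> int:
        return self.groups[0].input_dim

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Componentwise mean of the K group outputs; (n, L) in [0,1]."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.input_dim:
            raise ValueError(
                f"expected {self.input_dim} columns, got shape {X.shape}"
            )
        return np.mean([g.predict(X) for g in self.groups], axis=0)

    def predict_oob(self, X_train: np.ndarray) -> np.ndarray:
        """Out-of-bag scores for the rows this forest was trained on.

        Row i is averaged over the groups whose bootstrap did not contain i;
        rows in-bag everywhere fall back to the full-forest average.
        """
        if self.bootstrap_indices is None:
            raise ValueError("forest carries no bootstrap metadata")
        X_train = np.asarray(X_train, dtype=float)
        n = X_train.shape[0]
        preds = np.stack([g.predict(X_train) for g in self.groups])  # (K, n, L)
        oob = np.ones((len(self.groups), n), dtype=bool)
        for k, idx in enumerate(self.bootstrap_indices):
            oob[k, idx] = False
        weights = oob.astype(float)
        no_oob = weights.sum(axis=0) == 0
        weights[:, no_oob] = 1.0
        weights /= weights.sum(axis=0, keepdims=True)
        return np.einsum("kn,knl->nl", weights, preds)

    def used_features(self) -> set[int]:
        out: set[int] = set()
        for g in self.groups:
            for t in g.trees:
                out |= t.used_features()
        return out

    def to_dict(self) -> dict:
        return {
            "function_set": list(self.function_set.arities),
            "class_list": list(self.codec.class_list),
            "groups": [g.to_dict() for g in self.groups],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FNTGroupForest":
        return cls(
            [FNTGroup.from_dict(g) for g in d["groups"]],
            FunctionSet(tuple(int(a) for a in d["function_set"])),
            ClassCodec(tuple(d["class_list"])),
        )


def _bootstrap_indices(
    n: int, class_idx: np.ndarray, n_classes: int, rng: np.random.Generator
) -> np.ndarray:
    """n draws with replacement, redrawn until every class is represented."""
    for _ in range(_MAX_BOOTSTRAP_RETRIES):
        idx = rng.integers(n, size=n)
        if len(np.unique(class_idx[idx])) == n_classes:
            return idx
    raise RuntimeError(
        f"bootstrap failed to cover all {n_classes} classes in "
        f"{_MAX_BOOTSTRAP_RETRIES} redraws"
    )


def train_forest(
    X: np.ndarray,
    y: LabelSet,
    K: int,
    function_set: FunctionSet,
    gggp_cfg: GGGPConfig,
    pso_cfg: PSOConfig,
    outer_rounds: int = 3,
    seed: int | np.random.SeedSequence = 0,
    codec: ClassCodec | None = None,
) -> FNTGroupForest:
    """Bag K FNT Groups, each trained on its own bootstrap resample.

    Tree b of a group regresses bit b of the encoded labels. Each group
    consumes an independently spawned random stream, so with a fixed seed
    the first K0 groups are identical regardless of K >= K0.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    X = np.asarray(X, dtype=float)
    if X.shape[0] != len(y.sample_ids):
        raise ValueError("X rows and label count differ")
    if codec is None:
        codec = ClassCodec(tuple(y.class_list))
    codes = codec.encode_all(list(y.labels))  # (n, L)
    class_idx = y.class_indices()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    grammar = GrammarSpec(function_set, X.shape[1], gggp_cfg.max_depth)
    groups: list[FNTGroup] = []
    boots: list[np.ndarray] = []
    for child in ss.spawn(K):
        rng = np.random.default_rng(child)
        idx = _bootstrap_indices(X.shape[0], class_idx, codec.n_classes, rng)
        Xb, cb = X[idx], codes[idx]
        trees = [
            train_fnt(Xb, cb[:, b], grammar, gggp_cfg, pso_cfg,
                      outer_rounds=outer_rounds, rng=rng)
            for b in range(codec.code_length)
        ]
        groups.append(FNTGroup(trees))
        boots.append(idx)
        logger.info("trained group %d/%d", len(groups), K)
    return FNTGroupForest(groups, function_set, codec, bootstrap_indices=boots)
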