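"""Flexible neural trees: representation, evaluation, fitness.

A flexible neural tree (FNT) is a tree-shaped neural network. Internal
nodes ``+M`` compute sigma(sum_j w_j * I_j + theta) over their M children's
outputs; leaves emit input feature values directly. Both the topology and
the continuous parameters (w, theta) are learned — topology by
grammar-guided genetic programming (:mod:`cfnforest.evolution`), parameters
by particle swarm optimization (:mod:`cfnforest.pso`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "FunctionSet",
    "GrammarSpec",
    "Leaf",
    "FunctionNode",
    "FlexibleNeuralTree",
    "fitness",
    "sigmoid",
]

# pre-activation clamp; sigmoid is saturated far before +/-500
_CLAMP = 500.0


def sigmoid(z: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -_CLAMP, _CLAMP)))


@dataclass(frozen=True)
class FunctionSet:
    """The permitted internal-node arities, e.g. {+2, +3, +4}."""

    arities: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.arities:
            raise ValueError("function set must be non-empty")
        if len(set(self.arities)) != len(self.arities):
            raise ValueError("duplicate arities in function set")
        if any(a < 2 for a in self.arities):
            raise ValueError("all arities must be >= 2")
        object.__setattr__(self, "arities", tuple(sorted(self.arities)))

    def __contains__(self, arity: int) -> bool:
        return arity in self.arities

    def __iter__(self):
        return iter(self.arities)


@dataclass(frozen=True)
class GrammarSpec:
    """Context-free grammar {N, T, P, Sigma} constraining tree shapes.

    The nonterminal start symbol expands either to a function node of any
    arity in ``function_set`` (with that many nonterminal children) or to a
    terminal — a feature leaf ``x_0 .. x_{input_dim-1}``. ``max_depth``
    bounds derivations; a single node counts as depth 1.
    """

    function_set: FunctionSet
    input_dim: int
    max_depth: int = 5

    def __post_init__(self) -> None:
        if self.input_dim < 1:
            raise ValueError("input_dim must be positive")
        if self.max_depth < 1:
            raise ValueError("max_depth must be positive")

    def validate_tree(self, tree: "FlexibleNeuralTree") -> None:
        """Raise if ``tree`` is not derivable under this grammar."""
        if tree.input_dim != self.input_dim:
            raise ValueError("tree input_dim differs from grammar input_dim")
        if tree.depth() > self.max_depth:
            raise ValueError(
                f"tree depth {tree.depth()} exceeds grammar max_depth {self.max_depth}"
            )
        for node in tree.nodes():
            if isinstance(node, FunctionNode) and node.arity not in self.function_set:
                raise ValueError(f"arity {node.arity} not in function set")
            if isinstance(node, Leaf) and not 0 <= node.feature_index < self.input_dim:
                raise ValueError(f"leaf feature index {node.feature_index} out of range")

    def is_valid(self, tree: "FlexibleNeuralTree") -> bool:
        try:
            self.validate_tree(tree)
            return True
        except ValueError:
            return False


@dataclass
class Leaf:
    feature_index: int


@dataclass
class FunctionNode:
    children: list  # Leaf | FunctionNode
    weights: np.ndarray
    bias: float

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.children) != self.weights.size:
            raise ValueError(
                f"node has {len(self.children)} children but "
                f"{self.weights.size} weights"
            )
        if len(self.children) < 2:
            raise ValueError("function nodes must have arity >= 2")

    @property
    def arity(self) -> int:
        return len(self.children)


TreeNode = Leaf | FunctionNode


def _copy_node(node: TreeNode) -> TreeNode:
    if isinstance(node, Leaf):
        return Leaf(node.feature_index)
    return FunctionNode(
        [_copy_node(c) for c in node.children], node.weights.copy(), node.bias
    )


def _depth(node: TreeNode) -> int:
    if isinstance(node, Leaf):
        return 1
    return 1 + max(_depth(c) for c in node.children)


def _eval_batch(node: TreeNode, X: np.ndarray) -> np.ndarray:
    if isinstance(node, Leaf):
        return X[:, node.feature_index]
    acc = np.full(X.shape[0], node.bias, dtype=float)
    for w, child in zip(node.weights, node.children):
        acc += w * _eval_batch(child, X)
    return sigmoid(acc)


@dataclass
class FlexibleNeuralTree:
    root: TreeNode
    function_set: FunctionSet
    input_dim: int

    def __post_init__(self) -> None:
        if self.input_dim < 1:
            raise ValueError("input_dim must be positive")
        for node in self.nodes():
            if isinstance(node, Leaf):
                if not 0 <= node.feature_index < self.input_dim:
                    raise ValueError(
                        f"leaf feature index {node.feature_index} out of range "
                        f"for input_dim {self.input_dim}"
                    )

    # -- structure -----------------------------------------------------

    def nodes(self) -> list[TreeNode]:
        """All nodes in pre-order (parent before children, left to right)."""
        out: list[TreeNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            if isinstance(node, FunctionNode):
                stack.extend(reversed(node.children))
        return out

    def depth(self) -> int:
        return _depth(self.root)

    def copy(self) -> "FlexibleNeuralTree":
        return FlexibleNeuralTree(_copy_node(self.root), self.function_set, self.input_dim)

    def used_features(self) -> set[int]:
        return {n.feature_index for n in self.nodes() if isinstance(n, Leaf)}

    # -- evaluation ----------------------------------------------------

    def evaluate(self, x: np.ndarray) -> float:
        """Bottom-up output for a single input vector."""
        x = np.asarray(x, dtype=float)
        if x.shape != (self.input_dim,):
            raise ValueError(f"expected input of shape ({self.input_dim},), got {x.shape}")
        if not np.all(np.isfinite(x)):
            raise ValueError("input vector must be finite")
        return float(_eval_batch(self.root, x[None, :])[0])

    def evaluate_batch(self, X: np.ndarray) -> np.ndarray:
        """Vectorised evaluation over the rows of a samples×features matrix."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.input_dim:
            raise ValueError(
                f"expected (n, {self.input_dim}) matrix, got shape {X.shape}"
            )
        return _eval_batch(self.root, X)

    # -- parameter vector bridge (PSO position) ------------------------

    @property
    def n_params(self) -> int:
        return sum(
            n.arity + 1 for n in self.nodes() if isinstance(n, FunctionNode)
        )

    def flatten_params(self) -> np.ndarray:
        """Pre-order concatenation of (w_1..w_M, theta) per function node."""
        parts: list[np.ndarray] = []
        for n in self.nodes():
            if isinstance(n, FunctionNode):
                parts.append(n.weights)
                parts.append(np.array([n.bias]))
        if not parts:
            return np.empty(0)
        return np.concatenate(parts)

    def set_params(self, v: np.ndarray) -> "FlexibleNeuralTree":
        """Return a copy of the tree with parameters taken from ``v``."""
        v = np.asarray(v, dtype=float)
        if v.size != self.n_params:
            raise ValueError(
                f"parameter vector has length {v.size}, expected {self.n_params}"
            )
        new = self.copy()
        pos = 0
        for n in new.nodes():
            if isinstance(n, FunctionNode):
                m = n.arity
                n.weights = v[pos : pos + m].copy()
                n.bias = float(v[pos + m])
                pos += m + 1
        return new

    # -- persistence ---------------------------------------------------

    def to_dict(self) -> dict:
        def enc(node: TreeNode) -> dict:
            if isinstance(node, Leaf):
                return {"type": "leaf", "feature_index": node.feature_index}
            return {
                "type": "function",
                "arity": node.arity,
                "weights": [float(w) for w in node.weights],
                "bias": float(node.bias),
                "children": [enc(c) for c in node.children],
            }

        return {
            "root": enc(self.root),
            "function_set": list(self.function_set.arities),
            "input_dim": self.input_dim,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FlexibleNeuralTree":
        def dec(nd: dict) -> TreeNode:
            if nd["type"] == "leaf":
                return Leaf(int(nd["feature_index"]))
            return FunctionNode(
                [dec(c) for c in nd["children"]],
                np.array(nd["weights"], dtype=float),
                float(nd["bias"]),
            )

        return cls(
            dec(d["root"]),
            FunctionSet(tuple(int(a) for a in d["function_set"])),
            int(d["input_dim"]),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_json(cls, path: str | Path) -> "FlexibleNeuralTree":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fitness(tree: FlexibleNeuralTree, X: np.ndarray, y: np.ndarray) -> float:
    """Root-mean-square error between targets and tree outputs (minimized).

    Fit = sqrt((1/N) * sum_i (y1_i - y2_i)^2); zero iff the tree reproduces
    every target exactly.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] == 0:
        raise ValueError("empty dataset")
    if X.shape[0] != y.shape[0]:
        raise ValueError("X rows and y length differ")
    out = tree.evaluate_batch(X)
    return float(np.sqrt(np.mean((y - out) ** 2)))
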