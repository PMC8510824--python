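"""Synthetic class-conditional expression data.

Emulates the statistical structure the classifier assumes: a small block of
informative genes per class whose mean is shifted upward for that class,
pure-noise genes elsewhere, and missing values injected uniformly at random.
Values are Gaussian on purpose — the model consumes z-scored expression, so
count-level realism (e.g. negative-binomial RNA-seq counts) is not emulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .expression import ExpressionMatrix, LabelSet

__all__ = ["SyntheticSpec", "make_dataset", "make_worked_example"]


@dataclass
class SyntheticSpec:
    """Defaults describe a four-class, 50-samples-per-class benchmark with
    40 genes of which 10 are informative at a mean shift of 2.0."""

    n_per_class: tuple[int, ...] = (50, 50, 50, 50)
    n_genes: int = 40
    n_informative: int = 10
    shift: float = 2.0
    noise_sd: float = 1.0
    missing_rate: float = 0.05
    seed: int = 42

    def __post_init__(self) -> None:
        if len(self.n_per_class) < 2 or any(n < 1 for n in self.n_per_class):
            raise ValueError("need >= 2 classes with >= 1 sample each")
        if not 0 < self.n_informative <= self.n_genes:
            raise ValueError("require 0 < n_informative <= n_genes")
        if self.shift < 0 or self.noise_sd <= 0:
            raise ValueError("shift must be >= 0 and noise_sd > 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")


def make_dataset(spec: SyntheticSpec) -> tuple[ExpressionMatrix, LabelSet]:
    """Draw one labeled matrix from the specification.

    The first ``n_informative`` genes are split into M disjoint blocks of
    near-equal size (differing by at most one gene); class c elevates its
    own block by ``spec.shift``, so every informative gene is
    class-conditional and the remaining genes are pure noise. All genes
    carry N(0, noise_sd) noise. Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    M = len(spec.n_per_class)
    n = sum(spec.n_per_class)
    if spec.n_informative < M:
        raise ValueError("n_informative too small: every class needs >= 1 gene")
    values = rng.normal(0.0, spec.noise_sd, size=(n, spec.n_genes))
    blocks = np.array_split(np.arange(spec.n_informative), M)
    labels: list[str] = []
    row = 0
    for c, n_c in enumerate(spec.n_per_class):
        values[row : row + n_c, blocks[c]] += spec.shift
        labels.extend([f"class_{c}"] * n_c)
        row += n_c
    mask = rng.uniform(size=values.shape) < spec.missing_rate
    values = values.copy()
    values[mask] = np.nan
    X = ExpressionMatrix(
        [f"S{i:04d}" for i in range(n)],
        [f"G{j:04d}" for j in range(spec.n_genes)],
        values,
        mask,
    )
    y = LabelSet(list(X.sample_ids), labels, [f"class_{c}" for c in range(M)])
    return X, y


def make_worked_example() -> list[np.ndarray]:
    """The five two-bit score vectors used to demonstrate the confidence
    gate: with region [0, 0.2] ∪ [0.8, 1], the first and last are confident."""
    return [
        np.array(v)
        for v in ([0.07, 0.03], [0.35, 0.44], [0.52, 0.67], [0.83, 0.12], [0.95, 0.14])
    ]
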