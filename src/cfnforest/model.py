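"""Model/Results surface over the cascade trainer.

``CFNForest`` is constructed from data (an :class:`ExpressionMatrix` or a
pandas DataFrame plus labels), owns the preprocessing policy, and ``fit()``
returns a :class:`CFNForestResults` carrying the fitted cascade, its
training diagnostics and prediction/summary methods — the usual
model-then-results idiom of statistical modelling libraries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cascade import CascadeConfig, CascadeFitInfo, CascadeModel, fit_cascade
from .expression import (
    ExpressionMatrix,
    LabelSet,
    NormalizationStats,
    apply_normalization,
    filter_missing_samples,
    knn_impute,
    zscore_normalize,
)

__all__ = ["CFNForest", "CFNForestResults"]


class CFNForest:
    """Cascade flexible neural forest classifier bound to a dataset.

    Parameters
    ----------
    X : ExpressionMatrix
        Samples-by-genes expression values (missing entries allowed).
    y : LabelSet
        Per-sample class labels aligned with ``X``.
    config : CascadeConfig, optional
        Every training hyperparameter (forest size K, GP/PSO budgets,
        confidence region, stopping rule, ...); library defaults otherwise.
    missing_threshold, impute_k, divisor :
        Preprocessing policy: drop samples missing more than
        ``missing_threshold`` of their genes, KNN-impute with ``impute_k``
        neighbours, z-score per gene (``divisor="var"`` for the
        variance-division variant).
    """

    def __init__(
        self,
        X: ExpressionMatrix,
        y: LabelSet,
        config: CascadeConfig | None = None,
        missing_threshold: float = 0.20,
        impute_k: int = 5,
        divisor: str = "sd",
    ) -> None:
        if list(X.sample_ids) != list(y.sample_ids):
            raise ValueError("X and y sample IDs differ (order matters)")
        self.X = X
        self.y = y
        self.config = config or CascadeConfig()
        self.missing_threshold = missing_threshold
        self.impute_k = impute_k
        self.divisor = divisor

    @classmethod
    def from_dataframe(
        cls, X: pd.DataFrame, labels: pd.Series | list[str], **kwargs
    ) -> "CFNForest":
        """Build from a samples×genes DataFrame (NaN = missing) and labels."""
        Xm = ExpressionMatrix.from_dataframe(X)
        labs = list(labels)
        return cls(Xm, LabelSet(list(Xm.sample_ids), [str(l) for l in labs]), **kwargs)

    def fit(self, seed: int = 0) -> "CFNForestResults":
        Xf, removed = filter_missing_samples(self.X, self.missing_threshold)
        keep = [i for i, s in enumerate(self.X.sample_ids) if s in set(Xf.sample_ids)]
        y = self.y.subset(np.array(keep, dtype=int))
        if Xf.missing_mask.any():
            Xf = knn_impute(Xf, k=min(self.impute_k, Xf.n_samples - 1))
        Xn, stats = zscore_normalize(Xf, divisor=self.divisor)
        cascade, info = fit_cascade(Xn.values, y, self.config, seed=seed)
        return CFNForestResults(self, cascade, info, stats, removed)


@dataclass
class CFNForestResults:
    """A fitted cascade plus its preprocessing statistics and diagnostics."""

    model: CFNForest
    cascade: CascadeModel
    fit_info: CascadeFitInfo
    norm_stats: NormalizationStats
    removed_samples: list[str]

    @property
    def n_layers(self) -> int:
        return self.cascade.n_layers

    @property
    def layer_weights(self) -> np.ndarray:
        return self.cascade.layer_weights()

    @property
    def validation_accuracy(self) -> float:
        return self.fit_info.layer_val_accuracy[self.n_layers - 1]

    def _transform(self, X_new: ExpressionMatrix) -> np.ndarray:
        if X_new.missing_mask.any():
            X_new = knn_impute(
                X_new, k=min(self.model.impute_k, self.model.X.n_samples),
                reference=self.model.X,
            )
        return apply_normalization(X_new, self.norm_stats).values

    def predict(
        self, X_new: ExpressionMatrix | pd.DataFrame | np.ndarray
    ) -> tuple[list[str], np.ndarray]:
        """Class labels and fused score vectors for new samples.

        Raw arrays are assumed already preprocessed (z-scored); matrices and
        DataFrames go through imputation against the training samples and
        the stored normalization statistics.
        """
        if isinstance(X_new, pd.DataFrame):
            X_new = ExpressionMatrix.from_dataframe(X_new)
        if isinstance(X_new, ExpressionMatrix):
            Z = self._transform(X_new)
        else:
            Z = np.asarray(X_new, dtype=float)
        return self.cascade.predict(Z)

    def used_features(self) -> set[int]:
        out: set[int] = set()
        for layer in self.cascade.layers:
            for forest in layer.forests:
                out |= forest.used_features()
        return out

    def summary(self) -> str:
        info = self.fit_info
        lines = [
            "Cascade Flexible Neural Forest Results",
            "=" * 46,
            f"Classes:                {', '.join(self.cascade.codec.class_list)}",
            f"Code length L:          {self.cascade.codec.code_length}",
            f"Base features:          {self.cascade.base_input_dim}",
            f"Layers (trimmed):       {self.n_layers}",
            f"Groups per forest (K):  {self.cascade.layers[0].forests[0].n_groups}",
            f"Layer weights:          "
            + ", ".join(f"{w:.4f}" for w in self.layer_weights),
            f"Confidence region:      [0, {self.cascade.region.low}] U "
            f"[{self.cascade.region.high}, 1]",
            f"Train / validation n:   {info.n_train} / {info.n_validation}",
            f"Stopping:               {info.stopped_reason}",
            "-" * 46,
            "layer  val_accuracy  uncertain_train",
        ]
        for i, acc in enumerate(info.layer_val_accuracy, start=1):
            unc = info.uncertain_counts[i - 1] if i - 1 < len(info.uncertain_counts) else ""
            mark = " *" if i == self.n_layers else ""
            lines.append(f"{i:>5}  {acc:>12.4f}  {unc!s:>15}{mark}")
        lines.append("-" * 46)
        lines.append(
            "exit layer counts (train): "
            + ", ".join(f"{k}: {v}" for k, v in sorted(info.exit_counts.items()))
        )
        if self.removed_samples:
            lines.append(f"samples removed by missing filter: {len(self.removed_samples)}")
        return "\n".join(lines)

    def plot_layer_accuracy(self, ax=None):
        """Validation accuracy per cascade depth (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        depths = np.arange(1, len(self.fit_info.layer_val_accuracy) + 1)
        ax.plot(depths, self.fit_info.layer_val_accuracy, marker="o")
        ax.axvline(self.n_layers, ls="--", color="grey", label="retained depth")
        ax.set_xlabel("cascade depth")
        ax.set_ylabel("validation accuracy")
        ax.legend()
        return ax
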