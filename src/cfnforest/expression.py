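"""Expression-matrix I/O and preprocessing.

The preprocessing chain applied before any model fitting is

1. drop samples with more than 20% missing gene values,
2. fill the remaining gaps by K-nearest-neighbour imputation,
3. standardize each gene to zero mean and unit spread (z-score).

Normalization statistics are returned so held-out folds can be transformed
with training-fold statistics only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "NormalizationStats",
    "LabelSet",
    "read_expression",
    "write_expression",
    "read_labels",
    "write_labels",
    "filter_missing_samples",
    "knn_impute",
    "zscore_normalize",
    "apply_normalization",
    "preprocess",
]

_MISSING_TOKENS = {"", "NA", "na", "NaN", "nan", "NULL"}


@dataclass
class ExpressionMatrix:
    """A samples-by-genes real matrix with an explicit missing-value mask.

    ``values`` holds NaN at masked positions; ``missing_mask`` is the single
    source of truth for missingness.
    """

    sample_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray
    missing_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n, d = self.values.shape
        if len(self.sample_ids) != n or len(self.gene_ids) != d:
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.sample_ids)} sample IDs / {len(self.gene_ids)} gene IDs"
            )
        if self.missing_mask.shape != self.values.shape:
            raise ValueError("missing_mask shape differs from values shape")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample IDs")
        if len(set(self.gene_ids)) != d:
            raise ValueError("duplicate gene IDs")
        observed = ~self.missing_mask
        if not np.all(np.isfinite(self.values[observed])):
            raise ValueError("non-finite value in an observed (unmasked) cell")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            list(self.sample_ids),
            list(self.gene_ids),
            self.values.copy(),
            self.missing_mask.copy(),
        )

    def to_dataframe(self) -> pd.DataFrame:
        vals = self.values.copy()
        vals[self.missing_mask] = np.nan
        return pd.DataFrame(vals, index=self.sample_ids, columns=self.gene_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        values = df.to_numpy(dtype=float)
        mask = np.isnan(values)
        return cls(
            [str(s) for s in df.index],
            [str(g) for g in df.columns],
            values,
            mask,
        )


@dataclass
class NormalizationStats:
    """Per-gene location/scale fitted on training data and reused elsewhere."""

    gene_ids: list[str]
    mean: np.ndarray
    spread: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.spread = np.asarray(self.spread, dtype=float)
        if not (len(self.gene_ids) == self.mean.size == self.spread.size):
            raise ValueError("gene_ids, mean and spread must have equal lengths")
        if np.any(self.spread < 0):
            raise ValueError("spread must be nonnegative")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"gene_id": self.gene_ids, "mean": self.mean, "spread": self.spread}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "NormalizationStats":
        df = pd.read_csv(path)
        return cls(
            [str(g) for g in df["gene_id"]],
            df["mean"].to_numpy(),
            df["spread"].to_numpy(),
        )


@dataclass
class LabelSet:
    """Per-sample categorical labels with an explicit ordered class list."""

    sample_ids: list[str]
    labels: list[str]
    class_list: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.labels):
            raise ValueError("sample_ids and labels must have equal lengths")
        if not self.class_list:
            # first-appearance order keeps class codes reproducible
            seen: dict[str, None] = {}
            for lab in self.labels:
                seen.setdefault(lab, None)
            self.class_list = list(seen)
        unknown = set(self.labels) - set(self.class_list)
        if unknown:
            raise ValueError(f"labels not in class list: {sorted(unknown)}")
        if len(set(self.class_list)) != len(self.class_list):
            raise ValueError("duplicate classes in class list")
        if len(self.class_list) < 2:
            raise ValueError("at least two classes are required")

    @property
    def n_classes(self) -> int:
        return len(self.class_list)

    def class_indices(self) -> np.ndarray:
        lookup = {c: i for i, c in enumerate(self.class_list)}
        return np.array([lookup[lab] for lab in self.labels], dtype=int)

    def subset(self, idx: np.ndarray) -> "LabelSet":
        idx = np.asarray(idx, dtype=int)
        return LabelSet(
            [self.sample_ids[i] for i in idx],
            [self.labels[i] for i in idx],
            list(self.class_list),
        )


def read_expression(
    path: str | Path, delimiter: str = ",", transpose: bool = False
) -> ExpressionMatrix:
    """Read a delimited expression matrix.

    Expected layout: header row of gene IDs, first column of sample IDs;
    empty cells or ``NA`` denote missing values. ``transpose=True`` reads a
    genes-by-samples file; the in-memory orientation is always samples×genes.
    """
    path = Path(path)
    with path.open() as fh:
        lines = [ln.rstrip("\n").rstrip("\r") for ln in fh if ln.strip() != ""]
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = lines[0].split(delimiter)
    col_ids = [c.strip() for c in header[1:]]
    row_ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split(delimiter)
        if len(cells) != len(col_ids) + 1:
            raise ValueError(
                f"{path}: line {lineno} has {len(cells) - 1} values, "
                f"expected {len(col_ids)}"
            )
        row_ids.append(cells[0].strip())
        row = [
            np.nan if c.strip() in _MISSING_TOKENS else float(c) for c in cells[1:]
        ]
        rows.append(row)
    values = np.array(rows, dtype=float) if rows else np.empty((0, len(col_ids)))
    if transpose:
        values = values.T
        row_ids, col_ids = col_ids, row_ids
    return ExpressionMatrix(row_ids, col_ids, values, np.isnan(values))


def write_expression(
    X: ExpressionMatrix, path: str | Path, delimiter: str = ","
) -> None:
    """Write a matrix in the layout :func:`read_expression` reads (NA = missing)."""
    with Path(path).open("w") as fh:
        fh.write(delimiter.join(["sample_id", *X.gene_ids]) + "\n")
        for i, sid in enumerate(X.sample_ids):
            cells = [
                "NA" if X.missing_mask[i, j] else repr(float(X.values[i, j]))
                for j in range(X.n_genes)
            ]
            fh.write(delimiter.join([sid, *cells]) + "\n")


def read_labels(path: str | Path, delimiter: str = ",") -> LabelSet:
    df = pd.read_csv(path, delimiter=delimiter, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected columns (sample_id, label)")
    return LabelSet(list(df.iloc[:, 0]), list(df.iloc[:, 1]))


def write_labels(y: LabelSet, path: str | Path) -> None:
    pd.DataFrame({"sample_id": y.sample_ids, "label": y.labels}).to_csv(
        path, index=False
    )


def filter_missing_samples(
    X: ExpressionMatrix, threshold: float = 0.20
) -> tuple[ExpressionMatrix, list[str]]:
    """Drop samples whose missing fraction strictly exceeds ``threshold``.

    A sample missing exactly the threshold fraction is retained. The
    denominator is the total gene count before any filtering.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie strictly between 0 and 1")
    frac = X.missing_mask.mean(axis=1)
    keep = frac <= threshold
    removed = [s for s, k in zip(X.sample_ids, keep) if not k]
    if not keep.any():
        raise ValueError(
            "all samples exceed the missing-value threshold; relax the threshold"
        )
    kept = ExpressionMatrix(
        [s for s, k in zip(X.sample_ids, keep) if k],
        list(X.gene_ids),
        X.values[keep],
        X.missing_mask[keep],
    )
    return kept, removed


def _partial_distances(values: np.ndarray, mask: np.ndarray, target: int,
                       reference: np.ndarray, ref_mask: np.ndarray) -> np.ndarray:
    """Euclidean distance from row ``target`` to each reference row, computed
    over genes observed in both. Rows with no shared observed gene get inf."""
    obs_t = ~mask[target]
    shared = obs_t[None, :] & ~ref_mask  # (n_ref, d)
    diff = reference - values[target][None, :]
    diff = np.where(shared, diff, 0.0)
    d2 = np.einsum("ij,ij->i", diff, diff)
    n_shared = shared.sum(axis=1)
    d = np.sqrt(d2)
    d[n_shared == 0] = np.inf
    return d


def knn_impute(
    X: ExpressionMatrix, k: int = 5, reference: ExpressionMatrix | None = None
) -> ExpressionMatrix:
    """Fill missing cells with the mean of the k nearest samples.

    Distance is plain Euclidean over the genes observed in both rows.  For
    each missing cell the k nearest samples *that observe that gene* are
    averaged.  When ``reference`` is given (e.g. the training fold for a test
    fold), neighbours are drawn from it; otherwise neighbours are the other
    samples of ``X`` itself.  Observed entries are never altered.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    self_ref = reference is None
    ref = X if self_ref else reference
    if self_ref and k >= X.n_samples:
        raise ValueError("k must be smaller than the number of samples")
    if list(ref.gene_ids) != list(X.gene_ids):
        raise ValueError("reference gene set differs from target gene set")
    gene_all_missing = ref.missing_mask.all(axis=0)
    if gene_all_missing.any():
        bad = [g for g, m in zip(X.gene_ids, gene_all_missing) if m]
        raise ValueError(f"genes unobserved in every sample, cannot impute: {bad}")
    out = X.values.copy()
    for i in np.flatnonzero(X.missing_mask.any(axis=1)):
        d = _partial_distances(X.values, X.missing_mask, i, ref.values, ref.missing_mask)
        if self_ref:
            d[i] = np.inf
        order = np.argsort(d, kind="stable")
        for j in np.flatnonzero(X.missing_mask[i]):
            donors = [r for r in order if np.isfinite(d[r]) and not ref.missing_mask[r, j]]
            if not donors:
                raise ValueError(
                    f"no neighbour observes gene {X.gene_ids[j]!r} "
                    f"for sample {X.sample_ids[i]!r}"
                )
            out[i, j] = float(np.mean([ref.values[r, j] for r in donors[:k]]))
    return ExpressionMatrix(
        list(X.sample_ids), list(X.gene_ids), out, np.zeros_like(X.missing_mask)
    )


def zscore_normalize(
    X: ExpressionMatrix, divisor: str = "sd"
) -> tuple[ExpressionMatrix, NormalizationStats]:
    """Standardize each gene to (f − mean)/spread.

    ``divisor="sd"`` (default) uses the population standard deviation;
    ``divisor="var"`` divides by the variance instead, the literal printed
    form of the normalization. Zero-spread genes map to all-zero columns.
    """
    if X.missing_mask.any():
        raise ValueError("matrix contains missing values; impute before normalizing")
    if divisor not in ("sd", "var"):
        raise ValueError("divisor must be 'sd' or 'var'")
    mean = X.values.mean(axis=0)
    var = X.values.var(axis=0)  # population variance
    spread = np.sqrt(var) if divisor == "sd" else var
    stats = NormalizationStats(list(X.gene_ids), mean, spread)
    return apply_normalization(X, stats), stats


def apply_normalization(X: ExpressionMatrix, stats: NormalizationStats) -> ExpressionMatrix:
    """Apply previously fitted per-gene statistics (zero-spread genes → 0)."""
    if X.missing_mask.any():
        raise ValueError("matrix contains missing values; impute before normalizing")
    if list(stats.gene_ids) != list(X.gene_ids):
        raise ValueError("normalization stats fitted on a different gene set")
    safe = np.where(stats.spread == 0, 1.0, stats.spread)
    vals = (X.values - stats.mean) / safe
    vals[:, stats.spread == 0] = 0.0
    return ExpressionMatrix(
        list(X.sample_ids), list(X.gene_ids), vals, np.zeros_like(X.missing_mask)
    )


def preprocess(
    X: ExpressionMatrix,
    missing_threshold: float = 0.20,
    k: int = 5,
    divisor: str = "sd",
) -> tuple[ExpressionMatrix, NormalizationStats, list[str]]:
    """Full chain: missing-sample filter → KNN imputation → z-score."""
    Xf, removed = filter_missing_samples(X, missing_threshold)
    if Xf.missing_mask.any():
        Xf = knn_impute(Xf, k=min(k, max(1, Xf.n_samples - 1)))
    Xn, stats = zscore_normalize(Xf, divisor=divisor)
    return Xn, stats, removed
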