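"""Feature selection and normalization of gene-score matrices.

The classifier input space is built in three steps, applied to the
genes x cells score matrix:

1. **F-test feature selection** on the labeled reference: per gene, a one-way
   ANOVA F-statistic of the (log-normalized) score across the cell-type
   groups; the top ``k`` genes (default 3000) by F become the feature set.
2. **Cell-wise normalization**: each cell's scores over the selected genes
   are rescaled to sum to 10,000, then log(x+1)-transformed.
3. **Gene-wise standardization**: each gene is centered to zero mean and
   scaled to unit variance (population standard deviation).

Reference and target are standardized independently by default — each
dataset with its own per-gene statistics — which removes gross gene-wise
location/scale shift between them; ``standardize_with_ref_stats`` applies the
reference statistics to the target instead.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy import stats
from sklearn.base import BaseEstimator

from .io import GeneScoreMatrix, LabelVector

logger = logging.getLogger(__name__)


@dataclass
class FeatureSet:
    """Genes selected for classification, ordered by descending F-statistic."""

    gene_names: np.ndarray
    f_statistics: np.ndarray
    selection_k: int

    def __post_init__(self) -> None:
        self.gene_names = np.asarray(self.gene_names, dtype=object)
        self.f_statistics = np.asarray(self.f_statistics, dtype=float)
        if len(self.gene_names) != len(self.f_statistics):
            raise ValueError("gene_names and f_statistics length mismatch")

    def __len__(self) -> int:
        return len(self.gene_names)

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"gene": self.gene_names, "F": self.f_statistics}).to_csv(
            path, sep="\t", index=False, float_format="%.10g"
        )

    @classmethod
    def from_tsv(cls, path) -> "FeatureSet":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", dtype={"gene": str})
        return cls(df["gene"].to_numpy(), df["F"].to_numpy(float), len(df))


@dataclass
class StandardizationStats:
    """Per-gene mean/sd of log-normalized scores for one dataset."""

    mean: np.ndarray
    sd: np.ndarray
    tag: str = "reference"


def _dense(m: GeneScoreMatrix | np.ndarray) -> np.ndarray:
    if isinstance(m, GeneScoreMatrix):
        return m.toarray()
    if sp.issparse(m):
        return m.toarray()
    return np.asarray(m, dtype=float)


def normalize_cells(m: GeneScoreMatrix, scale: float = 10_000.0) -> GeneScoreMatrix:
    """Rescale each cell to total score ``scale``, then log(x+1)-transform.

    All-zero cells cannot be rescaled; they pass through as zero columns with
    a warning (quality filtering is upstream of this package).
    """
    if sp.issparse(m.values):
        X = m.values.tocsc(copy=True).astype(float)
        colsum = np.asarray(X.sum(axis=0)).ravel()
        zero_cols = colsum == 0
        factors = np.where(zero_cols, 0.0, scale / np.where(zero_cols, 1.0, colsum))
        X = X @ sp.diags(factors)
        X.data = np.log1p(X.data)
    else:
        X = np.array(m.values, dtype=float)
        colsum = X.sum(axis=0)
        zero_cols = colsum == 0
        X = np.log1p(X * np.where(zero_cols, 0.0, scale / np.where(zero_cols, 1.0, colsum)))
    if zero_cols.any():
        warnings.warn(
            f"{int(zero_cols.sum())} all-zero cell(s) left as zeros during normalization",
            UserWarning,
            stacklevel=2,
        )
    return GeneScoreMatrix(X, m.gene_names, m.barcodes)


def f_test_select(
    ref: GeneScoreMatrix,
    labels: LabelVector,
    k: int = 3000,
    space: str = "lognorm",
) -> FeatureSet:
    """Select the top-``k`` cell-type-informative genes by one-way ANOVA F-test.

    Parameters
    ----------
    ref : GeneScoreMatrix
        Reference scores, columns aligned with ``labels`` (same order).
    labels : LabelVector
        Cell-type label per reference cell; every type needs >= 2 cells.
    k : int
        Number of genes to keep. If ``k`` exceeds the gene count all genes
        are returned with a warning.
    space : {"lognorm", "raw"}
        Whether the F-statistic is computed on log-normalized scores
        (default; robust to per-cell depth) or on the raw scores.

    Notes
    -----
    Constant genes have an undefined 0/0 F-ratio and are assigned F=0 so
    they rank last. Genes with zero within-group but positive between-group
    variance separate the groups perfectly; their infinite F is clamped to
    the largest finite float so they rank first. Ties are broken by input
    gene order.
    """
    if ref.n_cells != len(labels):
        raise ValueError("reference matrix and labels are not aligned")
    if k < 1:
        raise ValueError("k must be >= 1")
    if space not in ("lognorm", "raw"):
        raise ValueError(f"unknown F-test space {space!r}")
    classes, counts = np.unique(labels.labels, return_counts=True)
    for cls, cnt in zip(classes, counts):
        if cnt < 2:
            raise ValueError(f"cell type {cls!r} has fewer than 2 cells")
    X = _dense(normalize_cells(ref) if space == "lognorm" else ref)

    groups = [X[:, labels.labels == cls] for cls in classes]
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant-input warnings handled below
        F, _ = stats.f_oneway(*groups, axis=1)
    F = np.asarray(F, dtype=float)
    F[np.isnan(F)] = 0.0  # constant genes: 0/0 defined as 0, rank last
    F[np.isinf(F)] = np.finfo(float).max  # perfect separators rank first

    if k > ref.n_genes:
        warnings.warn(
            f"k={k} exceeds the {ref.n_genes} available genes; returning all",
            UserWarning,
            stacklevel=2,
        )
        k = ref.n_genes
    order = np.argsort(-F, kind="stable")[:k]
    return FeatureSet(ref.gene_names[order], F[order], k)


def standardize_genes(m: GeneScoreMatrix) -> tuple[GeneScoreMatrix, StandardizationStats]:
    """Center and scale each gene to zero mean / unit variance (population sd).

    Constant genes (sd == 0) map to all-zero rows.
    """
    X = _dense(m)
    mean = X.mean(axis=1)
    sd = X.std(axis=1)  # population (1/n) convention
    safe_sd = np.where(sd == 0, 1.0, sd)
    Z = (X - mean[:, None]) / safe_sd[:, None]
    Z[sd == 0, :] = 0.0
    return (
        GeneScoreMatrix(Z, m.gene_names, m.barcodes, allow_negative=True),
        StandardizationStats(mean, sd),
    )


def align_to_features(m: GeneScoreMatrix, fs: FeatureSet) -> GeneScoreMatrix:
    """Reorder rows of ``m`` to the feature set, zero-filling absent genes.

    Raises if more than half the features are missing from ``m`` — with that
    little overlap a model trained on the feature set is not applicable.
    """
    index = {g: i for i, g in enumerate(m.gene_names)}
    rows = np.array([index.get(g, -1) for g in fs.gene_names])
    missing = rows < 0
    frac = missing.mean() if len(rows) else 0.0
    if frac > 0.5:
        raise ValueError(
            f"{frac:.0%} of the {len(fs)} model features are absent from the matrix"
        )
    if missing.any():
        logger.warning("%.1f%% of features missing; zero-filling", 100 * frac)
    X = _dense(m)
    out = np.zeros((len(fs), m.n_cells))
    out[~missing] = X[rows[~missing]]
    return GeneScoreMatrix(out, fs.gene_names, m.barcodes)


def align_cells(m: GeneScoreMatrix, labels: LabelVector) -> tuple[GeneScoreMatrix, LabelVector]:
    """Join a matrix with a label table on barcodes, keeping the intersection
    in matrix column order."""
    label_map = dict(zip(labels.barcodes, labels.labels))
    keep = np.array([bc in label_map for bc in m.barcodes])
    if not keep.any():
        raise ValueError("no barcodes shared between matrix and labels")
    if not keep.all():
        logger.warning("dropping %d matrix cells without labels", int((~keep).sum()))
    X = m.toarray()[:, keep] if not sp.issparse(m.values) else m.values[:, keep]
    barcodes = m.barcodes[keep]
    sub = GeneScoreMatrix(X, m.gene_names, barcodes)
    return sub, LabelVector(barcodes, np.array([label_map[b] for b in barcodes], dtype=object))


class GeneScorePreprocessor(BaseEstimator):
    """Fit the feature set and reference statistics; map matrices to model space.

    ``fit`` selects features on the labeled reference and records its
    standardization statistics. ``transform`` aligns a matrix to the feature
    set, normalizes cells and standardizes genes, returning a cells x features
    array ready for the classifiers. By default each transformed dataset is
    standardized with its own statistics (see module docstring).

    Attributes
    ----------
    feature_set_ : FeatureSet
    ref_stats_ : StandardizationStats
    missing_fraction_ : float
        Fraction of features absent from the most recently transformed matrix.
    """

    def __init__(
        self,
        n_features: int = 3000,
        scale: float = 10_000.0,
        ftest_space: str = "lognorm",
        standardize_with_ref_stats: bool = False,
    ):
        self.n_features = n_features
        self.scale = scale
        self.ftest_space = ftest_space
        self.standardize_with_ref_stats = standardize_with_ref_stats

    def fit(self, ref: GeneScoreMatrix, labels: LabelVector) -> "GeneScorePreprocessor":
        self.feature_set_ = f_test_select(ref, labels, k=self.n_features, space=self.ftest_space)
        aligned = align_to_features(ref, self.feature_set_)
        lognorm = normalize_cells(aligned, scale=self.scale)
        _, self.ref_stats_ = standardize_genes(lognorm)
        self.ref_stats_.tag = "reference"
        self.missing_fraction_ = 0.0
        return self

    def transform(self, m: GeneScoreMatrix, use_ref_stats: bool | None = None) -> np.ndarray:
        """Return the standardized cells x features array for ``m``."""
        if not hasattr(self, "feature_set_"):
            raise RuntimeError("preprocessor is not fitted")
        aligned = align_to_features(m, self.feature_set_)
        present = set(map(str, m.gene_names))
        self.missing_fraction_ = float(
            np.mean([str(g) not in present for g in self.feature_set_.gene_names])
        )
        lognorm = normalize_cells(aligned, scale=self.scale)
        if use_ref_stats is None:
            use_ref_stats = self.standardize_with_ref_stats
        if use_ref_stats:
            stats_ = self.ref_stats_
            X = _dense(lognorm)
            sd = np.where(stats_.sd == 0, 1.0, stats_.sd)
            Z = (X - stats_.mean[:, None]) / sd[:, None]
            Z[stats_.sd == 0, :] = 0.0
        else:
            std, _ = standardize_genes(lognorm)
            Z = std.toarray()
        return Z.T  # cells x features

    def fit_transform(self, ref: GeneScoreMatrix, labels: LabelVector) -> np.ndarray:
        """Fit on the reference and return its standardized array (own stats)."""
        self.fit(ref, labels)
        return self.transform(ref, use_ref_stats=False)
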