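"""The two-round annotation pipeline.

Round 1 trains an MLP on the labeled reference and predicts the target.
If the target is small (<= ``gate`` cells, default 1000) the argmax labels
are returned as-is. Otherwise the per-cell prediction entropy

    E_i = -sum_k q_ik log q_ik

ranks target cells by confidence; the ``quantile_cutoff`` fraction (default
0.4) with the lowest entropy become *anchors*. Their argmax pseudo-labels —
noisy but drawn from the target's own distribution — train a second-round
knowledge-distillation model after class-balancing by oversampling, and the
student re-predicts the non-anchors. Anchors keep their round-1 labels;
non-anchors take the student's calls.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import GeneScoreMatrix, LabelVector
from .models import KDClassifier, KDConfig, MLPConfig, TemperedMLP
from .preprocess import GeneScorePreprocessor, standardize_genes
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)


def compute_entropy(q: np.ndarray) -> np.ndarray:
    """Shannon entropy (nats) of each row of a row-stochastic matrix.

    ``0 * log 0`` is taken as 0, so one-hot rows have entropy exactly 0 and
    every value lies in ``[0, log K]``.
    """
    from scipy.special import xlogy

    q = np.atleast_2d(np.asarray(q, dtype=float))
    return -xlogy(q, q).sum(axis=1) + 0.0  # +0.0 normalizes -0.0 on one-hot rows


@dataclass
class AnchorSet:
    """Anchor indices with their pseudo-labels and oversampled multiset."""

    indices: np.ndarray  # pre-oversampling anchor cell indices (into target)
    pseudo_labels: np.ndarray  # first-round argmax label per anchor
    oversampled_indices: np.ndarray  # multiset actually used for KD training
    quantile_cutoff: float = 0.4

    def __len__(self) -> int:
        return len(self.indices)


def select_anchors(
    q: np.ndarray,
    E: np.ndarray,
    class_names: np.ndarray,
    quantile_cutoff: float = 0.4,
    per_type: bool = False,
) -> AnchorSet:
    """Pick the lowest-entropy target cells as anchors.

    Global mode (default) takes the ``floor(quantile_cutoff * M)`` cells of
    lowest entropy over the whole target; ties at the boundary are broken by
    cell order (stable sort). ``per_type=True`` instead applies the quantile
    within each first-round predicted type. Pseudo-labels are the argmax of
    ``q`` per anchor.
    """
    if not (0 < quantile_cutoff < 1):
        raise ValueError("quantile_cutoff must be in (0, 1)")
    q = np.atleast_2d(np.asarray(q, dtype=float))
    E = np.asarray(E, dtype=float)
    M = len(E)
    pred = np.asarray(class_names, dtype=object)[q.argmax(axis=1)]
    if per_type:
        chosen: list[int] = []
        for cls in np.unique(pred):
            idx = np.flatnonzero(pred == cls)
            n_cls = math.floor(quantile_cutoff * len(idx))
            order = idx[np.argsort(E[idx], kind="stable")]
            chosen.extend(order[:n_cls].tolist())
        indices = np.sort(np.asarray(chosen, dtype=int))
    else:
        n_anchor = math.floor(quantile_cutoff * M)
        indices = np.sort(np.argsort(E, kind="stable")[:n_anchor])
    return AnchorSet(indices, pred[indices], indices.copy(), quantile_cutoff)


def oversample_anchors(a: AnchorSet, seed: int | np.random.Generator = 2022) -> AnchorSet:
    """Balance anchor classes by oversampling minorities up to the mean count.

    The target count is the mean number of anchors per predicted type,
    rounded up; each type below it is augmented by sampling its own anchors
    with replacement. Types at or above the mean are left untouched.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    classes, counts = np.unique(a.pseudo_labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("oversampling requires >= 2 anchor classes")
    mean_count = math.ceil(counts.mean())
    extra: list[np.ndarray] = []
    for cls, cnt in zip(classes, counts):
        if cnt < mean_count:
            pool = a.indices[a.pseudo_labels == cls]
            extra.append(rng.choice(pool, size=mean_count - cnt, replace=True))
    oversampled = np.concatenate([a.indices, *extra]) if extra else a.indices.copy()
    return AnchorSet(a.indices, a.pseudo_labels, oversampled, a.quantile_cutoff)


@dataclass
class PredictionResult:
    """Per-cell calls plus the provenance needed to reproduce them."""

    barcodes: np.ndarray
    final_labels: np.ndarray
    first_round_labels: np.ndarray
    proba: np.ndarray  # first-round probabilities, cells x K
    class_names: np.ndarray
    entropy: np.ndarray
    is_anchor: np.ndarray
    n_rounds: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.barcodes)
        for name in ("final_labels", "first_round_labels", "entropy", "is_anchor"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length != number of cells")
        if self.proba.shape != (n, len(self.class_names)):
            raise ValueError("proba shape does not match cells x classes")


class TwoRoundAnnotator(BaseEstimator):
    """Supervised cell-type annotator with entropy anchors and distillation.

    ``fit`` runs preprocessing (F-test feature selection, normalization,
    standardization) and first-round MLP training on the reference;
    ``annotate`` executes the full prediction pipeline on a target matrix.

    Parameters
    ----------
    n_features : int
        Genes kept by F-test feature selection.
    quantile_cutoff : float
        Entropy quantile below which target cells become anchors.
    gate : int
        Second round runs only when the target exceeds this many cells.
    two_round : bool
        Master switch; ``False`` forces one-round annotation.
    epochs, batch_size, learning_rate, hidden_sizes, dropout_rate
        Round-1 MLP settings (the KD pair reuses the architecture).
    kd_alpha, kd_T1, kd_T2, kd_epochs, kd_t2_square
        Distillation settings.
    ftest_space, standardize_with_ref_stats, per_type_quantile
        Preprocessing / anchor-selection variants.
    random_state : int
        Seeds everything: round-1 training, oversampling (+1 offset) and KD
        training (+2 offset).
    """

    def __init__(
        self,
        n_features: int = 3000,
        quantile_cutoff: float = 0.4,
        gate: int = 1000,
        two_round: bool = True,
        hidden_sizes: tuple[int, ...] = (64, 16),
        dropout_rate: float = 0.1,
        epochs: int = 50,
        batch_size: int = 32,
        learning_rate: float = 1e-3,
        patience: int | None = 5,
        kd_alpha: float = 0.1,
        kd_T1: float = 1.0,
        kd_T2: float = 3.0,
        kd_epochs: int = 30,
        kd_t2_square: bool = False,
        ftest_space: str = "lognorm",
        standardize_with_ref_stats: bool = False,
        per_type_quantile: bool = False,
        random_state: int = 2022,
    ):
        self.n_features = n_features
        self.quantile_cutoff = quantile_cutoff
        self.gate = gate
        self.two_round = two_round
        self.hidden_sizes = hidden_sizes
        self.dropout_rate = dropout_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.patience = patience
        self.kd_alpha = kd_alpha
        self.kd_T1 = kd_T1
        self.kd_T2 = kd_T2
        self.kd_epochs = kd_epochs
        self.kd_t2_square = kd_t2_square
        self.ftest_space = ftest_space
        self.standardize_with_ref_stats = standardize_with_ref_stats
        self.per_type_quantile = per_type_quantile
        self.random_state = random_state

    # -- round 1 -----------------------------------------------------------

    def fit(self, ref: GeneScoreMatrix, labels: LabelVector) -> "TwoRoundAnnotator":
        if ref.n_cells != len(labels):
            raise ValueError("reference matrix and labels are not aligned")
        self.preprocessor_ = GeneScorePreprocessor(
            n_features=self.n_features,
            ftest_space=self.ftest_space,
            standardize_with_ref_stats=self.standardize_with_ref_stats,
        )
        X_ref = self.preprocessor_.fit_transform(ref, labels)
        self.mlp_ = TemperedMLP(
            hidden_sizes=self.hidden_sizes, dropout_rate=self.dropout_rate,
            epochs=self.epochs, batch_size=self.batch_size,
            learning_rate=self.learning_rate, temperature=1.0,
            patience=self.patience, random_state=self.random_state,
        ).fit(X_ref, labels.labels)
        self.classes_ = self.mlp_.classes_
        return self

    # -- full pipeline -----------------------------------------------------

    def annotate(self, target: GeneScoreMatrix) -> PredictionResult:
        """Run first-round prediction plus, when gated in, the KD round."""
        if not hasattr(self, "mlp_"):
            raise RuntimeError("annotator is not fitted")
        if target.n_cells == 0:
            raise ValueError("target matrix has no cells")
        M = target.n_cells

        # target is aligned to the reference feature set and, by default,
        # standardized on its own statistics (shift removal)
        aligned_lognorm = self._aligned_lognorm(target)
        X_tgt = self._standardize_cols(aligned_lognorm, np.arange(M))
        proba = self.mlp_.predict_proba(X_tgt)
        first_round = self.classes_[proba.argmax(axis=1)]
        entropy = compute_entropy(proba)

        provenance = {
            "params": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in self.get_params().items()},
            "n_target_cells": int(M),
            "n_features": int(len(self.preprocessor_.feature_set_)),
            "missing_feature_fraction": float(self.preprocessor_.missing_fraction_),
        }

        run_second = self.two_round and M > self.gate
        provenance["gate_triggered_second_round"] = bool(run_second)
        if not run_second:
            return PredictionResult(
                target.barcodes, first_round.copy(), first_round, proba,
                self.classes_, entropy, np.zeros(M, dtype=bool), 1, provenance,
            )

        anchors = select_anchors(
            proba, entropy, self.classes_,
            quantile_cutoff=self.quantile_cutoff, per_type=self.per_type_quantile,
        )
        if len(np.unique(anchors.pseudo_labels)) < 2:
            warnings.warn(
                "anchors collapse to a single predicted type; "
                "falling back to one-round annotation", UserWarning,
            )
            provenance["second_round_fallback"] = "single-class anchors"
            return PredictionResult(
                target.barcodes, first_round.copy(), first_round, proba,
                self.classes_, entropy, np.zeros(M, dtype=bool), 1, provenance,
            )
        anchors = oversample_anchors(anchors, seed=self.random_state + 1)
        counts = {str(c): int(n) for c, n in
                  zip(*np.unique(anchors.pseudo_labels, return_counts=True))}
        logger.info("anchor counts per type: %s", counts)
        provenance["anchor_counts"] = counts
        provenance["n_anchors"] = int(len(anchors))

        is_anchor = np.zeros(M, dtype=bool)
        is_anchor[anchors.indices] = True
        non_anchor_idx = np.flatnonzero(~is_anchor)

        # the second round lives in the target's own standardized space:
        # anchors and non-anchors belong to the same batch, so they share the
        # whole-target statistics rather than being re-standardized apart
        X_train = X_tgt[anchors.oversampled_indices]
        train_labels = anchors.pseudo_labels[
            np.searchsorted(anchors.indices, anchors.oversampled_indices)
        ]
        # teacher and student warm-start from the round-1 weights: the second
        # round fine-tunes toward the target domain instead of relearning
        # everything from a few hundred anchors
        student = KDClassifier(
            hidden_sizes=self.hidden_sizes, dropout_rate=self.dropout_rate,
            alpha=self.kd_alpha, T1=self.kd_T1, T2=self.kd_T2,
            epochs=self.kd_epochs, batch_size=self.batch_size,
            learning_rate=self.learning_rate, t2_square=self.kd_t2_square,
            init_weights=self.mlp_.core_.get_weights(),
            init_classes=self.classes_,
            random_state=self.random_state + 2,
        ).fit(X_train, train_labels)
        self.kd_ = student

        final = first_round.copy()
        if len(non_anchor_idx):
            final[non_anchor_idx] = student.predict(X_tgt[non_anchor_idx])
        return PredictionResult(
            target.barcodes, final, first_round, proba,
            self.classes_, entropy, is_anchor, 2, provenance,
        )

    def predict(self, target: GeneScoreMatrix) -> np.ndarray:
        return self.annotate(target).final_labels

    def predict_proba(self, target: GeneScoreMatrix) -> np.ndarray:
        """First-round probability matrix for the target."""
        aligned = self._aligned_lognorm(target)
        X = self._standardize_cols(aligned, np.arange(target.n_cells))
        return self.mlp_.predict_proba(X)

    # -- helpers -----------------------------------------------------------

    def _aligned_lognorm(self, m: GeneScoreMatrix) -> GeneScoreMatrix:
        from .preprocess import align_to_features, normalize_cells

        aligned = align_to_features(m, self.preprocessor_.feature_set_)
        present = set(map(str, m.gene_names))
        self.preprocessor_.missing_fraction_ = float(
            np.mean([str(g) not in present
                     for g in self.preprocessor_.feature_set_.gene_names])
        )
        return normalize_cells(aligned)

    def _standardize_cols(self, lognorm: GeneScoreMatrix, cols: np.ndarray) -> np.ndarray:
        """Standardize the selected cell columns as their own dataset and
        return them as cells x features (or apply reference stats if the
        annotator is configured that way)."""
        sub = GeneScoreMatrix(
            lognorm.toarray()[:, cols],
            lognorm.gene_names,
            [f"c{i}_{j}" for j, i in enumerate(cols)],
        )
        if self.standardize_with_ref_stats:
            stats = self.preprocessor_.ref_stats_
            sd = np.where(stats.sd == 0, 1.0, stats.sd)
            Z = (sub.toarray() - stats.mean[:, None]) / sd[:, None]
            Z[stats.sd == 0, :] = 0.0
            return Z.T
        std, _ = standardize_genes(sub)
        return std.toarray().T


def run_two_round(
    ref: GeneScoreMatrix,
    labels: LabelVector,
    target: GeneScoreMatrix,
    config: dict | None = None,
    **params,
) -> PredictionResult:
    """One-call pipeline: fit on the reference, annotate the target.

    ``config`` (a dict of :class:`TwoRoundAnnotator` parameters) and keyword
    overrides are merged, keywords winning.
    """
    merged = dict(config or {})
    merged.update(params)
    annotator = TwoRoundAnnotator(**merged)
    annotator.fit(ref, labels)
    return annotator.annotate(target)
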