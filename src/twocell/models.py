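"""First-round MLP and second-round teacher-student distillation classifiers.

Both rounds use the same light architecture: an input-dropout layer followed
by two ReLU hidden layers of 64 and 16 units and a linear output mapped to
probabilities by a tempered softmax

    sigma(z)_k = exp(z_k / T) / sum_j exp(z_j / T),

where the temperature ``T`` controls how smooth the distribution is (T=1 for
ordinary softmax; larger T yields softer probabilities).

The first round minimizes cross-entropy ``H(p, sigma(Z))`` against one-hot
labels. The second round is a *self*-knowledge-distillation pair: a teacher
MLP is trained with cross-entropy on the (noisy) anchor pseudo-labels, and a
student of identical architecture minimizes

    L_KD = alpha * H(p, q_s^{T1}) + (1 - alpha) * KL(q_t^{T2} || q_s^{T2}),

a weighted average of the hard-label cross-entropy (student probabilities at
temperature T1) and the KL divergence from the teacher's softened
probabilities at temperature T2. Defaults: alpha=0.1, T1=1, T2=3, 30 epochs
— weighting the teacher's soft labels heavily, which is what makes the
student tolerant of mislabeled anchors. As printed above, the KL term
carries no T2^2 gradient-scale factor; ``t2_square=True`` restores the
classic rescaling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array

from ._mlp import MLPCore, softmax_rows, train_loop
from .io import LabelVector
from .preprocess import FeatureSet, StandardizationStats

_EPS = 1e-12  # probability clip inside logs


# ---------------------------------------------------------------------------
# Configs
# ---------------------------------------------------------------------------

@dataclass
class MLPConfig:
    """Hyperparameters of one MLP classifier."""

    hidden_sizes: tuple[int, ...] = (64, 16)
    dropout_rate: float = 0.1
    epochs: int = 50
    batch_size: int = 32
    learning_rate: float = 1e-3
    temperature: float = 1.0
    patience: int | None = 5  # early stop on training-loss plateau; None disables

    def __post_init__(self) -> None:
        if any(h <= 0 for h in self.hidden_sizes):
            raise ValueError("hidden sizes must be positive")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")


@dataclass
class KDConfig:
    """Hyperparameters of the distillation round."""

    alpha: float = 0.1
    T1: float = 1.0
    T2: float = 3.0
    epochs: int = 30
    t2_square: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.alpha <= 1):
            raise ValueError("alpha must be in [0, 1]")
        if self.T1 <= 0 or self.T2 <= 0:
            raise ValueError("temperatures must be > 0")


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def tempered_softmax(Z: np.ndarray, T: float = 1.0) -> np.ndarray:
    """Row-stochastic tempered softmax of a logits matrix.

    Computed with row-max subtraction for overflow safety; shift-invariant
    in the logits.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if not np.isfinite(Z).all():
        raise ValueError("logits must be finite")
    return softmax_rows(Z, T)


def cross_entropy(p: np.ndarray, q: np.ndarray, reduction: str = "mean") -> float:
    """Cross-entropy ``-sum_i sum_k p_ik log q_ik`` between one-hot targets
    and predicted probabilities (clipped at 1e-12).

    ``reduction="mean"`` (default, used for reporting and optimization)
    averages over cells; ``"sum"`` returns the raw double sum.
    """
    p = np.atleast_2d(np.asarray(p, dtype=float))
    q = np.atleast_2d(np.asarray(q, dtype=float))
    if p.shape != q.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {q.shape}")
    total = -(p * np.log(np.clip(q, _EPS, None))).sum()
    return float(total / p.shape[0]) if reduction == "mean" else float(total)


def _kl_rows(a: np.ndarray, b: np.ndarray) -> float:
    """Mean over rows of KL(a || b) = sum_k a_k log(a_k / b_k)."""
    a = np.clip(a, _EPS, None)
    b = np.clip(b, _EPS, None)
    return float((a * (np.log(a) - np.log(b))).sum(axis=1).mean())


def kd_loss(
    hard: np.ndarray,
    teacher_logits: np.ndarray,
    student_logits: np.ndarray,
    cfg: KDConfig | None = None,
) -> float:
    """Distillation loss: ``alpha*CE(hard, q_s^T1) + (1-alpha)*KL(q_t^T2 || q_s^T2)``."""
    cfg = cfg or KDConfig()
    hard = np.atleast_2d(np.asarray(hard, dtype=float))
    t = np.atleast_2d(np.asarray(teacher_logits, dtype=float))
    s = np.atleast_2d(np.asarray(student_logits, dtype=float))
    if not (hard.shape == t.shape == s.shape):
        raise ValueError("hard labels, teacher and student logits must share a shape")
    ce = cross_entropy(hard, tempered_softmax(s, cfg.T1))
    kl = _kl_rows(tempered_softmax(t, cfg.T2), tempered_softmax(s, cfg.T2))
    scale = cfg.T2**2 if cfg.t2_square else 1.0
    return cfg.alpha * ce + (1.0 - cfg.alpha) * scale * kl


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

def _as_label_array(y) -> np.ndarray:
    if isinstance(y, LabelVector):
        return y.labels
    return np.asarray(y, dtype=object)


def _one_hot(y: np.ndarray, classes: np.ndarray) -> np.ndarray:
    index = {c: i for i, c in enumerate(classes)}
    P = np.zeros((len(y), len(classes)))
    for i, lab in enumerate(y):
        P[i, index[lab]] = 1.0
    return P


class TemperedMLP(ClassifierMixin, BaseEstimator):
    """MLP classifier with input dropout and a tempered softmax head.

    Parameters mirror :class:`MLPConfig`; ``random_state`` seeds weight
    initialization, batch shuffling and dropout masks, making training
    bit-reproducible on one machine.

    Attributes
    ----------
    classes_ : ndarray of class labels in output-column order
    loss_curve_ : list of per-epoch mean training cross-entropy
    core_ : the underlying weight container
    """

    def __init__(
        self,
        hidden_sizes: tuple[int, ...] = (64, 16),
        dropout_rate: float = 0.1,
        epochs: int = 50,
        batch_size: int = 32,
        learning_rate: float = 1e-3,
        temperature: float = 1.0,
        patience: int | None = 5,
        random_state: int = 2022,
    ):
        self.hidden_sizes = hidden_sizes
        self.dropout_rate = dropout_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.temperature = temperature
        self.patience = patience
        self.random_state = random_state

    def _config(self) -> MLPConfig:
        return MLPConfig(
            hidden_sizes=tuple(self.hidden_sizes),
            dropout_rate=self.dropout_rate,
            epochs=self.epochs,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            temperature=self.temperature,
            patience=self.patience,
        )

    def fit(self, X, y, classes: Sequence | None = None,
            init_weights: dict | None = None,
            allow_absent_classes: bool = False) -> "TemperedMLP":
        cfg = self._config()
        X = check_array(X, dtype=float)
        y = _as_label_array(y)
        if len(y) != X.shape[0]:
            raise ValueError("X and y have different numbers of cells")
        present = np.unique(y)
        if classes is not None:
            classes = np.asarray(list(classes), dtype=object)
            missing = set(classes) - set(present)
            if missing and not allow_absent_classes:
                raise ValueError(f"class(es) absent from training labels: {sorted(missing)}")
            self.classes_ = classes
        else:
            self.classes_ = present
        P = _one_hot(y, self.classes_)
        rng = np.random.default_rng(self.random_state)
        self.core_ = MLPCore(X.shape[1], cfg.hidden_sizes, len(self.classes_), rng)
        if init_weights is not None:
            self.core_.set_weights(init_weights)
        T = cfg.temperature

        def grad_fn(logits, idx):
            probs = softmax_rows(logits, T)
            target = P[idx]
            loss = cross_entropy(target, probs)
            return (probs - target) / (T * len(idx)), loss

        self.loss_curve_ = train_loop(
            self.core_, X, grad_fn,
            epochs=cfg.epochs, batch_size=cfg.batch_size,
            learning_rate=cfg.learning_rate, dropout=cfg.dropout_rate,
            rng=rng, patience=cfg.patience,
        )
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X) -> np.ndarray:
        X = check_array(X, dtype=float)
        if X.shape[1] != self.core_.n_in:
            raise ValueError(
                f"X has {X.shape[1]} features; model expects {self.core_.n_in}"
            )
        logits, _ = self.core_.forward(X)  # dropout off at inference
        return logits

    def predict_proba(self, X) -> np.ndarray:
        return softmax_rows(self.decision_function(X), self.temperature)

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]


class KDClassifier(ClassifierMixin, BaseEstimator):
    """Self-distillation classifier for noisily labeled training data.

    A teacher :class:`TemperedMLP` is trained with plain cross-entropy
    (T=1) on the pseudo-labels; its logits, softened at ``T2``, become the
    student's soft targets. The student (identical architecture, its own
    initialization seeded at ``random_state + 1``) minimizes the weighted
    KD loss for ``epochs`` epochs. Predictions come from the student at
    temperature ``T1``.

    The teacher is optimized at T=1 and softened only when its soft targets
    are produced; softening during teacher training is not part of this
    model.

    ``init_weights`` optionally warm-starts both networks from an existing
    model of the same architecture (the annotation pipeline passes the
    first-round weights, so the second round fine-tunes toward the target
    domain instead of relearning from a few hundred anchors); by default
    both are freshly initialized.
    """

    def __init__(
        self,
        hidden_sizes: tuple[int, ...] = (64, 16),
        dropout_rate: float = 0.1,
        alpha: float = 0.1,
        T1: float = 1.0,
        T2: float = 3.0,
        epochs: int = 30,
        batch_size: int = 32,
        learning_rate: float = 1e-3,
        t2_square: bool = False,
        init_weights: dict | None = None,
        init_classes: Sequence | None = None,
        random_state: int = 2022,
    ):
        self.hidden_sizes = hidden_sizes
        self.dropout_rate = dropout_rate
        self.alpha = alpha
        self.T1 = T1
        self.T2 = T2
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.t2_square = t2_square
        self.init_weights = init_weights
        self.init_classes = init_classes
        self.random_state = random_state

    def fit(self, X, y, classes: Sequence | None = None) -> "KDClassifier":
        kd = KDConfig(alpha=self.alpha, T1=self.T1, T2=self.T2,
                      epochs=self.epochs, t2_square=self.t2_square)
        X = check_array(X, dtype=float)
        y = _as_label_array(y)
        if len(np.unique(y)) < 2 and classes is None:
            raise ValueError("distillation requires >= 2 classes among the pseudo-labels")
        if classes is None and self.init_classes is not None:
            classes = self.init_classes
        self.teacher_ = TemperedMLP(
            hidden_sizes=self.hidden_sizes, dropout_rate=self.dropout_rate,
            epochs=self.epochs, batch_size=self.batch_size,
            learning_rate=self.learning_rate, temperature=1.0,
            patience=None, random_state=self.random_state,
        ).fit(X, y, classes=classes, init_weights=self.init_weights,
              allow_absent_classes=self.init_weights is not None)
        self.classes_ = self.teacher_.classes_
        P = _one_hot(y, self.classes_)
        # frozen teacher's soft targets, softened at T2
        soft = softmax_rows(self.teacher_.decision_function(X), kd.T2)

        rng = np.random.default_rng(self.random_state + 1)
        core = MLPCore(X.shape[1], tuple(self.hidden_sizes), len(self.classes_), rng)
        if self.init_weights is not None:
            core.set_weights(self.init_weights)
        a, T1, T2 = kd.alpha, kd.T1, kd.T2
        kl_scale = T2**2 if kd.t2_square else 1.0

        def grad_fn(logits, idx):
            q1 = softmax_rows(logits, T1)
            loss = a * cross_entropy(P[idx], q1)
            grad = a * (q1 - P[idx]) / T1
            if a < 1.0:
                q2 = softmax_rows(logits, T2)
                loss += (1 - a) * kl_scale * _kl_rows(soft[idx], q2)
                grad += (1 - a) * kl_scale * (q2 - soft[idx]) / T2
            return grad / len(idx), loss

        self.loss_curve_ = train_loop(
            core, X, grad_fn,
            epochs=kd.epochs, batch_size=self.batch_size,
            learning_rate=self.learning_rate, dropout=self.dropout_rate,
            rng=rng, patience=None,
        )
        self.core_ = core
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X) -> np.ndarray:
        X = check_array(X, dtype=float)
        if X.shape[1] != self.core_.n_in:
            raise ValueError(
                f"X has {X.shape[1]} features; model expects {self.core_.n_in}"
            )
        logits, _ = self.core_.forward(X)
        return logits

    def predict_proba(self, X) -> np.ndarray:
        return softmax_rows(self.decision_function(X), self.T1)

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]


# ---------------------------------------------------------------------------
# Persistence and functional wrappers
# ---------------------------------------------------------------------------

@dataclass
class TrainedModel:
    """A fitted first-round classifier plus everything needed to apply it:
    the feature list, class ordering and preprocessing statistics."""

    estimator: TemperedMLP
    feature_set: FeatureSet | None = None
    ref_stats: StandardizationStats | None = None
    config: dict = field(default_factory=dict)
    seed: int = 2022

    @property
    def class_names(self) -> np.ndarray:
        return self.estimator.classes_

    def save(self, path: str | Path) -> None:
        """Serialize to a single ``.npz`` archive (weights + JSON metadata)."""
        arrays = {k: v for k, v in self.estimator.core_.get_weights().items()}
        meta = {
            "class_names": [str(c) for c in self.estimator.classes_],
            "params": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in self.estimator.get_params().items()},
            "config": self.config,
            "seed": self.seed,
        }
        if self.feature_set is not None:
            meta["feature_genes"] = [str(g) for g in self.feature_set.gene_names]
            arrays["feature_F"] = self.feature_set.f_statistics
        if self.ref_stats is not None:
            arrays["ref_mean"] = self.ref_stats.mean
            arrays["ref_sd"] = self.ref_stats.sd
        arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        with np.load(path, allow_pickle=False) as z:
            arrays = {k: z[k] for k in z.files}
        meta = json.loads(bytes(arrays.pop("meta_json")).decode())
        params = meta["params"]
        params["hidden_sizes"] = tuple(params["hidden_sizes"])
        est = TemperedMLP(**params)
        est.classes_ = np.asarray(meta["class_names"], dtype=object)
        feature_F = arrays.pop("feature_F", None)
        ref_mean = arrays.pop("ref_mean", None)
        ref_sd = arrays.pop("ref_sd", None)
        rng = np.random.default_rng(0)
        hidden = tuple(params["hidden_sizes"])
        n_in = arrays["W0"].shape[0]
        est.core_ = MLPCore(n_in, hidden, len(est.classes_), rng)
        est.core_.set_weights(arrays)
        est.n_features_in_ = n_in
        fs = None
        if "feature_genes" in meta:
            fs = FeatureSet(np.asarray(meta["feature_genes"], dtype=object),
                            feature_F, len(meta["feature_genes"]))
        stats = None
        if ref_mean is not None:
            stats = StandardizationStats(ref_mean, ref_sd, "reference")
        return cls(est, fs, stats, meta.get("config", {}), meta.get("seed", 2022))


def train_mlp(X: np.ndarray, y, cfg: MLPConfig | None = None, seed: int = 2022) -> TrainedModel:
    """Train a first-round MLP on a standardized cells x features matrix."""
    cfg = cfg or MLPConfig()
    est = TemperedMLP(
        hidden_sizes=cfg.hidden_sizes, dropout_rate=cfg.dropout_rate,
        epochs=cfg.epochs, batch_size=cfg.batch_size,
        learning_rate=cfg.learning_rate, temperature=cfg.temperature,
        patience=cfg.patience, random_state=seed,
    ).fit(X, y)
    return TrainedModel(est, config=asdict(cfg), seed=seed)


def train_kd(
    anchors_X: np.ndarray,
    pseudo_labels,
    cfg_mlp: MLPConfig | None = None,
    cfg_kd: KDConfig | None = None,
    seed: int = 2022,
) -> KDClassifier:
    """Train the teacher-student pair on anchor cells; returns the student."""
    cfg_mlp = cfg_mlp or MLPConfig()
    cfg_kd = cfg_kd or KDConfig()
    if np.asarray(anchors_X).shape[0] == 0:
        raise ValueError("anchors_X is empty")
    return KDClassifier(
        hidden_sizes=cfg_mlp.hidden_sizes, dropout_rate=cfg_mlp.dropout_rate,
        alpha=cfg_kd.alpha, T1=cfg_kd.T1, T2=cfg_kd.T2, epochs=cfg_kd.epochs,
        batch_size=cfg_mlp.batch_size, learning_rate=cfg_mlp.learning_rate,
        t2_square=cfg_kd.t2_square, random_state=seed,
    ).fit(anchors_X, pseudo_labels)


def predict_proba(model, X: np.ndarray) -> np.ndarray:
    """Probability matrix (rows sum to 1) for a fitted model or TrainedModel."""
    est = model.estimator if isinstance(model, TrainedModel) else model
    return est.predict_proba(X)
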