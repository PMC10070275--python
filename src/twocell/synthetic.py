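"""Synthetic gene-score matrices with known labels and a reference-target shift.

The generator emulates the statistical shape of smoothed scATAC-seq gene
activity scores: non-negative, non-integer, very sparse, with cell-type
structure carried by small sets of marker genes. Per cell of type ``k`` and
gene ``g`` a score is drawn from a zero-inflated log-normal,

    score = Bernoulli(1 - p0(m_gk)) * LogNormal(m_gk, 0.5),
    m_gk  = mu_g + effect * 1[g marker of k],

so ``marker_effect`` is the natural-log fold elevation of a type's markers.
Detection is mean-dependent, as in accessibility data: the dropout
probability ``p0(m) = sigmoid((x0 - m) / tau)`` falls with the underlying
log-mean (highly accessible marker genes are rarely missed), with the
midpoint ``x0`` solved so the expected overall zero fraction equals
``sparsity``.
Target cells are additionally multiplied gene-wise by ``exp(shift_g)`` with
``shift_g ~ Normal(0, shift_strength)`` shared across all target cells — a
depth/accessibility-bias-like batch factor that leaves the cell labels
well-defined while degrading naive reference-to-target transfer. Cell-type
proportions may differ between reference and target (composition shift); by
default the target proportions are the reference's rotated by one type.

An integer negative-binomial score mode is available for robustness testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import GeneScoreMatrix, LabelVector

_LOGNORMAL_SIGMA = 0.5  # within-gene biological spread on the log scale
_DROPOUT_TAU = 0.5  # steepness of the mean-dependent detection curve


@dataclass
class SyntheticConfig:
    """Study-condition knobs for one reference/target pair.

    Defaults describe a moderately hard, shifted task: 2000 genes, 4 cell
    types with 20 markers each elevated e^2-fold, 70% zeros, 1500 cells on
    each side, and a gene-wise log-normal batch factor of strength 0.8
    applied to the target.
    """

    n_genes: int = 2000
    n_ref: int = 1500
    n_target: int = 1500
    n_types: int = 4
    markers_per_type: int = 20
    marker_effect: float = 2.0
    sparsity: float = 0.7
    shift_strength: float = 0.8
    ref_proportions: tuple[float, ...] | None = None
    target_proportions: tuple[float, ...] | None = None
    distribution: str = "lognormal"  # or "negative_binomial"
    seed: int = 2022

    def __post_init__(self) -> None:
        if self.markers_per_type * self.n_types > self.n_genes:
            raise ValueError("more planted markers than genes")
        if not (0 <= self.sparsity < 1):
            raise ValueError("sparsity must be in [0, 1)")
        if self.shift_strength < 0:
            raise ValueError("shift_strength must be >= 0")
        for name in ("ref_proportions", "target_proportions"):
            p = getattr(self, name)
            if p is not None:
                p = np.asarray(p, dtype=float)
                if len(p) != self.n_types or p.min() < 0 or abs(p.sum() - 1) > 1e-8:
                    raise ValueError(f"{name} must be a length-{self.n_types} simplex vector")


@dataclass
class SyntheticDataset:
    """A generated reference/target pair; target labels exist only for scoring."""

    ref: GeneScoreMatrix
    ref_labels: LabelVector
    target: GeneScoreMatrix
    target_labels: LabelVector
    marker_genes: dict[str, list[str]] = field(default_factory=dict)
    config: SyntheticConfig | None = None


def _default_proportions(K: int) -> np.ndarray:
    # mildly imbalanced: proportional to K, K-1, ..., 1
    p = np.arange(K, 0, -1, dtype=float)
    return p / p.sum()


def _draw_matrix(
    rng: np.random.Generator,
    cfg: SyntheticConfig,
    mu: np.ndarray,  # genes x types log-mean matrix
    types: np.ndarray,  # per-cell type index
    shift: np.ndarray | None = None,  # per-gene log batch factor
) -> np.ndarray:
    from scipy.optimize import brentq
    from scipy.special import expit

    base_logmean = mu[:, types]  # genes x cells
    if shift is not None:
        # the batch factor acts on the underlying accessibility level, so it
        # moves both the score magnitude and the detection probability
        logmean = base_logmean + shift[:, None]
    else:
        logmean = base_logmean
    if cfg.distribution == "lognormal":
        X = rng.lognormal(mean=logmean, sigma=_LOGNORMAL_SIGMA)
    elif cfg.distribution == "negative_binomial":
        m = np.exp(logmean)
        r = 2.0  # dispersion; variance = m + m^2/r
        X = rng.negative_binomial(r, r / (r + m)).astype(float)
    else:
        raise ValueError(f"unknown distribution {cfg.distribution!r}")
    if cfg.sparsity == 0:
        return X
    # mean-dependent dropout: midpoint calibrated on the *unshifted* means so
    # that E[zero fraction] == sparsity in the absence of a batch factor
    x0 = brentq(lambda x: expit((x - base_logmean) / _DROPOUT_TAU).mean() - cfg.sparsity, -50, 50)
    keep = rng.random(logmean.shape) >= expit((x0 - logmean) / _DROPOUT_TAU)
    return X * keep


def generate(cfg: SyntheticConfig | None = None, **overrides) -> SyntheticDataset:
    """Draw a labeled reference/target pair, deterministic given ``cfg.seed``."""
    if cfg is None:
        cfg = SyntheticConfig(**overrides)
    elif overrides:
        raise TypeError("pass either a config or keyword overrides, not both")
    rng = np.random.default_rng(cfg.seed)
    G, K = cfg.n_genes, cfg.n_types
    type_names = np.array([f"type{k}" for k in range(K)], dtype=object)
    gene_names = np.array([f"gene{g}" for g in range(G)], dtype=object)

    # baseline gene log-means, then plant marker elevations
    base_mu = rng.normal(0.0, 0.5, size=G)
    marker_idx = rng.choice(G, size=K * cfg.markers_per_type, replace=False)
    mu = np.tile(base_mu[:, None], (1, K))
    markers: dict[str, list[str]] = {}
    for k in range(K):
        idx = marker_idx[k * cfg.markers_per_type : (k + 1) * cfg.markers_per_type]
        mu[idx, k] += cfg.marker_effect
        markers[str(type_names[k])] = gene_names[idx].tolist()

    ref_p = np.asarray(cfg.ref_proportions, float) if cfg.ref_proportions else _default_proportions(K)
    tgt_p = np.asarray(cfg.target_proportions, float) if cfg.target_proportions else np.roll(ref_p, 1)

    ref_types = rng.choice(K, size=cfg.n_ref, p=ref_p)
    tgt_types = rng.choice(K, size=cfg.n_target, p=tgt_p)

    X_ref = _draw_matrix(rng, cfg, mu, ref_types)
    shift = rng.normal(0.0, cfg.shift_strength, size=G) if cfg.shift_strength > 0 else None
    X_tgt = _draw_matrix(rng, cfg, mu, tgt_types, shift=shift)

    ref_bc = np.array([f"ref_cell{i}" for i in range(cfg.n_ref)], dtype=object)
    tgt_bc = np.array([f"tgt_cell{i}" for i in range(cfg.n_target)], dtype=object)
    return SyntheticDataset(
        ref=GeneScoreMatrix(X_ref, gene_names, ref_bc),
        ref_labels=LabelVector(ref_bc, type_names[ref_types]),
        target=GeneScoreMatrix(X_tgt, gene_names, tgt_bc),
        target_labels=LabelVector(tgt_bc, type_names[tgt_types]),
        marker_genes=markers,
        config=cfg,
    )
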