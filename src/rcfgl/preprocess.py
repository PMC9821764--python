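"""Sample covariances, CV-based gene pruning and the condition-ordering heuristic."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .io import ExpressionPanel

logger = logging.getLogger(__name__)


@dataclass
class CovariancePanel:
    """Per-condition ML sample covariances S^(k) (divisor n_k) and sample sizes."""

    conditions: list
    S: np.ndarray  # (K, p, p)
    n: np.ndarray  # (K,)
    gene_ids: list

    def __post_init__(self):
        self.S = np.asarray(self.S, dtype=float)
        self.n = np.asarray(self.n)
        self.conditions = [str(c) for c in self.conditions]
        self.gene_ids = [str(g) for g in self.gene_ids]
        K = len(self.conditions)
        p = len(self.gene_ids)
        if self.S.shape != (K, p, p):
            raise ValueError(f"S must have shape ({K}, {p}, {p}), got {self.S.shape}")
        if self.n.shape != (K,) or np.any(self.n < 1):
            raise ValueError("n must hold one positive sample size per condition")
        for k in range(K):
            if not np.allclose(self.S[k], self.S[k].T, atol=1e-12):
                raise ValueError(f"S[{k}] is not symmetric")
            if np.any(np.diag(self.S[k]) < 0):
                raise ValueError(f"S[{k}] has a negative diagonal entry")
            evals = np.linalg.eigvalsh(self.S[k])
            if evals[0] < -1e-10 * max(evals[-1], 1e-300):
                raise ValueError(f"S[{k}] is not positive semidefinite")

    @property
    def K(self):
        return len(self.conditions)

    @property
    def p(self):
        return len(self.gene_ids)

    def subset(self, idx):
        """Covariance panel restricted to gene indices ``idx`` (order kept)."""
        idx = np.asarray(idx, dtype=int)
        return CovariancePanel(
            conditions=list(self.conditions),
            S=self.S[:, idx[:, None], idx[None, :]],
            n=self.n.copy(),
            gene_ids=[self.gene_ids[i] for i in idx],
        )

    def reorder_conditions(self, order):
        idx = [self.conditions.index(o) if isinstance(o, str) else int(o)
               for o in order]
        if sorted(idx) != list(range(self.K)):
            raise ValueError("order must be a permutation of the conditions")
        return CovariancePanel(
            conditions=[self.conditions[i] for i in idx],
            S=self.S[idx], n=self.n[idx], gene_ids=list(self.gene_ids),
        )


@dataclass
class ConditionOrdering:
    """Distance matrix between conditions, linkage record and leaf order."""

    conditions: list
    distance_matrix: np.ndarray
    order: list  # condition labels, dendrogram leaf order
    linkage_record: np.ndarray


def compute_covariance(panel: ExpressionPanel) -> CovariancePanel:
    """Column-centered ML covariance S^(k) = Yc^T Yc / n_k per condition.

    The divisor is n_k, matching the n_k-weighted Gaussian log-likelihood
    the fused graphical lasso maximizes.  Zero-variance genes are legal
    (S_ii = 0) but logged, since they carry no network information.
    """
    S = []
    for c, y in zip(panel.conditions, panel.Y):
        yc = y - y.mean(axis=0, keepdims=True)
        s = yc.T @ yc / y.shape[0]
        s = 0.5 * (s + s.T)
        zero = np.flatnonzero(np.diag(s) == 0)
        for g in zero:
            logger.warning(
                "condition %s: gene %s has zero variance", c, panel.gene_ids[g]
            )
        S.append(s)
    return CovariancePanel(
        conditions=list(panel.conditions), S=np.array(S),
        n=panel.n, gene_ids=list(panel.gene_ids),
    )


def prune_by_cv(panel: ExpressionPanel, cv_cutoff: float,
                definition: str = "sd_over_mean") -> ExpressionPanel:
    """Drop genes whose coefficient of variation falls below ``cv_cutoff``.

    The CV is computed per gene on the row-concatenation of all conditions.
    The default definition is SD/|mean| (population SD); ``mean_over_sd``
    computes the reciprocal reading instead.  Surviving gene order is kept.
    """
    if cv_cutoff < 0:
        raise ValueError("cv_cutoff must be nonnegative")
    if definition not in ("sd_over_mean", "mean_over_sd"):
        raise ValueError(f"unknown CV definition {definition!r}")
    stacked = np.vstack(panel.Y)
    sd = stacked.std(axis=0)
    mean = np.abs(stacked.mean(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        if definition == "sd_over_mean":
            cv = np.where(mean > 0, sd / mean, np.where(sd > 0, np.inf, 0.0))
        else:
            cv = np.where(sd > 0, mean / sd, np.where(mean > 0, np.inf, 0.0))
    keep = np.flatnonzero(cv >= cv_cutoff)
    if keep.size == 0:
        raise ValueError(f"all genes pruned at CV cutoff {cv_cutoff}")
    return ExpressionPanel(
        conditions=list(panel.conditions),
        Y=[y[:, keep] for y in panel.Y],
        gene_ids=[panel.gene_ids[i] for i in keep],
    )


def condition_distance(S_a: np.ndarray, S_b: np.ndarray) -> float:
    """Euclidean (Frobenius) distance between two covariance matrices."""
    S_a = np.asarray(S_a, dtype=float)
    S_b = np.asarray(S_b, dtype=float)
    if S_a.shape != S_b.shape:
        raise ValueError(f"shape mismatch: {S_a.shape} vs {S_b.shape}")
    return float(np.sqrt(np.sum((S_a - S_b) ** 2)))


def order_conditions(cov: CovariancePanel) -> ConditionOrdering:
    """Order conditions by average-linkage clustering of covariance distances.

    The recommended fusion order is the dendrogram leaf order, which places
    the most similar conditions adjacent -- exactly what the sequential
    fused penalty rewards.  Deterministic given the distance matrix.
    """
    K = cov.K
    if K < 2:
        raise ValueError("need at least 2 conditions to order")
    d = np.zeros((K, K))
    for a in range(K):
        for b in range(a + 1, K):
            d[a, b] = d[b, a] = condition_distance(cov.S[a], cov.S[b])
    if K == 2:
        return ConditionOrdering(
            conditions=list(cov.conditions), distance_matrix=d,
            order=list(cov.conditions), linkage_record=np.zeros((0, 4)),
        )
    Zl = linkage(squareform(d, checks=False), method="average")
    leaf_idx = leaves_list(Zl)
    return ConditionOrdering(
        conditions=list(cov.conditions), distance_matrix=d,
        order=[cov.conditions[i] for i in leaf_idx], linkage_record=Zl,
    )
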