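"""ADMM solver for the condition-adaptive sequential fused graphical lasso.

The estimator minimizes, over symmetric positive-definite Theta^(1..K),

    - sum_k n_k [ log det Theta^(k) - tr(S^(k) Theta^(k)) ]  +  P(Theta)

with P the lasso + fused penalty of the chosen flavor (see
:func:`penalty_value`).  ADMM splits Theta (smooth log-det step, closed
form via one eigendecomposition per condition) from its copy Z (the fused
lasso prox, separable across gene pairs into K-chains) with scaled duals U.
The final network is read from Z, which carries exact zeros from the prox.

Penalty sums run over ordered pairs i != j, so each unordered gene pair is
counted twice; this matches the printed penalty definitions and only
rescales lambda by a factor of 2 relative to an unordered-sum convention.

lambda scale: the tuning parameters multiply an n_k-weighted likelihood, so
their natural magnitude grows with the sample size.  ``rcfgl_fit`` accepts
them on the per-sample scale by default (``lambda_scale="samples"``,
internally multiplied by the mean sample size), which keeps useful values
in the familiar 0.01-0.5 range regardless of n; ``"absolute"`` passes them
through untouched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .preprocess import CovariancePanel
from .prox import chain_prox_batch
from .weights import WeightSet

logger = logging.getLogger(__name__)

FLAVORS = ("FGL", "FMGL", "CFGL", "RCFGL")


@dataclass
class PenaltyConfig:
    """Lasso strength, fusion strength, penalty flavor and fusion weights.

    ``weights``: for RCFGL a :class:`~rcfgl.weights.WeightSet` (or list of
    K-1 matrices) aligned with consecutive condition pairs; for CFGL a dict
    {(k, k'): matrix, k < k'} over all condition pairs; ignored by
    FGL/FMGL (implicit all-ones).
    """

    lambda1: float
    lambda2: float
    flavor: str = "RCFGL"
    weights: object = None

    def __post_init__(self):
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("lambda1 and lambda2 must be nonnegative")
        if self.flavor not in FLAVORS:
            raise ValueError(f"flavor must be one of {FLAVORS}")

    def sequential_weights(self, K, p):
        """Materialize the K-1 sequential weight matrices (all-ones default)."""
        if self.weights is None:
            return [np.ones((p, p)) for _ in range(K - 1)]
        W = self.weights.W if isinstance(self.weights, WeightSet) else list(self.weights)
        if len(W) != K - 1:
            raise ValueError(f"need {K - 1} sequential weight matrices, got {len(W)}")
        return [np.asarray(w, dtype=float) for w in W]


@dataclass
class PrecisionEstimates:
    """Converged estimates: Theta (PD), Z (exact zeros = network) + diagnostics."""

    conditions: list
    gene_ids: list
    Theta: np.ndarray  # (K, p, p)
    Z: np.ndarray  # (K, p, p)
    converged: bool
    n_iter: int
    primal_residual: float
    dual_residual: float
    config: PenaltyConfig
    blocks: list = field(default=None)  # set when screening was used

    @property
    def K(self):
        return len(self.conditions)


def _offdiag_abs_sum(M):
    return float(np.sum(np.abs(M)) - np.sum(np.abs(np.diag(M))))


def penalty_value(theta, config: PenaltyConfig) -> float:
    """Evaluate the penalty of the given flavor at a Theta panel.

    Sums run over ordered pairs i != j (each unordered pair twice).  The
    four flavors differ only in the fusion term: FGL/CFGL use all pairwise
    condition differences (CFGL weighted), FMGL/RCFGL use consecutive
    differences only (RCFGL weighted).
    """
    th = np.asarray(theta, dtype=float)
    K = th.shape[0]
    p = th.shape[1]
    val = config.lambda1 * sum(_offdiag_abs_sum(th[k]) for k in range(K))
    if config.lambda2 == 0 or K == 1:
        return val
    if config.flavor == "FGL":
        fuse = sum(_offdiag_abs_sum(th[a] - th[b])
                   for a in range(K) for b in range(a + 1, K))
    elif config.flavor == "FMGL":
        fuse = sum(_offdiag_abs_sum(th[k] - th[k + 1]) for k in range(K - 1))
    elif config.flavor == "CFGL":
        if not isinstance(config.weights, dict):
            raise ValueError("CFGL requires weights as a dict {(k, k'): matrix}")
        fuse = 0.0
        for a in range(K):
            for b in range(a + 1, K):
                w = np.asarray(config.weights[(a, b)], dtype=float)
                M = w * np.abs(th[a] - th[b])
                fuse += float(np.sum(M) - np.sum(np.diag(M)))
    else:  # RCFGL
        W = config.sequential_weights(K, p)
        fuse = 0.0
        for k in range(K - 1):
            M = W[k] * np.abs(th[k] - th[k + 1])
            fuse += float(np.sum(M) - np.sum(np.diag(M)))
    return val + config.lambda2 * fuse


def objective_value(theta, cov: CovariancePanel, config: PenaltyConfig) -> float:
    """Penalized negative log-likelihood being minimized.

    - sum_k n_k [ log det Theta^(k) - tr(S^(k) Theta^(k)) ] + penalty.
    """
    th = np.asarray(theta, dtype=float)
    val = 0.0
    for k in range(th.shape[0]):
        sign, logdet = np.linalg.slogdet(th[k])
        if sign <= 0:
            raise ValueError(f"Theta[{k}] is not positive definite")
        val -= cov.n[k] * (logdet - float(np.sum(cov.S[k] * th[k])))
    return val + penalty_value(th, config)


def theta_update(S, n_k, Z, U, rho):
    """Closed-form minimizer of the smooth Theta subproblem.

    Eigendecompose S - (rho/n_k)(Z - U) = V D V^T; the update is
    V Dtilde V^T with Dtilde_jj = (n_k / 2 rho)(-D_jj + sqrt(D_jj^2 +
    4 rho / n_k)), the unique positive root of the per-eigenvalue
    stationarity quadratic.  Output is symmetric positive definite and
    satisfies -n_k(Theta^-1 - S) + rho(Theta - Z + U) = 0.
    """
    if rho <= 0:
        raise ValueError("rho must be positive")
    M = S - (rho / n_k) * (Z - U)
    M = 0.5 * (M + M.T)
    if not np.all(np.isfinite(M)):
        raise ValueError("non-finite input to the Theta update")
    d, V = np.linalg.eigh(M)
    dtil = (n_k / (2.0 * rho)) * (-d + np.sqrt(d * d + 4.0 * rho / n_k))
    Th = (V * dtil) @ V.T
    return 0.5 * (Th + Th.T)


def z_update(A, config: PenaltyConfig, rho):
    """Fused-lasso prox of the A panel, entrywise across conditions.

    For every unordered pair i < j the K-vector A_ij^(1..K) passes through
    the exact chain prox with t1 = lambda1/rho, t2 = lambda2/rho and the
    pair's weight chain; the result is mirrored to (j, i).  Diagonals carry
    no penalty and are copied unchanged.  Only sequential flavors
    (FMGL/RCFGL) are supported here.
    """
    A = np.asarray(A, dtype=float)
    K, p, _ = A.shape
    if config.flavor in ("FGL", "CFGL") and K > 2:
        raise ValueError(
            f"{config.flavor} pairwise prox is not provided; "
            "use RCFGL/FMGL (sequential) flavors"
        )
    W = config.sequential_weights(K, p)
    iu, ju = np.triu_indices(p, k=1)
    chains = np.ascontiguousarray(A[:, iu, ju].T)  # (m, K)
    wchains = (np.ascontiguousarray(
        np.stack([W[k][iu, ju] for k in range(K - 1)], axis=1))
        if K > 1 else np.empty((iu.size, 0)))
    zc = chain_prox_batch(chains, wchains, config.lambda1 / rho,
                          config.lambda2 / rho)
    Z = np.empty_like(A)
    for k in range(K):
        Z[k] = np.diag(np.diag(A[k]))
        Z[k][iu, ju] = zc[:, k]
        Z[k][ju, iu] = zc[:, k]
    return Z


def u_update(U, Theta, Z):
    """Scaled dual ascent: U + (Theta - Z), elementwise per condition."""
    return np.asarray(U) + (np.asarray(Theta) - np.asarray(Z))


def rcfgl_fit(cov: CovariancePanel, weights=None, lambda1=0.1, lambda2=0.05,
              rho=1.0, max_iter=500, tol=1e-4, mode="rcfgl",
              lambda_scale="samples", init=None) -> PrecisionEstimates:
    """Fit the sequential fused graphical lasso by ADMM.

    Parameters
    ----------
    cov : CovariancePanel
        Sample covariances and sample sizes, in fusion order.
    weights : WeightSet, list of K-1 matrices, or None
        Fusion weights for consecutive condition pairs.  ``mode="rfgl"``
        (or ``weights=None``) uses all-ones weights, i.e. the non-adaptive
        sequential penalty.
    lambda1, lambda2 : float
        Sparsity and fusion strengths, on the scale set by ``lambda_scale``.
    rho : float
        ADMM coupling constant (fixed; default 1.0), on the same scale as
        the lambdas: with ``lambda_scale="samples"`` it is likewise
        multiplied by the mean sample size, which keeps the splitting
        well-conditioned against the n_k-weighted likelihood.
    tol : float
        Stop when both max_k ||Theta-Z||_F / max(1, ||Z||_F) and
        max_k ||Z - Z_prev||_F / max(1, ||Z_prev||_F) fall below tol.
    init : PrecisionEstimates or (Theta, Z, U) triple, optional
        Warm start; default Theta = I, Z = U = 0.

    Non-convergence returns a result with ``converged=False`` and a
    warning, not an exception.
    """
    if mode not in ("rcfgl", "rfgl"):
        raise ValueError("mode must be 'rcfgl' or 'rfgl'")
    if lambda_scale not in ("samples", "absolute"):
        raise ValueError("lambda_scale must be 'samples' or 'absolute'")
    K, p = cov.K, cov.p
    scale = float(np.mean(cov.n)) if lambda_scale == "samples" else 1.0
    rho = rho * scale
    if mode == "rfgl":
        weights = None
    if isinstance(weights, WeightSet):
        weights.check_alignment(cov.conditions)
    config = PenaltyConfig(lambda1=lambda1 * scale, lambda2=lambda2 * scale,
                           flavor="RCFGL" if mode == "rcfgl" else "FMGL",
                           weights=weights)
    config.sequential_weights(K, p)  # validate early

    if init is None:
        Theta = np.tile(np.eye(p), (K, 1, 1))
        Z = np.zeros((K, p, p))
        U = np.zeros((K, p, p))
    elif isinstance(init, PrecisionEstimates):
        Theta, Z = init.Theta.copy(), init.Z.copy()
        U = np.zeros((K, p, p))
    else:
        Theta, Z, U = (np.array(m, dtype=float) for m in init)

    converged = False
    it = 0
    primal = dual = np.inf
    for it in range(1, max_iter + 1):
        for k in range(K):
            Theta[k] = theta_update(cov.S[k], cov.n[k], Z[k], U[k], rho)
        A = Theta + U
        Z_prev = Z
        Z = z_update(A, config, rho)
        U = U + (Theta - Z)
        primal = max(np.linalg.norm(Theta[k] - Z[k]) for k in range(K))
        dual = rho * max(np.linalg.norm(Z[k] - Z_prev[k]) for k in range(K))
        rel_primal = max(
            np.linalg.norm(Theta[k] - Z[k]) / max(1.0, np.linalg.norm(Z[k]))
            for k in range(K))
        rel_dz = max(
            np.linalg.norm(Z[k] - Z_prev[k]) / max(1.0, np.linalg.norm(Z_prev[k]))
            for k in range(K))
        logger.debug("iter %d primal %.3e dual %.3e", it, primal, dual)
        if rel_primal < tol and rel_dz < tol:
            converged = True
            break
    if not converged:
        logger.warning(
            "ADMM did not converge in %d iterations "
            "(primal %.3e, dual %.3e)", max_iter, primal, dual)
    return PrecisionEstimates(
        conditions=list(cov.conditions), gene_ids=list(cov.gene_ids),
        Theta=Theta, Z=Z, converged=converged, n_iter=it,
        primal_residual=primal, dual_residual=dual, config=config,
    )
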