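"""Condition-specificity fusion weights W^(k,k+1).

A weight of 1 keeps the fusion penalty active for a gene pair (the entry is
believed shared between the two conditions); 0 disables it (believed
differential).  The default estimator tests, for every gene pair and every
consecutive condition pair, whether the precision-matrix entry differs
between conditions, using de-sparsified node-wise lasso estimates and a
two-sample z statistic, with Benjamini-Hochberg control across the
p(p-1)/2 gene pairs.  Oracle weights (exact equality of true entries) and
user-supplied weights bypass the test entirely, so downstream behavior can
be studied independently of this estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.linear_model import Lasso

from .io import ExpressionPanel


@dataclass
class WeightSet:
    """K-1 symmetric nonnegative p x p matrices, aligned to the condition order.

    Entries are binary for estimated/oracle/user weights; the CFGL-emulating
    W* modification can produce entries equal to 2.
    """

    W: list
    source: str = "user"
    conditions: list = field(default=None)  # condition order the set aligns to

    def __post_init__(self):
        self.W = [np.asarray(w, dtype=float) for w in self.W]
        for i, w in enumerate(self.W):
            if w.ndim != 2 or w.shape[0] != w.shape[1]:
                raise ValueError(f"W[{i}] must be square")
            if not np.allclose(w, w.T, atol=1e-12):
                raise ValueError(f"W[{i}] must be symmetric")
            if np.any(w < 0):
                raise ValueError(f"W[{i}] must be nonnegative")
            if w.shape != self.W[0].shape:
                raise ValueError("all weight matrices must share a shape")

    def __len__(self):
        return len(self.W)

    def check_alignment(self, conditions):
        if len(self.W) != len(conditions) - 1:
            raise ValueError(
                f"{len(self.W)} weight matrices cannot align with "
                f"{len(conditions)} conditions")
        if self.conditions is not None and list(self.conditions) != list(conditions):
            raise ValueError(
                "weight set was built for condition order "
                f"{self.conditions}, got {list(conditions)}")


def ones_weights(K, p, conditions=None):
    """All-ones weights: the RCFGL penalty then equals the FMGL penalty."""
    return WeightSet(W=[np.ones((p, p)) for _ in range(K - 1)],
                     source="ones", conditions=conditions)


def _desparsified_precision(Y, lam):
    """Node-wise lasso precision estimate with de-sparsification.

    Columns are standardized, each gene is lasso-regressed on the rest, the
    initial row estimates Theta_j = (-beta_j, 1)/tau_j^2 are assembled, and
    the bias is removed with T = Theta + Theta^T - Theta^T Sigma_hat Theta.
    Returns (T, Theta_init, Sigma_hat); all on the standardized scale.
    """
    n, p = Y.shape
    X = Y - Y.mean(axis=0, keepdims=True)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X = X / sd
    Sig = X.T @ X / n
    Theta = np.zeros((p, p))
    model = Lasso(alpha=lam, fit_intercept=False, max_iter=5000, tol=1e-8)
    for j in range(p):
        idx = np.arange(p) != j
        model.fit(X[:, idx], X[:, j])
        beta = model.coef_
        resid = X[:, j] - X[:, idx] @ beta
        tau2 = float(resid @ X[:, j]) / n  # KKT-consistent noise estimate
        tau2 = max(tau2, 1e-12)
        Theta[j, j] = 1.0 / tau2
        Theta[j, idx] = -beta / tau2
    T = Theta + Theta.T - Theta.T @ Sig @ Theta
    return T, Theta, Sig


def _bh_reject(pvals, alpha):
    """Benjamini-Hochberg step-up; returns a boolean rejection mask."""
    m = pvals.size
    order = np.argsort(pvals, kind="stable")
    ranked = pvals[order]
    thresh = alpha * (np.arange(1, m + 1) / m)
    below = ranked <= thresh
    reject = np.zeros(m, dtype=bool)
    if below.any():
        kmax = np.max(np.flatnonzero(below))
        reject[order[: kmax + 1]] = True
    return reject


def estimate_weights(panel: ExpressionPanel, alpha=0.05,
                     lasso_lambda=None) -> WeightSet:
    """Estimate binary weights by entrywise differential tests.

    For each consecutive condition pair and gene pair (i, j), the
    de-sparsified precision entries T^(k)_ij are compared with
    z = (T^(k) - T^(k+1)) / sqrt(var_k/n_k + var_{k+1}/n_{k+1}), where
    var = Theta_ii Theta_jj + Theta_ij^2 is the asymptotic variance of the
    de-sparsified entry.  Two-sided p-values are BH-corrected at ``alpha``
    across the p(p-1)/2 entries per pair; rejected entries get weight 0.

    ``lasso_lambda`` defaults to sqrt(2 log(p) / n_k) per condition.
    Identical expression matrices give identically zero statistics, hence
    all-ones weights.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    K, p = panel.K, panel.p
    if K < 2:
        raise ValueError("need at least 2 conditions")
    for c, nk in zip(panel.conditions, panel.n):
        if nk < 10:
            raise ValueError(
                f"condition {c!r} has n={nk} < 10, too small for the "
                "differential test; use ones or user-supplied weights")
    T = []
    V = []
    for k in range(K):
        n_k = panel.Y[k].shape[0]
        lam = (np.sqrt(2.0 * np.log(p) / n_k)
               if lasso_lambda is None else lasso_lambda)
        Tk, Theta0, _ = _desparsified_precision(panel.Y[k], lam)
        var = np.outer(np.diag(Theta0), np.diag(Theta0)) + Theta0 * Theta0.T
        T.append(Tk)
        V.append(np.maximum(var, 1e-12) / n_k)
    iu, ju = np.triu_indices(p, k=1)
    W = []
    for k in range(K - 1):
        num = T[k][iu, ju] - T[k + 1][iu, ju]
        den = np.sqrt(V[k][iu, ju] + V[k + 1][iu, ju])
        z = num / den
        pvals = 2.0 * stats.norm.sf(np.abs(z))
        reject = _bh_reject(pvals, alpha)
        w = np.ones((p, p))
        w[iu[reject], ju[reject]] = 0.0
        w[ju[reject], iu[reject]] = 0.0
        W.append(w)
    return WeightSet(W=W, source="estimated", conditions=list(panel.conditions))


def oracle_weights(truth, conditions=None) -> WeightSet:
    """Weights from known truth: 1 where consecutive true entries are equal."""
    truth = [np.asarray(t, dtype=float) for t in truth]
    if len(truth) < 2:
        raise ValueError("need at least 2 true precision matrices")
    shape = truth[0].shape
    if any(t.shape != shape for t in truth):
        raise ValueError("true precision matrices must share a shape")
    W = [(truth[k] == truth[k + 1]).astype(float) for k in range(len(truth) - 1)]
    for w in W:
        np.fill_diagonal(w, 1.0)
    return WeightSet(W=W, source="oracle", conditions=conditions)


def modify_weights_for_cfgl_k3(W12, W13, W23) -> WeightSet:
    """K=3 pairwise-to-sequential weight lift: W*12 = W12 + W13, W*23 = W23 + W13.

    With these modified weights the sequential penalty upper-bounds the
    pairwise condition-adaptive penalty (triangle inequality on the middle
    condition), which is how a CFGL-like fit is emulated.  Entries lie in
    {0, 1, 2} for binary inputs.
    """
    mats = [np.asarray(m, dtype=float) for m in (W12, W13, W23)]
    shape = mats[0].shape
    if any(m.shape != shape for m in mats):
        raise ValueError("the three pairwise weight matrices must share a shape")
    return WeightSet(W=[mats[0] + mats[1], mats[2] + mats[1]], source="modified")
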