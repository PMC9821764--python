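"""AIC-based tuning parameter selection for (lambda1, lambda2).

AIC(l1, l2) = sum_k [ n_k tr(S^(k) Theta_hat^(k))
                      - n_k log det Theta_hat^(k) + 2 E_k ],

where E_k counts the unique nonzero elements of the estimate.  Here
"unique nonzero elements" is read as the unordered off-diagonal pairs
(edges) of Z, which carries exact zeros; diagonals, which are always
nonzero and would only shift the score by the constant 2 p K, are excluded
by default (``include_diagonal=True`` restores the strictly literal
count).  AIC is known to favor models that are too large, so an edge
density above 20% triggers a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .admm import PrecisionEstimates, rcfgl_fit
from .preprocess import CovariancePanel

logger = logging.getLogger(__name__)


@dataclass
class ModelScore:
    lambda1: float
    lambda2: float
    aic: float
    E: list  # per-condition edge counts
    converged: bool


def aic_score(est: PrecisionEstimates, cov: CovariancePanel,
              include_diagonal=False) -> ModelScore:
    """AIC of a fitted model; E_k counts exact nonzeros of Z (upper triangle)."""
    K, p = cov.K, cov.p
    iu = np.triu_indices(p, k=1)
    aic = 0.0
    E = []
    for k in range(K):
        sign, logdet = np.linalg.slogdet(est.Theta[k])
        if sign <= 0:
            raise ValueError(f"Theta[{k}] is not positive definite")
        e_k = int(np.count_nonzero(est.Z[k][iu]))
        if include_diagonal:
            e_k += int(np.count_nonzero(np.diag(est.Z[k])))
        aic += cov.n[k] * float(np.sum(cov.S[k] * est.Theta[k]))
        aic -= cov.n[k] * logdet
        aic += 2.0 * e_k
        E.append(e_k)
    cfg = est.config
    return ModelScore(lambda1=cfg.lambda1, lambda2=cfg.lambda2,
                      aic=float(aic), E=E, converged=est.converged)


def grid_search_aic(cov: CovariancePanel, weights=None, lambda1_grid=(0.1,),
                    lambda2_grid=(0.05,), lambda_scale="samples",
                    include_diagonal=False, **options):
    """Fit every (lambda1, lambda2) pair and return (scores, best, best_est).

    Warm-starts along the lambda1 axis within each lambda2 row.  Cells
    whose fit raises are recorded with aic = inf and excluded from the
    argmin; the reported lambdas in each ModelScore are the user-scale
    values.  Deterministic given the inputs.
    """
    lambda1_grid = list(lambda1_grid)
    lambda2_grid = list(lambda2_grid)
    if not lambda1_grid or not lambda2_grid:
        raise ValueError("grids must be nonempty")
    p = cov.p
    n_pairs = p * (p - 1) // 2
    scores = []
    best = None
    best_est = None
    for l2 in lambda2_grid:
        init = None
        for l1 in sorted(lambda1_grid):
            try:
                est = rcfgl_fit(cov, weights=weights, lambda1=l1, lambda2=l2,
                                lambda_scale=lambda_scale, init=init, **options)
                init = est
                sc = aic_score(est, cov, include_diagonal=include_diagonal)
                sc = ModelScore(lambda1=l1, lambda2=l2, aic=sc.aic, E=sc.E,
                                converged=sc.converged)
            except Exception as err:
                logger.warning("fit failed at lambda1=%g lambda2=%g: %s",
                               l1, l2, err)
                sc = ModelScore(lambda1=l1, lambda2=l2, aic=float("inf"),
                                E=[], converged=False)
                est = None
            scores.append(sc)
            if np.isfinite(sc.aic) and (best is None or sc.aic < best.aic):
                best = sc
                best_est = est
    if best is None:
        raise RuntimeError("every grid cell failed")
    if best.E and max(best.E) / n_pairs > 0.20:
        logger.warning(
            "AIC-chosen model has edge density %.1f%% (> 20%%); AIC tends to "
            "select models that are too large -- consider interpretability "
            "and stability as well", 100 * max(best.E) / n_pairs)
    return scores, best, best_est
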