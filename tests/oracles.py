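"""Independent oracles used by the test suite.

None of these share code with the solver path they certify: the chain prox
is checked against a bounded-variable least-squares solve of its dual and
against an exact interval-arithmetic subgradient feasibility check; the
penalized log-det problem is checked against a smoothed-objective
quasi-Newton minimizer on the upper-triangle parameterization.
"""

import numpy as np
from scipy.optimize import lsq_linear, minimize


def chain_objective(z, a, t1, t2, w):
    z = np.atleast_1d(np.asarray(z, dtype=float))
    a = np.atleast_1d(np.asarray(a, dtype=float))
    w = np.atleast_1d(np.asarray(w, dtype=float)) if len(a) > 1 else np.empty(0)
    return (0.5 * np.sum((z - a) ** 2) + t1 * np.sum(np.abs(z))
            + t2 * np.sum(w * np.abs(np.diff(z))))


def _diff_matrix(K):
    D = np.zeros((K - 1, K))
    for k in range(K - 1):
        D[k, k] = -1.0
        D[k, k + 1] = 1.0
    return D


def chain_prox_dual(a, t1, t2, w):
    """Generic convex solver for the fused-lasso chain prox via its dual.

    z = a - t1 s - D^T phi with s in [-1,1]^K, phi_k in [-t2 w_k, t2 w_k];
    the dual is a box-constrained least-squares problem, solved here with
    two independent scipy methods; the better primal objective wins.
    """
    a = np.atleast_1d(np.asarray(a, dtype=float))
    K = a.size
    if K == 1:
        M = t1 * np.eye(1)
        lo, hi = np.array([-1.0]), np.array([1.0])
    else:
        D = _diff_matrix(K)
        M = np.hstack([t1 * np.eye(K), D.T])
        box = np.concatenate([np.ones(K), t2 * np.asarray(w, dtype=float)])
        lo, hi = -box, box
    lo = lo - 1e-13
    hi = hi + 1e-13
    best = None
    for method in ("bvls", "trf"):
        res = lsq_linear(M, a, bounds=(lo, hi), tol=1e-15, max_iter=2000,
                         method=method)
        z = a - M @ res.x
        obj = chain_objective(z, a, t1, t2, w if K > 1 else [])
        if best is None or obj < best[1]:
            best = (z, obj)
    return best[0]


def chain_subgradient_gap(z, a, t1, t2, w):
    """Exact optimality certificate for the chain prox by interval propagation.

    Optimality requires duals psi_k in t2 w_k d|z_{k+1}-z_k| and
    u_k in t1 d|z_k| with z_k - a_k + u_k + psi_{k-1} - psi_k = 0,
    psi_0 = psi_K = 0.  Propagating the feasible interval for psi forward
    yields 0 at the end iff z is optimal; the return value is how far the
    intervals must be inflated for feasibility (0 at the exact optimum).
    """
    z = np.atleast_1d(np.asarray(z, dtype=float))
    a = np.atleast_1d(np.asarray(a, dtype=float))
    K = z.size
    w = np.atleast_1d(np.asarray(w, dtype=float)) if K > 1 else np.empty(0)
    zero_tol = 1e-12
    lo = hi = 0.0  # interval for psi_{k-1}, starting at psi_0 = 0
    gap = 0.0
    for k in range(K):
        # u_k interval
        if z[k] > zero_tol:
            ulo = uhi = t1
        elif z[k] < -zero_tol:
            ulo = uhi = -t1
        else:
            ulo, uhi = -t1, t1
        # psi_k = z_k - a_k + u_k + psi_{k-1}
        base = z[k] - a[k]
        plo = base + ulo + lo
        phi = base + uhi + hi
        # constraint interval for psi_k
        if k == K - 1:
            clo = chi = 0.0
        else:
            bound = t2 * w[k]
            dz = z[k + 1] - z[k]
            if dz > zero_tol:
                clo = chi = bound
            elif dz < -zero_tol:
                clo = chi = -bound
            else:
                clo, chi = -bound, bound
        new_lo = max(plo, clo)
        new_hi = min(phi, chi)
        if new_lo > new_hi:
            gap = max(gap, new_lo - new_hi)
            mid = 0.5 * (new_lo + new_hi)
            new_lo = new_hi = mid
        lo, hi = new_lo, new_hi
    return gap


def tv_prox_dual(a, lam):
    """Weighted 1-D TV denoising via its dual box QP (lsq_linear)."""
    a = np.atleast_1d(np.asarray(a, dtype=float))
    K = a.size
    if K == 1:
        return a.copy()
    D = _diff_matrix(K)
    b = np.asarray(lam, dtype=float) + 1e-13
    res = lsq_linear(D.T, a, bounds=(-b, b), tol=1e-15, max_iter=2000)
    return a - D.T @ res.x


def _smooth_abs(x, eps):
    return np.sqrt(x * x + eps * eps)


def fused_logdet_oracle(S_list, n_list, lambda1, lambda2, W_seq=None,
                        pairwise=False, W_pair=None,
                        eps_schedule=(1e-3, 1e-5, 1e-7), theta0=None):
    """Smoothed-objective minimizer of the penalized multi-condition log-det.

    Minimizes -sum_k n_k[logdet T^k - tr(S^k T^k)] + lambda1*sum_{i!=j}|T|
    + fusion (sequential weighted by W_seq, or all-pairs weighted by W_pair
    when ``pairwise``), with |x| ~ sqrt(x^2+eps^2) and eps continuation,
    L-BFGS-B on the stacked upper triangles.  Returns (theta, exact_obj).
    """
    S_list = [np.asarray(S, dtype=float) for S in S_list]
    K = len(S_list)
    p = S_list[0].shape[0]
    iu, ju = np.triu_indices(p)
    off = iu != ju
    m = iu.size
    if W_seq is None:
        W_seq = [np.ones((p, p)) for _ in range(K - 1)]
    W_seq = [np.asarray(w, dtype=float) for w in W_seq]
    if pairwise and W_pair is None:
        W_pair = {(a, b): np.ones((p, p)) for a in range(K)
                  for b in range(a + 1, K)}

    def unpack(x):
        th = np.zeros((K, p, p))
        for k in range(K):
            v = x[k * m:(k + 1) * m]
            th[k][iu, ju] = v
            th[k][ju, iu] = v
        return th

    def fg(x, eps):
        th = unpack(x)
        f = 0.0
        G = np.zeros((K, p, p))
        for k in range(K):
            try:
                c = np.linalg.cholesky(th[k])
            except np.linalg.LinAlgError:
                return np.inf, np.zeros_like(x)
            logdet = 2.0 * np.sum(np.log(np.diag(c)))
            f += -n_list[k] * (logdet - np.sum(S_list[k] * th[k]))
            G[k] += -n_list[k] * (np.linalg.inv(th[k]) - S_list[k])
            # lasso on off-diagonals, ordered pairs (factor 2)
            od = th[k].copy()
            np.fill_diagonal(od, 0.0)
            f += lambda1 * np.sum(_smooth_abs(od, eps)) - lambda1 * eps * p
            Gl = lambda1 * od / _smooth_abs(od, eps)
            np.fill_diagonal(Gl, 0.0)
            G[k] += Gl
        pairs = ([(k, k + 1, W_seq[k]) for k in range(K - 1)] if not pairwise
                 else [(a, b, W_pair[(a, b)]) for a in range(K)
                       for b in range(a + 1, K)])
        for a, b, w in pairs:
            d = th[a] - th[b]
            np.fill_diagonal(d, 0.0)
            wm = w.copy()
            np.fill_diagonal(wm, 0.0)
            f += lambda2 * np.sum(wm * _smooth_abs(d, eps))
            Gf = lambda2 * wm * d / _smooth_abs(d, eps)
            G[a] += Gf
            G[b] -= Gf
        # matrix gradient -> triangle gradient (off-diagonals appear twice)
        g = np.empty_like(x)
        for k in range(K):
            gk = G[k][iu, ju].copy()
            gk[off] += G[k][ju, iu][off]  # off-diagonal params appear twice
            g[k * m:(k + 1) * m] = gk
        return f, g

    if theta0 is not None:
        starts = [np.concatenate([np.asarray(t)[iu, ju] for t in theta0])]
    else:
        ridge = [np.linalg.inv(S + 0.2 * np.trace(S) / p * np.eye(p))
                 for S in S_list]
        starts = [
            np.concatenate([np.eye(p)[iu, ju] for _ in range(K)]),
            np.concatenate([0.5 * (r + r.T)[iu, ju] for r in ridge]),
        ]
    best = None
    for x0 in starts:
        x = x0
        for eps in eps_schedule:
            res = minimize(lambda v: fg(v, eps), x, jac=True,
                           method="L-BFGS-B",
                           options={"maxiter": 5000, "ftol": 1e-15,
                                    "gtol": 1e-12, "maxcor": 30,
                                    "maxls": 50})
            x = res.x
        theta = unpack(x)
        obj = exact_fused_objective(theta, S_list, n_list, lambda1, lambda2,
                                    W_seq, pairwise, W_pair)
        if best is None or obj < best[1]:
            best = (theta, obj)
    return best


def exact_fused_objective(theta, S_list, n_list, lambda1, lambda2,
                          W_seq=None, pairwise=False, W_pair=None):
    th = np.asarray(theta, dtype=float)
    K, p, _ = th.shape
    if W_seq is None:
        W_seq = [np.ones((p, p)) for _ in range(K - 1)]
    f = 0.0
    for k in range(K):
        sign, logdet = np.linalg.slogdet(th[k])
        assert sign > 0
        f += -n_list[k] * (logdet - np.sum(S_list[k] * th[k]))
        od = th[k].copy()
        np.fill_diagonal(od, 0.0)
        f += lambda1 * np.sum(np.abs(od))
    pairs = ([(k, k + 1, W_seq[k]) for k in range(K - 1)] if not pairwise
             else [(a, b, W_pair[(a, b)]) for a in range(K)
                   for b in range(a + 1, K)])
    for a, b, w in pairs:
        d = np.abs(th[a] - th[b]) * np.asarray(w)
        f += lambda2 * (np.sum(d) - np.sum(np.diag(d)))
    return float(f)
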