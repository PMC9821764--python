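"""Exact proximal operators for the fused-lasso Z step.

The ADMM Z update decouples over matrix entries: for each gene pair (i, j)
one solves, over the K-vector z = (Z_ij^(1), ..., Z_ij^(K)),

    min_z  t1 * sum_k |z_k|  +  t2 * sum_k w_k |z_k - z_{k+1}|
           + 1/2 * sum_k (z_k - a_k)^2,

with t1 = lambda1/rho, t2 = lambda2/rho and w the chain of fusion weights
between consecutive conditions.  This module solves that problem exactly:

* the pure total-variation part (t1 = 0) is 1-D TV denoising, solved by a
  taut-string construction that handles arbitrary nonnegative, possibly
  zero, per-link weights;
* the combined problem is solved by fusing first and shrinking second
  (``soft_threshold`` applied to the weighted-TV output), the known exact
  decomposition for the chain fused lasso.

Zero fusion weights decouple the chain exactly: each maximal run of
positive weights is an independent TV problem.  The kernels are plain
Python loops compiled with numba when it is importable, and run as-is
otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    NUMBA = True
except ImportError:  # pragma: no cover
    NUMBA = False

    def njit(*args, **kwargs):
        if len(args) == 1 and callable(args[0]):
            return args[0]

        def deco(func):
            return func

        return deco


@njit(cache=True)
def _taut_string(a, lam, z):
    """Exact 1-D weighted TV denoising via the taut-string construction.

    Minimizes 1/2 ||z - a||^2 + sum_k lam_k |z_{k+1} - z_k| by threading the
    shortest (taut) string through the tube of halfwidth lam_k around the
    running sums of ``a``; the string's increments are the solution.  The
    tube is pinned at both ends, so the mean of ``a`` is preserved.  Writes
    into ``z`` (length K); ``lam`` has length K-1, entries >= 0 (a zero
    pinches the tube shut, forcing the string through that knot).
    """
    K = a.shape[0]
    if K == 1:
        z[0] = a[0]
        return
    s = np.empty(K + 1)
    s[0] = 0.0
    for i in range(K):
        s[i + 1] = s[i] + a[i]
    ub = s.copy()
    lb = s.copy()
    for k in range(1, K):
        ub[k] += lam[k - 1]
        lb[k] -= lam[k - 1]
    ax = 0  # anchor knot: last point the string is known to pass through
    ay = 0.0
    while ax < K:
        hi = np.inf  # smallest feasible slope against the upper tube
        lo = -np.inf  # largest feasible slope against the lower tube
        hi_x = ax + 1
        lo_x = ax + 1
        done = False
        for x in range(ax + 1, K + 1):
            su = (ub[x] - ay) / (x - ax)
            sl = (lb[x] - ay) / (x - ax)
            if su < hi:
                hi = su
                hi_x = x
            if sl > lo:
                lo = sl
                lo_x = x
            if lo > hi:
                # No straight line fits: the string bends at a tube wall.
                # If the lower wall caused the conflict the string touches
                # the upper wall at its binding knot, and conversely.
                if lo_x == x:
                    for j in range(ax, hi_x):
                        z[j] = hi
                    ay = ub[hi_x]
                    ax = hi_x
                else:
                    for j in range(ax, lo_x):
                        z[j] = lo
                    ay = lb[lo_x]
                    ax = lo_x
                done = True
                break
        if not done:
            slope = (s[K] - ay) / (K - ax)
            for j in range(ax, K):
                z[j] = slope
            ax = K
    return


@njit(cache=True)
def _chain_prox_batch(A, W, t1, t2, out):
    """Solve the fused-lasso prox for a batch of chains.

    A: (m, K) inputs, W: (m, K-1) fusion weights, out: (m, K).  Each chain
    is split at zero-weight links into independent TV segments, denoised,
    then soft-thresholded by t1.
    """
    m, K = A.shape
    buf = np.empty(K)
    lam = np.empty(K)
    z = np.empty(K)
    for i in range(m):
        start = 0
        while start < K:
            end = start
            while end < K - 1 and t2 * W[i, end] > 0.0:
                end += 1
            L = end - start + 1
            for j in range(L):
                buf[j] = A[i, start + j]
            for j in range(L - 1):
                lam[j] = t2 * W[i, start + j]
            _taut_string(buf[:L], lam[: L - 1], z[:L])
            for j in range(L):
                v = z[j]
                if v > t1:
                    out[i, start + j] = v - t1
                elif v < -t1:
                    out[i, start + j] = v + t1
                else:
                    out[i, start + j] = 0.0
            start = end + 1
    return


@dataclass
class ChainSignal:
    """One matrix entry's cross-condition chain for the Z subproblem.

    a : values A_ij^(1..K); w : K-1 nonnegative fusion weights between
    consecutive conditions; t1, t2 : effective lasso / fusion strengths
    (lambda1/rho, lambda2/rho).
    """

    a: np.ndarray
    w: np.ndarray = field(default=None)
    t1: float = 0.0
    t2: float = 0.0

    def __post_init__(self):
        self.a = np.atleast_1d(np.asarray(self.a, dtype=float))
        if self.w is None:
            self.w = np.ones(self.a.size - 1)
        self.w = np.atleast_1d(np.asarray(self.w, dtype=float)) \
            if self.a.size > 1 else np.empty(0)
        if self.w.size != self.a.size - 1:
            raise ValueError(
                f"need len(w) == len(a) - 1, got {self.w.size} != {self.a.size - 1}"
            )
        if self.t1 < 0 or self.t2 < 0:
            raise ValueError("t1 and t2 must be nonnegative")
        if np.any(self.w < 0):
            raise ValueError("fusion weights must be nonnegative")


def soft_threshold(x, t):
    """Lasso prox: sign(x) * max(|x| - t, 0)."""
    if t < 0:
        raise ValueError("threshold must be nonnegative")
    x = np.asarray(x, dtype=float)
    out = np.sign(x) * np.maximum(np.abs(x) - t, 0.0)
    return float(out) if out.ndim == 0 else out


def tv1d_prox(a, t):
    """Uniform-weight 1-D TV denoising: argmin 1/2||z-a||^2 + t*sum|dz|."""
    a = np.atleast_1d(np.asarray(a, dtype=float))
    if a.size == 0:
        raise ValueError("empty input")
    if t < 0:
        raise ValueError("t must be nonnegative")
    z = np.empty_like(a)
    _taut_string(a, np.full(max(a.size - 1, 0), float(t)), z)
    return z


def weighted_tv_prox(a, t, w):
    """Weighted 1-D TV denoising: argmin 1/2||z-a||^2 + t*sum w_k|dz_k|.

    Zero weights decouple the chain; each maximal positive-weight segment is
    solved independently by the taut string.
    """
    sig = ChainSignal(a=a, w=w, t1=0.0, t2=float(t))
    out = np.empty((1, sig.a.size))
    _chain_prox_batch(sig.a[None, :], sig.w[None, :], 0.0, sig.t2, out)
    return out[0]


def fused_lasso_prox_1d(sig: ChainSignal) -> np.ndarray:
    """Exact minimizer of the weighted 1-D fused lasso signal approximator.

    Computed as soft_threshold(weighted_tv_prox(a, t2, w), t1): fuse first,
    shrink second.  For K = 1 this reduces to plain soft-thresholding.
    """
    out = np.empty((1, sig.a.size))
    _chain_prox_batch(sig.a[None, :], sig.w[None, :], sig.t1, sig.t2, out)
    return out[0]


def chain_prox_batch(A, W, t1, t2):
    """Vectorized fused-lasso prox over m chains (A: (m,K), W: (m,K-1))."""
    A = np.ascontiguousarray(A, dtype=float)
    W = np.ascontiguousarray(W, dtype=float)
    if t1 < 0 or t2 < 0:
        raise ValueError("t1 and t2 must be nonnegative")
    if np.any(W < 0):
        raise ValueError("fusion weights must be nonnegative")
    out = np.empty_like(A)
    _chain_prox_batch(A, W, float(t1), float(t2), out)
    return out
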