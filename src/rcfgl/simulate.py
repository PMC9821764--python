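"""Synthetic multi-condition co-expression data with known ground truth.

Each condition's gene network is block-diagonal: ``n_blocks`` sub-networks
of ``block_size`` genes (default 5 x 100).  A sharing map says, per block,
which conditions carry the same sub-network; shared blocks reuse one
simulated network, unshared blocks are drawn independently.  Each
sub-network topology comes from the Barabasi-Albert preferential-attachment
model (scale-free, like real co-expression graphs); edge weights are
Unif([-0.9, -0.6] u [0.6, 0.9]); the weighted matrix A gets an eigenvalue
shift A* = A + (|delta| + eps) I (delta its smallest eigenvalue -- the
bare |delta| shift would leave A* singular, so a slack eps > 0 is added)
and is standardized to a unit-diagonal covariance
Sigma_ij = [A*^-1]_ij / sqrt([A*^-1]_ii [A*^-1]_jj).  The true precision
is Theta_ij = A*_ij * sqrt([A*^-1]_ii [A*^-1]_jj), so its support equals
the simulated adjacency exactly.  Samples are i.i.d. N_p(0, Sigma_k).

Built-in scenarios (K conditions; "=" marks identical networks):
S1 K=3, 1=2, condition 3 shares blocks 1-3 only; S2 K=3, 1=2, 3
independent; S3 K=4, 1=2 and 3=4; S4 K=4, 1=2 only; S5 K=3, 1=3; S6 K=4,
1=3; S7 K=4, 1=4.  Defaults follow the study design: 500 genes, 100
samples per condition, ten replicates with consecutive seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .io import ExpressionPanel
from .weights import WeightSet, oracle_weights

#: per scenario: list over blocks of per-condition sharing labels
_SHARING = {
    "S1": [(0, 0, 0)] * 3 + [(0, 0, 1)] * 2,
    "S2": [(0, 0, 1)] * 5,
    "S3": [(0, 0, 1, 1)] * 5,
    "S4": [(0, 0, 1, 2)] * 5,
    "S5": [(0, 1, 0)] * 5,
    "S6": [(0, 1, 0, 2)] * 5,
    "S7": [(0, 1, 2, 0)] * 5,
}

SCENARIO_NAMES = tuple(sorted(_SHARING))


@dataclass
class SimScenario:
    """Generator specification for one multi-condition experiment."""

    name: str
    K: int
    sharing: list  # per block, a K-tuple of group labels
    n: object = 100  # samples per condition (int or per-condition list)
    block_size: int = 100
    ba_m: int = 1
    d_range: tuple = (0.6, 0.9)  # magnitude support; signs are symmetric
    eps: float = 0.1
    seed: int = 0

    def __post_init__(self):
        self.sharing = [tuple(s) for s in self.sharing]
        for s in self.sharing:
            if len(s) != self.K:
                raise ValueError(
                    f"sharing entry {s} does not cover all {self.K} conditions")
        if np.isscalar(self.n):
            self.n = [int(self.n)] * self.K
        if len(self.n) != self.K:
            raise ValueError("need one sample size per condition")

    @property
    def n_blocks(self):
        return len(self.sharing)

    @property
    def p(self):
        return self.n_blocks * self.block_size


@dataclass
class TruthPanel:
    """Ground truth of a simulated experiment."""

    conditions: list
    gene_ids: list
    Theta: np.ndarray  # (K, p, p), exact zeros off the simulated support
    Sigma: np.ndarray  # (K, p, p), unit diagonal
    adjacency: np.ndarray  # (K, p, p) bool
    blocks: list  # gene-index lists per block
    weights: WeightSet = field(default=None)  # oracle weights
    spec: SimScenario = field(default=None)


def scenario(name, **overrides) -> SimScenario:
    """Built-in scenario by name (S1..S7), with optional field overrides."""
    if name not in _SHARING:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")
    sharing = _SHARING[name]
    return SimScenario(name=name, K=len(sharing[0]), sharing=sharing, **overrides)


def simulate_ba_topology(p, m, seed):
    """Barabasi-Albert adjacency: symmetric 0/1, zero diagonal, connected."""
    if p < 2:
        raise ValueError("need p >= 2")
    if m < 1 or m >= p:
        raise ValueError("need 1 <= m < p")
    g = nx.barabasi_albert_graph(p, m, seed=int(seed))
    adj = nx.to_numpy_array(g, dtype=bool)
    return adj


def build_precision_from_topology(adj, d_range=(0.6, 0.9), eps=0.1, rng=None):
    """Weighted network -> (true precision, unit-diagonal covariance).

    Edge weights are drawn uniformly from +-[d_lo, d_hi]; the eigenvalue
    shift and the correlation-style standardization guarantee a PD Sigma
    with exactly the requested support in Theta.
    """
    rng = np.random.default_rng(rng)
    adj = np.asarray(adj, dtype=bool)
    p = adj.shape[0]
    iu, ju = np.triu_indices(p, k=1)
    on = adj[iu, ju]
    mag = rng.uniform(d_range[0], d_range[1], size=int(on.sum()))
    sign = rng.choice([-1.0, 1.0], size=mag.size)
    A = np.eye(p)
    A[iu[on], ju[on]] = sign * mag
    A[ju[on], iu[on]] = A[iu[on], ju[on]]
    delta = float(np.linalg.eigvalsh(A)[0])
    Astar = A + (abs(delta) + eps) * np.eye(p)
    Minv = np.linalg.inv(Astar)
    dM = np.diag(Minv)
    Sigma = Minv / np.sqrt(np.outer(dM, dM))
    Sigma = 0.5 * (Sigma + Sigma.T)
    np.fill_diagonal(Sigma, 1.0)
    # Theta = Sigma^-1 = E^-1 A* E^-1 with E = diag(1/sqrt(dM)); computing it
    # this way keeps the zeros of the adjacency exact.
    Theta = Astar * np.sqrt(np.outer(dM, dM))
    Theta = 0.5 * (Theta + Theta.T)
    return Theta, Sigma


def simulate_scenario(spec: SimScenario):
    """Generate (TruthPanel, ExpressionPanel) for a scenario, fully seeded."""
    rng = np.random.default_rng(spec.seed)
    K, p, bs = spec.K, spec.p, spec.block_size
    conditions = [f"cond{k + 1}" for k in range(K)]
    width = len(str(p))
    gene_ids = [f"g{i + 1:0{width}d}" for i in range(p)]
    Theta = np.zeros((K, p, p))
    Sigma = np.zeros((K, p, p))
    adjacency = np.zeros((K, p, p), dtype=bool)
    blocks = []
    chol_blocks = [[None] * spec.n_blocks for _ in range(K)]
    for b, labels in enumerate(spec.sharing):
        sl = slice(b * bs, (b + 1) * bs)
        blocks.append(list(range(b * bs, (b + 1) * bs)))
        per_label = {}
        for lab in labels:  # generation order = first appearance per block
            if lab in per_label:
                continue
            adj = simulate_ba_topology(bs, spec.ba_m,
                                       seed=int(rng.integers(2 ** 31)))
            th, sg = build_precision_from_topology(adj, spec.d_range,
                                                  spec.eps, rng)
            per_label[lab] = (adj, th, sg, np.linalg.cholesky(sg))
        for k, lab in enumerate(labels):
            adj, th, sg, L = per_label[lab]
            adjacency[k][sl, sl] = adj
            Theta[k][sl, sl] = th
            Sigma[k][sl, sl] = sg
            chol_blocks[k][b] = L
    Y = []
    for k in range(K):
        G = rng.standard_normal((spec.n[k], p))
        yk = np.empty_like(G)
        for b in range(spec.n_blocks):
            sl = slice(b * bs, (b + 1) * bs)
            yk[:, sl] = G[:, sl] @ chol_blocks[k][b].T
        Y.append(yk)
    truth = TruthPanel(
        conditions=conditions, gene_ids=gene_ids, Theta=Theta, Sigma=Sigma,
        adjacency=adjacency, blocks=blocks,
        weights=(oracle_weights(list(Theta), conditions=conditions)
                 if K >= 2 else None), spec=spec,
    )
    panel = ExpressionPanel(conditions=conditions, Y=Y, gene_ids=gene_ids)
    return truth, panel
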