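"""Evaluation measures for simulated network recovery and method comparison."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import NetworkSet


@dataclass
class EvalReport:
    """Edge-detection counts over all conditions and unordered gene pairs.

    ``precision`` is None (undefined) when nothing was detected.
    """

    TP: int
    FP: int
    FN: int
    precision: object  # float or None
    recall: float
    sse: float = None
    tol: float = 0.01


def precision_recall(est, truth, tol=0.01) -> EvalReport:
    """Edge detection against the truth at detection threshold ``tol``.

    An estimated entry with |Theta_hat_ij| >= tol counts as a detected
    edge; a true edge is any nonzero off-diagonal true entry.  Counts are
    pooled over conditions and unordered pairs i < j.
    """
    That = est.Theta if hasattr(est, "Theta") else np.asarray(est, dtype=float)
    Ttrue = truth.Theta if hasattr(truth, "Theta") else np.asarray(truth, dtype=float)
    if That.shape != Ttrue.shape:
        raise ValueError(f"shape mismatch: {That.shape} vs {Ttrue.shape}")
    K, p, _ = That.shape
    iu = np.triu_indices(p, k=1)
    tp = fp = fn = 0
    for k in range(K):
        true_edge = Ttrue[k][iu] != 0
        found = np.abs(That[k][iu]) >= tol
        tp += int(np.sum(true_edge & found))
        fp += int(np.sum(~true_edge & found))
        fn += int(np.sum(true_edge & ~found))
    prec = tp / (tp + fp) if (tp + fp) > 0 else None
    rec = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    return EvalReport(TP=tp, FP=fp, FN=fn, precision=prec, recall=rec, tol=tol)


def sse_metric(est, truth) -> float:
    """Sum of squared errors over all p x p entries and all conditions."""
    That = est.Theta if hasattr(est, "Theta") else np.asarray(est, dtype=float)
    Ttrue = truth.Theta if hasattr(truth, "Theta") else np.asarray(truth, dtype=float)
    if That.shape != Ttrue.shape:
        raise ValueError(f"shape mismatch: {That.shape} vs {Ttrue.shape}")
    return float(np.sum((That - Ttrue) ** 2))


def top_edges(est, Z, source="theta"):
    """Per-condition top-Z edge sets ranked by |entry|.

    Ranks off-diagonal entries of Theta (default) or of the sparse Z panel
    by absolute value within each condition; ties break lexicographically
    on (i, j).  Returns a list of sets of index pairs (i, j), i < j.
    """
    panel = est.Theta if source == "theta" else est.Z
    K, p, _ = panel.shape
    iu, ju = np.triu_indices(p, k=1)
    out = []
    for k in range(K):
        vals = np.abs(panel[k][iu, ju])
        order = np.lexsort((ju, iu, -vals))
        take = order[: int(Z)]
        out.append({(int(iu[t]), int(ju[t])) for t in take})
    return out


def jaccard_top_edges(netsA, netsB) -> float:
    """Jaccard index of the unions of per-condition edge sets.

    |(U_i M_i) n (U_i N_i)| / |(U_i M_i) u (U_i N_i)| over unordered gene
    pairs; 1 means the two methods report the same top edges.
    """
    ua = set().union(*[set(s) for s in netsA]) if netsA else set()
    ub = set().union(*[set(s) for s in netsB]) if netsB else set()
    denom = len(ua | ub)
    return 1.0 if denom == 0 else len(ua & ub) / denom


def categorize_edges(nets) -> dict:
    """Partition detected edges by the exact subset of conditions containing them.

    ``nets``: a NetworkSet, or a list of per-condition edge collections of
    (i, j) pairs.  Returns {condition-subset tuple: count}; for K = 3 the
    nonempty subsets are the seven mutually exclusive categories, and the
    counts sum to the number of distinct edges.
    """
    if isinstance(nets, NetworkSet):
        conds = nets.conditions
        per_cond = [
            {tuple(r) for r in nets.edges[c][["gene_i", "gene_j"]].itertuples(index=False)}
            for c in conds
        ]
    else:
        per_cond = [set(map(tuple, s)) for s in nets]
        conds = list(range(len(per_cond)))
    all_edges = set().union(*per_cond) if per_cond else set()
    counts = {}
    for e in all_edges:
        subset = tuple(conds[k] for k in range(len(conds)) if e in per_cond[k])
        counts[subset] = counts.get(subset, 0) + 1
    return counts


def hub_genes(net, min_degree=5):
    """Genes with more than ``min_degree`` connections (strict inequality).

    ``net``: a single condition's edge collection -- a NetworkSet edge
    DataFrame or an iterable of (gene_i, gene_j) pairs.  Returns
    [(gene, degree)] sorted by degree descending, then gene ID.
    """
    if hasattr(net, "itertuples"):
        pairs = [(r.gene_i, r.gene_j) for r in net.itertuples(index=False)]
    else:
        pairs = [(a, b) for a, b, *_ in (tuple(e) for e in net)]
    deg = {}
    for a, b in pairs:
        deg[a] = deg.get(a, 0) + 1
        deg[b] = deg.get(b, 0) + 1
    hubs = [(g, d) for g, d in deg.items() if d > min_degree]
    hubs.sort(key=lambda gd: (-gd[1], str(gd[0])))
    return hubs
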