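"""Reading and writing expression panels, networks and precision matrices.

File conventions: expression files are delimited text, one file per
condition, header row of gene IDs, rows = samples (a transpose flag handles
genes-in-rows files).  Networks are written either as long-format edge
lists (condition, gene_i, gene_j, weight) or as dense symmetric adjacency
CSVs.  All writers round-trip at full floating precision.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ExpressionPanel:
    """K expression matrices with a shared, ordered gene set.

    conditions : K condition labels, order matters (it is the fusion order).
    Y : per condition an (n_k, p) float matrix, rows = samples.
    gene_ids : p gene identifiers shared by every condition.
    """

    conditions: list
    Y: list
    gene_ids: list

    def __post_init__(self):
        self.conditions = [str(c) for c in self.conditions]
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.Y = [np.asarray(y, dtype=float) for y in self.Y]
        if len(self.conditions) != len(self.Y):
            raise ValueError("one expression matrix per condition required")
        if len(set(self.conditions)) != len(self.conditions):
            raise ValueError("condition labels must be unique")
        p = len(self.gene_ids)
        if p < 2:
            raise ValueError("need at least 2 genes")
        for c, y in zip(self.conditions, self.Y):
            if y.ndim != 2 or y.shape[1] != p:
                raise ValueError(
                    f"condition {c!r}: expected shape (n_k, {p}), got {y.shape}"
                )
            if y.shape[0] < 2:
                raise ValueError(f"condition {c!r}: need at least 2 samples")
            if not np.all(np.isfinite(y)):
                raise ValueError(f"condition {c!r}: non-finite values present")

    @property
    def K(self):
        return len(self.conditions)

    @property
    def p(self):
        return len(self.gene_ids)

    @property
    def n(self):
        return np.array([y.shape[0] for y in self.Y])

    def reorder_conditions(self, order):
        """Return a panel with conditions permuted into ``order`` (labels or indices)."""
        idx = [self.conditions.index(o) if isinstance(o, str) else int(o)
               for o in order]
        if sorted(idx) != list(range(self.K)):
            raise ValueError("order must be a permutation of the conditions")
        return ExpressionPanel(
            conditions=[self.conditions[i] for i in idx],
            Y=[self.Y[i] for i in idx],
            gene_ids=list(self.gene_ids),
        )


@dataclass
class NetworkSet:
    """Per-condition edge tables over unordered gene pairs (i < j)."""

    conditions: list
    gene_ids: list
    edges: dict  # condition -> DataFrame[gene_i, gene_j, weight]

    def __post_init__(self):
        self.conditions = [str(c) for c in self.conditions]
        self.gene_ids = [str(g) for g in self.gene_ids]
        known = set(self.gene_ids)
        order = {g: i for i, g in enumerate(self.gene_ids)}
        norm = {}
        for c in self.conditions:
            df = self.edges.get(c)
            if df is None:
                df = pd.DataFrame(columns=["gene_i", "gene_j", "weight"])
            df = pd.DataFrame(df, columns=["gene_i", "gene_j", "weight"]).copy()
            df["gene_i"] = df["gene_i"].astype(str)
            df["gene_j"] = df["gene_j"].astype(str)
            df["weight"] = df["weight"].astype(float)
            for col in ("gene_i", "gene_j"):
                bad = set(df[col]) - known
                if bad:
                    raise ValueError(f"condition {c!r}: unknown genes {sorted(bad)}")
            if (df["gene_i"] == df["gene_j"]).any():
                raise ValueError(f"condition {c!r}: self-loops are not allowed")
            # canonical i < j orientation by gene order
            gi = df["gene_i"].map(order)
            gj = df["gene_j"].map(order)
            flip = gi > gj
            df.loc[flip, ["gene_i", "gene_j"]] = df.loc[
                flip, ["gene_j", "gene_i"]
            ].values
            norm[c] = df.reset_index(drop=True)
        self.edges = norm


def _read_one(path, delimiter):
    if not os.path.exists(path):
        raise FileNotFoundError(f"expression file not found: {path}")
    sep = delimiter
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=None,
                     float_precision="round_trip")
    return df


def read_expression_panel(paths, conditions=None, delimiter=None,
                          transpose=False, intersect=False):
    """Read one delimited file per condition into an :class:`ExpressionPanel`.

    Each file must have a header row of gene IDs and a numeric body
    (rows = samples unless ``transpose``).  Gene sets must agree across
    files; with ``intersect=True`` the common genes are taken, in the order
    of the first file, otherwise any mismatch is an error.  Missing or
    non-numeric cells are an error (the Gaussian likelihood assumes
    complete rows); the offending file, row and column are named.
    """
    paths = list(paths)
    if conditions is None:
        conditions = [os.path.splitext(os.path.basename(p))[0] for p in paths]
    frames = []
    for path in paths:
        df = _read_one(path, delimiter)
        if transpose:
            df = df.set_index(df.columns[0]).T.reset_index(drop=True)
            df.columns = [str(c) for c in df.columns]
        for col in df.columns:
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = vals.index[vals.isna()]
            if len(bad):
                raise ValueError(
                    f"non-numeric or missing value in {path}, "
                    f"row {int(bad[0])}, column {col!r}"
                )
            df[col] = vals
        frames.append(df)
    gene_sets = [list(df.columns) for df in frames]
    common = gene_sets[0]
    if intersect:
        keep = set(common)
        for gs in gene_sets[1:]:
            keep &= set(gs)
        common = [g for g in gene_sets[0] if g in keep]
        if len(common) < 2:
            raise ValueError("fewer than 2 genes shared across conditions")
        frames = [df[common] for df in frames]
    else:
        for path, gs in zip(paths, gene_sets):
            if sorted(gs) != sorted(common):
                raise ValueError(
                    f"gene set of {path} differs from {paths[0]}; "
                    "pass intersect=True to take the common genes"
                )
        frames = [df[common] for df in frames]
    return ExpressionPanel(
        conditions=list(conditions),
        Y=[df.to_numpy(dtype=float) for df in frames],
        gene_ids=list(common),
    )


def write_expression_panel(panel: ExpressionPanel, outdir, delimiter="\t"):
    """Write one <condition>.tsv per condition; returns the paths."""
    os.makedirs(outdir, exist_ok=True)
    ext = "csv" if delimiter == "," else "tsv"
    paths = []
    for c, y in zip(panel.conditions, panel.Y):
        _check_label(c)
        path = os.path.join(outdir, f"{c}.{ext}")
        pd.DataFrame(y, columns=panel.gene_ids).to_csv(
            path, sep=delimiter, index=False, float_format="%.17g"
        )
        paths.append(path)
    return paths


def _check_label(label):
    if os.sep in label or (os.altsep and os.altsep in label) or "/" in label:
        raise ValueError(f"condition label {label!r} contains a path separator")


def write_network_set(net: NetworkSet, path, format="edgelist"):
    """Write a NetworkSet as a long edge-list TSV or dense adjacency CSVs.

    ``edgelist``: single TSV with columns (condition, gene_i, gene_j,
    weight).  ``adjacency``: ``path`` is a directory receiving one
    symmetric, zero-diagonal CSV per condition.
    """
    if format == "edgelist":
        rows = []
        for c in net.conditions:
            df = net.edges[c].copy()
            df.insert(0, "condition", c)
            rows.append(df)
        out = (pd.concat(rows, ignore_index=True) if rows else
               pd.DataFrame(columns=["condition", "gene_i", "gene_j", "weight"]))
        out.to_csv(path, sep="\t", index=False, float_format="%.17g")
    elif format == "adjacency":
        os.makedirs(path, exist_ok=True)
        order = {g: i for i, g in enumerate(net.gene_ids)}
        p = len(net.gene_ids)
        for c in net.conditions:
            _check_label(c)
            mat = np.zeros((p, p))
            for _, r in net.edges[c].iterrows():
                i, j = order[r["gene_i"]], order[r["gene_j"]]
                mat[i, j] = mat[j, i] = r["weight"]
            pd.DataFrame(mat, index=net.gene_ids, columns=net.gene_ids).to_csv(
                os.path.join(path, f"network_{c}.csv"), float_format="%.17g"
            )
    else:
        raise ValueError(f"unknown format {format!r}")


def read_network_set(path, format="edgelist", conditions=None, gene_ids=None):
    """Inverse of :func:`write_network_set`."""
    if format == "edgelist":
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        conds = (list(dict.fromkeys(df["condition"].astype(str)))
                 if conditions is None else list(conditions))
        if gene_ids is None:
            gene_ids = sorted(set(df["gene_i"].astype(str)) |
                              set(df["gene_j"].astype(str)))
        edges = {}
        for c in conds:
            sub = df[df["condition"].astype(str) == c]
            edges[c] = sub[["gene_i", "gene_j", "weight"]]
        return NetworkSet(conditions=conds, gene_ids=list(gene_ids), edges=edges)
    elif format == "adjacency":
        if conditions is None:
            raise ValueError("conditions required to read adjacency format")
        edges = {}
        gids = None
        for c in conditions:
            mat = pd.read_csv(os.path.join(path, f"network_{c}.csv"),
                              index_col=0, float_precision="round_trip")
            gids = [str(g) for g in mat.columns]
            arr = mat.to_numpy(dtype=float)
            iu = np.triu_indices(len(gids), k=1)
            nz = arr[iu] != 0
            edges[c] = pd.DataFrame({
                "gene_i": [gids[i] for i in iu[0][nz]],
                "gene_j": [gids[j] for j in iu[1][nz]],
                "weight": arr[iu][nz],
            })
        return NetworkSet(conditions=list(conditions), gene_ids=gids, edges=edges)
    raise ValueError(f"unknown format {format!r}")


def write_precision_panel(estimates, outdir):
    """Write theta_<cond>.csv and z_<cond>.csv per condition (dense, full precision)."""
    os.makedirs(outdir, exist_ok=True)
    gids = estimates.gene_ids
    for k, c in enumerate(estimates.conditions):
        _check_label(c)
        for name, panel in (("theta", estimates.Theta), ("z", estimates.Z)):
            pd.DataFrame(panel[k], index=gids, columns=gids).to_csv(
                os.path.join(outdir, f"{name}_{c}.csv"), float_format="%.17g"
            )


def read_precision_panel(outdir, conditions):
    """Read back matrices written by :func:`write_precision_panel`.

    Returns (Theta, Z, gene_ids) with Theta, Z of shape (K, p, p).
    """
    thetas, zs, gids = [], [], None
    for c in conditions:
        th = pd.read_csv(os.path.join(outdir, f"theta_{c}.csv"), index_col=0,
                         float_precision="round_trip")
        zz = pd.read_csv(os.path.join(outdir, f"z_{c}.csv"), index_col=0,
                         float_precision="round_trip")
        gids = [str(g) for g in th.columns]
        thetas.append(th.to_numpy(dtype=float))
        zs.append(zz.to_numpy(dtype=float))
    return np.array(thetas), np.array(zs), gids


def network_from_estimates(estimates, source="z"):
    """Build a NetworkSet from the exact-zero pattern of the estimates.

    Edges are the nonzero off-diagonal entries of Z (default) or of
    Theta; the stored weight is the corresponding matrix entry.
    """
    panel = estimates.Z if source == "z" else estimates.Theta
    gids = estimates.gene_ids
    p = len(gids)
    iu = np.triu_indices(p, k=1)
    edges = {}
    for k, c in enumerate(estimates.conditions):
        vals = panel[k][iu]
        nz = vals != 0
        edges[c] = pd.DataFrame({
            "gene_i": [gids[i] for i in iu[0][nz]],
            "gene_j": [gids[j] for j in iu[1][nz]],
            "weight": vals[nz],
        })
    return NetworkSet(conditions=list(estimates.conditions),
                      gene_ids=list(gids), edges=edges)
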