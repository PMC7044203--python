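"""Marker-regression cell-type mapping.

Each cell is scored against a binary marker panel with a linear probability
model: the panel column for cell type ``c`` (1 = marker of that type) is
regressed on the cell's expression over the panel genes,

    y_c = b0 + b1 * x_s + e,      e ~ N(0, sigma^2),

and the slope's t-statistic (G - 2 degrees of freedom, G = panel genes)
measures how specifically the cell expresses that type's markers.  A cell
is a candidate for every type with p < p0 and t > 0; clusters vote through
the proportion of their cells passing each type's threshold, and small or
silent clusters are merged into the nearest assigned cluster in the 2-D
embedding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "CellTypeScores", "CellTypeAssignment", "validate_panel", "score_cells",
    "call_cells", "cluster_profile", "assign_clusters", "MarkerMapper",
    "MappingResults", "UNASSIGNED",
]

UNASSIGNED = "unassigned"
_T_CAP = 1e6  # stands in for +/- infinity on perfect fits


def validate_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Check a genes x cell-types marker panel: binary, >=3 genes, and a
    response column with variance (>=1 marker, not all genes) per type."""
    import warnings

    values = panel.to_numpy()
    if not np.isin(values, (0, 1)).all():
        raise ValueError("marker panel must be binary")
    if panel.shape[0] < 3:
        raise ValueError("marker panel needs >= 3 genes (regression df)")
    degenerate = [c for c in panel.columns
                  if panel[c].sum() == 0 or panel[c].sum() == panel.shape[0]]
    if degenerate:
        raise ValueError(
            f"cell types with a constant marker column: {degenerate}")
    weak = [c for c in panel.columns if panel[c].sum() < 2]
    if weak:
        warnings.warn(f"cell types with a single marker gene: {weak}")
    if panel.index.duplicated().any():
        raise ValueError("duplicated genes in marker panel")
    return panel.astype(np.int8)


@dataclass
class CellTypeScores:
    """Per-cell, per-type LPM slope, t, and p, plus the call threshold."""

    beta: pd.DataFrame       # cells x types, slope b1
    t: pd.DataFrame          # cells x types
    p: pd.DataFrame          # cells x types
    p0: float = 0.01
    unassignable: np.ndarray = field(default=None)  # cells with constant x

    def pass_matrix(self) -> pd.DataFrame:
        """Indicator of (t > 0) & (p < p0) per cell and type."""
        return (self.t > 0) & (self.p < self.p0)


def score_cells(
    expr: pd.DataFrame,
    panel: pd.DataFrame,
    p0: float = 0.01,
) -> CellTypeScores:
    """Fit the per-cell linear probability model against every cell type.

    ``expr`` is cells x genes expression (any genes; it is restricted to
    the panel's genes, which must all be present).  Cells whose expression
    is constant across the panel genes have an undefined slope and are
    flagged unassignable.
    """
    panel = validate_panel(panel)
    missing = panel.index.difference(expr.columns)
    if len(missing):
        raise ValueError(
            f"{len(missing)} panel genes absent from expression matrix, "
            f"e.g. {list(missing[:5])}"
        )
    X = expr.loc[:, panel.index].to_numpy(dtype=np.float64)   # S x G
    Y = panel.to_numpy(dtype=np.float64)                      # G x C
    S, G = X.shape
    dof = G - 2

    Xc = X - X.mean(axis=1, keepdims=True)
    Sxx = (Xc ** 2).sum(axis=1)                               # S
    Sxy = Xc @ Y                                              # S x C
    Syy = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)             # C

    unassignable = Sxx <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = Sxy / Sxx[:, None]
        rss = np.clip(Syy[None, :] - beta * Sxy, 0.0, None)
        sigma2 = rss / dof
        t = beta / np.sqrt(sigma2 / Sxx[:, None])
    # perfect fits: zero residual variance with a defined slope
    perfect = (sigma2 <= 1e-300) & ~unassignable[:, None] & (np.abs(beta) > 0)
    t[perfect] = np.sign(beta[perfect]) * _T_CAP
    t = np.clip(t, -_T_CAP, _T_CAP)
    p = 2 * scipy.stats.t.sf(np.abs(t), df=dof)
    p[perfect] = 0.0
    t[unassignable] = np.nan
    p[unassignable] = np.nan

    idx, cols = expr.index, panel.columns
    return CellTypeScores(
        beta=pd.DataFrame(beta, index=idx, columns=cols),
        t=pd.DataFrame(t, index=idx, columns=cols),
        p=pd.DataFrame(p, index=idx, columns=cols),
        p0=p0,
        unassignable=unassignable,
    )


def call_cells(scores: CellTypeScores) -> pd.Series:
    """Assign each cell the single best-passing type, or ``unassigned``.

    Candidates are types with p < p0 and t > 0; among multiple candidates
    the smallest p wins, ties go to the largest t, residual ties to the
    lexicographically first type name.
    """
    passing = scores.pass_matrix().to_numpy()
    p = scores.p.to_numpy()
    t = scores.t.to_numpy()
    cols = np.asarray(scores.p.columns, dtype=object)
    order = np.argsort(cols)  # lexicographic fallback
    calls = np.full(len(scores.p), UNASSIGNED, dtype=object)
    for i in range(len(calls)):
        cand = np.flatnonzero(passing[i])
        if len(cand) == 0:
            continue
        cand = sorted(cand, key=lambda j: (p[i, j], -t[i, j],
                                           int(np.where(order == j)[0][0])))
        calls[i] = cols[cand[0]]
    return pd.Series(calls, index=scores.p.index, name="called_type")


def cluster_profile(scores: CellTypeScores, clusters: np.ndarray) -> pd.DataFrame:
    """Proportion P[c, k] of cluster k's cells passing type c's threshold.

    A cell passing for several types contributes to each of their
    numerators, so rows may sum above 1.
    """
    passing = scores.pass_matrix()
    clusters = np.asarray(clusters)
    rows = []
    ids = np.unique(clusters)
    for k in ids:
        members = clusters == k
        if not members.any():
            raise ValueError(f"cluster {k} is empty")
        rows.append(passing.loc[members].mean(axis=0))
    return pd.DataFrame(rows, index=pd.Index(ids, name="cluster"))


@dataclass
class CellTypeAssignment:
    cluster_type: pd.Series     # cluster -> assigned type
    cell_type: pd.Series        # per-cell final type (via its cluster)
    merge_log: pd.DataFrame     # source cluster, target cluster, type, distance


def assign_clusters(
    profile: pd.DataFrame,
    scores: CellTypeScores,
    clusters: np.ndarray,
    embedding: np.ndarray,
    min_cluster_frac: float = 0.005,
) -> CellTypeAssignment:
    """Vote clusters into types and merge small/silent clusters.

    Each cluster gets ``argmax_c P[c, k]`` (ties broken by the larger sum
    of t over passing cells).  Clusters smaller than ``min_cluster_frac``
    of all cells, or with an all-zero profile, are merged into the type of
    the nearest assigned cluster by Euclidean centroid distance in the
    embedding.
    """
    clusters = np.asarray(clusters)
    n_total = len(clusters)
    t = scores.t
    passing = scores.pass_matrix()

    assigned: dict[int, str] = {}
    small: list[int] = []
    for k in profile.index:
        members = clusters == k
        size = int(members.sum())
        row = profile.loc[k]
        if size < min_cluster_frac * n_total or row.max() == 0:
            small.append(int(k))
            continue
        best = row[row == row.max()].index
        if len(best) > 1:
            t_sum = (t.loc[members, best] * passing.loc[members, best]).sum(axis=0)
            best = t_sum[t_sum == t_sum.max()].index
        assigned[int(k)] = sorted(best)[0]
    if not assigned:
        raise ValueError("no cluster passed the assignment rules")

    centroids = {
        int(k): embedding[clusters == k].mean(axis=0) for k in profile.index
    }
    log_rows = []
    for k in small:
        dists = {
            kk: float(np.linalg.norm(centroids[k] - centroids[kk]))
            for kk in assigned
        }
        target = min(dists, key=lambda kk: (dists[kk], kk))
        assigned[k] = assigned[target]
        log_rows.append({
            "source_cluster": k, "target_cluster": target,
            "target_type": assigned[target], "distance": dists[target],
        })

    cluster_type = pd.Series(assigned, name="cell_type").sort_index()
    cell_type = pd.Series(
        [assigned[int(c)] for c in clusters], name="final_type"
    )
    return CellTypeAssignment(
        cluster_type=cluster_type,
        cell_type=cell_type,
        merge_log=pd.DataFrame(
            log_rows,
            columns=["source_cluster", "target_cluster", "target_type", "distance"],
        ),
    )


class MarkerMapper:
    """Model-style front end: build from expression + panel, ``fit`` maps cells.

    Parameters
    ----------
    expr : DataFrame
        Cells x genes expression on the normalized (optionally
        batch-adjusted) scale.
    panel : DataFrame
        Binary genes x cell-types marker matrix.
    clusters : array-like
        Per-cell cluster ids.
    embedding : ndarray
        Cells x 2 coordinates used for small-cluster merging.
    """

    def __init__(self, expr: pd.DataFrame, panel: pd.DataFrame,
                 clusters, embedding: np.ndarray):
        self.expr = expr
        self.panel = validate_panel(panel)
        self.clusters = np.asarray(clusters)
        self.embedding = np.asarray(embedding)

    def fit(self, p0: float = 0.01,
            min_cluster_frac: float = 0.005) -> "MappingResults":
        scores = score_cells(self.expr, self.panel, p0=p0)
        calls = call_cells(scores)
        profile = cluster_profile(scores, self.clusters)
        assignment = assign_clusters(
            profile, scores, self.clusters, self.embedding,
            min_cluster_frac=min_cluster_frac,
        )
        return MappingResults(self, scores, calls, profile, assignment)


@dataclass
class MappingResults:
    model: MarkerMapper
    scores: CellTypeScores
    calls: pd.Series
    profile: pd.DataFrame
    assignment: CellTypeAssignment

    def cell_table(self) -> pd.DataFrame:
        """Per-cell barcode, cluster, direct call, final cluster-voted type."""
        return pd.DataFrame({
            "cluster": self.model.clusters,
            "called_type": self.calls.to_numpy(),
            "final_type": self.assignment.cell_type.to_numpy(),
        }, index=self.calls.index)

    def summary(self) -> pd.DataFrame:
        """Per-cluster size, winning type, and winning proportion."""
        sizes = pd.Series(self.model.clusters).value_counts().sort_index()
        out = pd.DataFrame({
            "n_cells": sizes,
            "assigned_type": self.assignment.cluster_type,
            "top_proportion": self.profile.max(axis=1),
        })
        out.index.name = "cluster"
        return out
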