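"""Quality control, library-size normalization, and batch adjustment.

QC rules follow the droplet-scRNA-seq conventions of the emulated study:
cells are discarded when more than 10 % of reads map to mitochondrial
genes, when fewer than 370 genes are expressed, or when total reads exceed
100,000 (a read-count doublet proxy); genes are kept when detected in at
least one cell.  All thresholds are evaluated on the raw count matrix, so
gene and cell filters commute.

Normalization is counts-per-10k followed by natural-log ``log1p``.  Batch
adjustment is parametric empirical-Bayes location/scale correction (the
ComBat algorithm): gene-wise standardization, per-batch location and scale
estimates shrunk toward parametric priors by iterative moment-matched
updates, then back-transformation.  A final per-gene recentring restores
the pre-adjustment grand mean exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["QCThresholds", "filter_genes", "filter_cells", "normalize",
           "combat", "eb_batch_adjust"]


@dataclass(frozen=True)
class QCThresholds:
    """Cell/gene retention thresholds (defaults are the study's rules)."""

    min_genes_per_cell: int = 370
    max_mito_fraction: float = 0.10
    max_reads_per_cell: int = 100_000
    min_cells_per_gene_with_umi: int = 1

    def __post_init__(self) -> None:
        if min(self.min_genes_per_cell, self.max_reads_per_cell,
               self.min_cells_per_gene_with_umi) <= 0:
            raise ValueError("QC thresholds must be positive")
        if not 0 < self.max_mito_fraction <= 1:
            raise ValueError("max_mito_fraction must be in (0, 1]")


def _counts(adata: ad.AnnData) -> sp.csr_matrix:
    counts = adata.layers.get("counts", adata.X)
    return sp.csr_matrix(counts)


def filter_genes(adata: ad.AnnData,
                 thr: QCThresholds = QCThresholds()) -> ad.AnnData:
    """Drop genes detected (count >= 1) in fewer than the threshold number
    of cells; survivor order is preserved."""
    counts = _counts(adata)
    detected = (counts > 0).sum(axis=0).A1
    keep = detected >= thr.min_cells_per_gene_with_umi
    if not keep.any():
        warnings.warn("gene filter removed every gene")
    return adata[:, keep].copy()


def filter_cells(
    adata: ad.AnnData,
    mito_gene_ids: list[str] | None = None,
    thr: QCThresholds = QCThresholds(),
) -> tuple[ad.AnnData, pd.DataFrame]:
    """Apply the three cell-level rules and report which rule fired per cell.

    A cell is removed iff its mitochondrial read fraction exceeds
    ``max_mito_fraction`` (strict), it expresses fewer than
    ``min_genes_per_cell`` genes (strict), or its total reads exceed
    ``max_reads_per_cell`` (strict).  ``mito_gene_ids`` defaults to
    ``var['is_mito']`` if present, else to the ``MT-`` prefix convention.

    Returns the filtered AnnData and a per-cell QC report with columns
    ``n_genes``, ``total_reads``, ``mito_fraction``, ``removed_by``.
    """
    counts = _counts(adata)
    if mito_gene_ids is None:
        if "is_mito" in adata.var:
            mito_mask = adata.var["is_mito"].to_numpy(bool)
        else:
            mito_mask = adata.var_names.str.upper().str.startswith("MT-")
    else:
        mito_mask = adata.var_names.isin(mito_gene_ids)
        n_found = int(mito_mask.sum())
        if n_found < len(set(mito_gene_ids)):
            warnings.warn(
                f"only {n_found}/{len(set(mito_gene_ids))} mito genes present "
                "in the matrix"
            )

    total = counts.sum(axis=1).A1
    n_genes = (counts > 0).sum(axis=1).A1
    mito = counts[:, np.flatnonzero(mito_mask)].sum(axis=1).A1 if mito_mask.any() \
        else np.zeros(counts.shape[0])
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito / np.maximum(total, 1), 1.0)

    rules = {
        "high_mito": mito_frac > thr.max_mito_fraction,
        "low_genes": n_genes < thr.min_genes_per_cell,
        "high_reads": total > thr.max_reads_per_cell,
    }
    removed_by = [
        ",".join(name for name, mask in rules.items() if mask[i])
        for i in range(counts.shape[0])
    ]
    report = pd.DataFrame(
        {
            "n_genes": n_genes,
            "total_reads": total.astype(np.int64),
            "mito_fraction": mito_frac,
            "removed_by": removed_by,
        },
        index=adata.obs_names.copy(),
    )
    keep = np.array([r == "" for r in removed_by])
    if not keep.any():
        raise ValueError("cell QC removed every cell")
    return adata[keep].copy(), report


def normalize(adata: ad.AnnData, scale: float = 10_000.0) -> ad.AnnData:
    """Counts-per-``scale`` normalization with natural-log ``log1p``.

    ``X`` becomes ``log(1 + count * scale / cell_total)``; raw counts stay
    in ``layers['counts']``.
    """
    adata = adata.copy()
    counts = _counts(adata)
    totals = counts.sum(axis=1).A1
    if (totals == 0).any():
        raise ValueError("cannot normalize cells with zero total counts")
    X = sp.csr_matrix(counts, dtype=np.float64)
    X = sp.diags(scale / totals) @ X
    X.data = np.log1p(X.data)
    adata.layers["counts"] = counts
    adata.X = X.astype(np.float32)
    adata.uns["normalized"] = True
    return adata


def combat(
    X: np.ndarray,
    batch: np.ndarray,
    covariates: pd.DataFrame | None = None,
    *,
    conv: float = 1e-4,
    max_iter: int = 500,
) -> tuple[np.ndarray, np.ndarray]:
    """Parametric empirical-Bayes batch adjustment of a genes x cells matrix.

    Standardizes each gene against a model with batch indicators (plus
    optional covariates), estimates per-batch location (gamma) and scale
    (delta) parameters, shrinks them toward a normal / inverse-gamma prior
    via the standard iterative moment-matched updates, back-transforms, and
    finally recenters each gene to its original grand mean.

    Returns ``(adjusted, passthrough_mask)`` where the mask flags
    zero-variance genes that were returned unchanged.
    """
    X = np.asarray(X, dtype=np.float64)
    G, n = X.shape
    batches, batch_idx = np.unique(np.asarray(batch), return_inverse=True)
    B = len(batches)
    counts = np.bincount(batch_idx, minlength=B)
    if B < 2:
        warnings.warn("single batch: ComBat is the identity transform")
        return X.copy(), np.zeros(G, dtype=bool)
    if counts.min() < 2:
        raise ValueError("every batch needs at least 2 cells")

    design = np.zeros((n, B))
    design[np.arange(n), batch_idx] = 1.0
    if covariates is not None and covariates.shape[1] > 0:
        cov = pd.get_dummies(covariates.astype("category"), drop_first=True)
        cov_mat = cov.to_numpy(dtype=np.float64)
        if np.linalg.matrix_rank(np.hstack([design, cov_mat])) < B + cov_mat.shape[1]:
            raise ValueError("covariates confounded with batch")
        design = np.hstack([design, cov_mat])

    var_tot = X.var(axis=1)
    passthrough = var_tot <= 1e-12
    active = ~passthrough
    out = X.copy()
    if not active.any():
        return out, passthrough
    Xa = X[active]

    beta = np.linalg.solve(design.T @ design, design.T @ Xa.T)  # (B+k) x G
    grand = (counts / n) @ beta[:B]                             # per-gene grand mean
    resid = Xa - (design @ beta).T
    var_pooled = (resid ** 2).mean(axis=1)
    var_pooled = np.maximum(var_pooled, 1e-12)
    stand_mean = grand[:, None] + (design[:, B:] @ beta[B:]).T
    Z = (Xa - stand_mean) / np.sqrt(var_pooled)[:, None]

    gamma_hat = np.stack([Z[:, batch_idx == b].mean(axis=1) for b in range(B)])
    delta_hat = np.stack([
        Z[:, batch_idx == b].var(axis=1, ddof=1) for b in range(B)
    ])
    gamma_bar = gamma_hat.mean(axis=1)
    t2 = gamma_hat.var(axis=1, ddof=1)

    def _aprior(d):
        m, s2 = d.mean(), d.var(ddof=1)
        return (2 * s2 + m ** 2) / s2

    def _bprior(d):
        m, s2 = d.mean(), d.var(ddof=1)
        return (m * s2 + m ** 3) / s2

    Z_adj = np.empty_like(Z)
    for b in range(B):
        cols = batch_idx == b
        nb = counts[b]
        a_pr, b_pr = _aprior(delta_hat[b]), _bprior(delta_hat[b])
        g_old, d_old = gamma_hat[b].copy(), delta_hat[b].copy()
        Zb = Z[:, cols]
        for _ in range(max_iter):
            g_new = (nb * t2[b] * gamma_hat[b] + d_old * gamma_bar[b]) / (
                nb * t2[b] + d_old
            )
            ss = ((Zb - g_new[:, None]) ** 2).sum(axis=1)
            d_new = (b_pr + 0.5 * ss) / (nb / 2 + a_pr - 1)
            change = max(
                np.abs(g_new - g_old).max() / max(np.abs(g_old).max(), 1e-12),
                np.abs(d_new - d_old).max() / max(np.abs(d_old).max(), 1e-12),
            )
            g_old, d_old = g_new, d_new
            if change < conv:
                break
        Z_adj[:, cols] = (Zb - g_old[:, None]) / np.sqrt(d_old)[:, None]

    adjusted = Z_adj * np.sqrt(var_pooled)[:, None] + stand_mean
    # restore the per-gene grand mean exactly
    adjusted += (Xa.mean(axis=1) - adjusted.mean(axis=1))[:, None]
    out[active] = adjusted
    return out, passthrough


def eb_batch_adjust(
    adata: ad.AnnData,
    batch_key: str = "participant",
    covariate_keys: tuple[str, ...] = ("condition",),
) -> ad.AnnData:
    """ComBat adjustment of normalized expression across ``batch_key``.

    The condition of interest is included as a model covariate by default
    so the adjustment does not absorb the signal the downstream stages
    test; pass ``covariate_keys=()`` to disable.
    """
    if not adata.uns.get("normalized", False):
        warnings.warn("eb_batch_adjust called on data not flagged as normalized")
    adata = adata.copy()
    X = np.asarray(sp.csr_matrix(adata.X).todense(), dtype=np.float64).T  # genes x cells
    cov = adata.obs[list(covariate_keys)] if covariate_keys else None
    adjusted, passthrough = combat(X, adata.obs[batch_key].to_numpy(), cov)
    adata.X = adjusted.T.astype(np.float32)
    adata.var["combat_passthrough"] = passthrough
    adata.uns["batch_adjusted"] = True
    return adata
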