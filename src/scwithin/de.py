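"""Per-gene differential expression with a participant random intercept.

Within each cell type, each gene's normalized expression is modeled as

    expr ~ intercept + condition  +  (1 | participant)

fitted by REML; the condition coefficient (post minus pre, log scale) is
tested with a Wald test.  With very few participants the random-intercept
variance is weakly identified, so a fit that fails to converge or whose
variance component collapses to zero falls back to OLS with participant as
a fixed covariate; the fallback is recorded per gene.  Benjamini-Hochberg
adjustment is applied within each cell type across its tested genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

__all__ = ["fit_gene", "de_table", "classify_sharing", "MixedDiffExpr",
           "DEResults", "bh_adjust"]

_COLUMNS = ["cell_type", "gene", "effect", "se", "p", "q", "direction",
            "n_cells", "fit_method"]


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    return multipletests(np.asarray(p, dtype=float), method="fdr_bh")[1]


def fit_gene(
    expr: np.ndarray,
    condition: np.ndarray,
    participant: np.ndarray,
) -> tuple[float, float, float, str]:
    """Condition effect for one gene: ``(effect, se, p, fit_method)``.

    ``condition`` holds ``pre``/``post`` labels; the effect is post minus
    pre on the scale of ``expr``.  ``fit_method`` is ``mixed`` for the REML
    random-intercept fit, ``ols_fixed_participant`` for the fallback, or
    ``degenerate`` when the response is constant.
    """
    expr = np.asarray(expr, dtype=np.float64)
    condition = np.asarray(condition)
    participant = np.asarray(participant)
    conds = set(condition)
    if not {"pre", "post"} <= conds:
        raise ValueError(f"need both conditions, got {sorted(conds)}")
    if len(set(participant)) < 2:
        raise ValueError("need >= 2 participants for a random intercept")
    if np.ptp(expr) == 0:
        return 0.0, 0.0, 1.0, "degenerate"

    cond = (condition == "post").astype(np.float64)
    exog = np.column_stack([np.ones_like(cond), cond])

    result = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = sm.MixedLM(expr, exog, groups=participant)
            fit = model.fit(reml=True, method="lbfgs")
            re_var = float(np.asarray(fit.cov_re)[0, 0])
            if fit.converged and np.isfinite(fit.bse[1]) and re_var > 1e-8:
                result = (float(fit.params[1]), float(fit.bse[1]),
                          float(fit.pvalues[1]), "mixed")
        except (np.linalg.LinAlgError, ValueError):
            result = None
    if result is None:
        dummies = pd.get_dummies(pd.Series(participant), drop_first=True)
        exog_f = np.column_stack([exog, dummies.to_numpy(dtype=np.float64)])
        fit = sm.OLS(expr, exog_f).fit()
        result = (float(fit.params[1]), float(fit.bse[1]),
                  float(fit.pvalues[1]), "ols_fixed_participant")
    effect, se, p, method = result
    if not np.isfinite(p):
        effect, se, p, method = 0.0, 0.0, 1.0, "degenerate"
    return effect, se, p, method


def de_table(
    X,
    genes: pd.Index,
    cell_types: np.ndarray,
    condition: np.ndarray,
    participant: np.ndarray,
    *,
    min_cells: int = 50,
    min_frac: float = 0.01,
) -> "DEResults":
    """Per-cell-type DE tables with BH adjustment within each type.

    ``X`` is cells x genes normalized expression.  Types with fewer than
    ``min_cells`` cells, or missing a condition, are reported untested.
    Within a tested type, only genes detected (nonzero) in at least
    ``min_frac`` of its cells are fitted; skipped genes are logged in the
    per-type status.
    """
    Xd = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)
    cell_types = np.asarray(cell_types)
    condition = np.asarray(condition)
    participant = np.asarray(participant)

    rows: list[dict] = []
    status: dict[str, str] = {}
    n_skipped: dict[str, int] = {}
    for ct in sorted(set(cell_types)):
        members = cell_types == ct
        n = int(members.sum())
        if n < min_cells:
            status[ct] = "excluded:low_n"
            continue
        conds = set(condition[members])
        if not {"pre", "post"} <= conds:
            status[ct] = "excluded:missing_condition"
            continue
        Xi = Xd[members]
        detected = (Xi > 0).mean(axis=0) >= min_frac
        n_skipped[ct] = int((~detected).sum())
        tested = np.flatnonzero(detected)
        if len(tested) == 0:
            status[ct] = "excluded:no_detected_genes"
            continue
        status[ct] = "tested"
        cond_i, part_i = condition[members], participant[members]
        for j in tested:
            effect, se, p, method = fit_gene(Xi[:, j], cond_i, part_i)
            rows.append({
                "cell_type": ct, "gene": genes[j], "effect": effect,
                "se": se, "p": p, "direction": "up" if effect > 0 else "down",
                "n_cells": n, "fit_method": method,
            })

    table = pd.DataFrame(rows)
    if len(table):
        table["q"] = np.nan
        for ct in table["cell_type"].unique():
            mask = table["cell_type"] == ct
            table.loc[mask, "q"] = bh_adjust(table.loc[mask, "p"].to_numpy())
        table = table[_COLUMNS].sort_values(
            ["cell_type", "q", "p"]).reset_index(drop=True)
    else:
        table = pd.DataFrame(columns=_COLUMNS)
    return DEResults(table=table, type_status=status, n_genes_skipped=n_skipped)


def classify_sharing(table: pd.DataFrame, q_threshold: float = 0.05) -> pd.DataFrame:
    """Classify significant genes as cell-type-specific or shared.

    A gene significant (q < threshold) in exactly one tested type is
    ``specific``; in two or more, ``shared``.  ``core`` flags genes
    significant in at least three types, and ``concordant`` says whether
    all significant effects share a sign.
    """
    sig = table[table["q"] < q_threshold]
    rows = []
    for gene, grp in sig.groupby("gene"):
        n = len(grp)
        signs = set(np.sign(grp["effect"]))
        rows.append({
            "gene": gene,
            "cell_types": ",".join(sorted(grp["cell_type"])),
            "n_types": n,
            "class": "specific" if n == 1 else "shared",
            "core": n >= 3,
            "concordant": len(signs - {0.0}) <= 1,
        })
    out = pd.DataFrame(
        rows, columns=["gene", "cell_types", "n_types", "class", "core",
                       "concordant"],
    )
    return out.sort_values(["n_types", "gene"],
                           ascending=[False, True]).reset_index(drop=True)


class MixedDiffExpr:
    """Model-style front end for the per-gene mixed-model DE analysis.

    Built from a cells x genes expression matrix and per-cell labels;
    ``fit`` runs every (cell type, gene) regression and returns a
    :class:`DEResults`.
    """

    def __init__(self, X, genes: pd.Index, cell_types, condition, participant,
                 *, min_cells: int = 50, min_frac: float = 0.01):
        self.X = X
        self.genes = pd.Index(genes)
        self.cell_types = np.asarray(cell_types)
        self.condition = np.asarray(condition)
        self.participant = np.asarray(participant)
        self.min_cells = min_cells
        self.min_frac = min_frac

    @classmethod
    def from_anndata(cls, adata, cell_types, **kwargs) -> "MixedDiffExpr":
        return cls(adata.X, adata.var_names, cell_types,
                   adata.obs["condition"].to_numpy(),
                   adata.obs["participant"].to_numpy(), **kwargs)

    def fit(self) -> "DEResults":
        return de_table(
            self.X, self.genes, self.cell_types, self.condition,
            self.participant, min_cells=self.min_cells, min_frac=self.min_frac,
        )


@dataclass
class DEResults:
    """Per-(cell type, gene) effects with BH q-values and fit provenance."""

    table: pd.DataFrame
    type_status: dict[str, str] = field(default_factory=dict)
    n_genes_skipped: dict[str, int] = field(default_factory=dict)

    def significant(self, q_threshold: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["q"] < q_threshold]

    def sharing(self, q_threshold: float = 0.05) -> pd.DataFrame:
        return classify_sharing(self.table, q_threshold)

    def summary(self, q_threshold: float = 0.05) -> pd.DataFrame:
        """Per cell type: status, genes tested, and significant up/down counts."""
        rows = []
        for ct, st in sorted(self.type_status.items()):
            sub = self.table[self.table["cell_type"] == ct]
            sig = sub[sub["q"] < q_threshold]
            rows.append({
                "cell_type": ct, "status": st, "n_genes_tested": len(sub),
                "n_significant": len(sig),
                "n_up": int((sig["direction"] == "up").sum()),
                "n_down": int((sig["direction"] == "down").sum()),
            })
        return pd.DataFrame(rows)
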