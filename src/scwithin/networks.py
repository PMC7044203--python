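"""Knowledge-constrained co-expression networks, overlap and enrichment tests.

Candidate genes (nominal p below a cutoff in the differential-expression
stage) are connected only along edges present in a prior gene-gene edge
list (e.g. derived from KEGG pathways).  Each admissible edge is tested by
OLS of one gene on the other across the cells of one cell type and one
condition; edges surviving BH-FDR within the (cell type, condition)
stratum form the condition's network, and a hub is a node with at least
``min_degree`` edges in at least one condition (degrees are never summed
across conditions).  The same hypergeometric engine serves the list-overlap
statistic (expected overlap, representation factor, exact upper tail) and
gene-set enrichment over GMT collections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "select_candidates", "test_edges", "find_hubs", "receptor_coexpression",
    "overlap_test", "gene_set_enrichment", "OverlapResult",
]

_EDGE_COLUMNS = ["gene_a", "gene_b", "slope", "t", "p", "q", "status"]


def select_candidates(de_table: pd.DataFrame, p_nom: float = 0.001) -> list[str]:
    """Genes with unadjusted p strictly below ``p_nom``, ordered by p."""
    sel = de_table[de_table["p"] < p_nom].sort_values("p")
    return sel["gene"].tolist()


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)


def test_edges(
    candidates: list[str],
    edge_list: list[tuple[str, str]],
    X,
    genes: pd.Index,
    *,
    fdr: float = 0.05,
    min_cells: int = 10,
) -> pd.DataFrame:
    """Test prior edges between candidate genes across one cell stratum.

    ``X`` is cells x genes expression restricted to the stratum (one cell
    type, one condition).  Each admissible edge (both endpoints candidates
    and present in the matrix) is fitted by OLS of ``gene_b`` on
    ``gene_a``; the slope's two-sided p is BH-adjusted across tested edges
    and edges with q < ``fdr`` get status ``significant``.  Edges touching
    a zero-variance gene are reported ``untestable``.
    """
    Xd = _dense(X)
    if Xd.shape[0] < min_cells:
        raise ValueError(
            f"stratum has {Xd.shape[0]} cells, fewer than min_cells={min_cells}"
        )
    pos = {g: i for i, g in enumerate(genes)}
    cand = [g for g in candidates if g in pos]
    cand_set = set(cand)
    n = Xd.shape[0]

    rows = []
    for a, b in edge_list:
        if a not in cand_set or b not in cand_set or a == b:
            continue
        x, y = Xd[:, pos[a]], Xd[:, pos[b]]
        sxx = ((x - x.mean()) ** 2).sum()
        syy = ((y - y.mean()) ** 2).sum()
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append({"gene_a": a, "gene_b": b, "slope": np.nan,
                         "t": np.nan, "p": np.nan, "status": "untestable"})
            continue
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        slope = sxy / sxx
        rss = max(syy - slope * sxy, 0.0)
        if rss <= 1e-300:
            t, p = np.inf, 0.0
        else:
            se = np.sqrt(rss / (n - 2) / sxx)
            t = slope / se
            p = 2 * scipy.stats.t.sf(abs(t), df=n - 2)
        rows.append({"gene_a": a, "gene_b": b, "slope": slope,
                     "t": t, "p": p, "status": "tested"})

    table = pd.DataFrame(rows, columns=[c for c in _EDGE_COLUMNS if c != "q"])
    table["q"] = np.nan
    tested = table["status"] == "tested"
    if tested.any():
        table.loc[tested, "q"] = multipletests(
            table.loc[tested, "p"].to_numpy(), method="fdr_bh")[1]
        table.loc[tested & (table["q"] < fdr), "status"] = "significant"
    return table[_EDGE_COLUMNS].reset_index(drop=True)


def degrees(edge_table: pd.DataFrame) -> pd.Series:
    """Node degrees over the significant edges of one condition's table."""
    sig = edge_table[edge_table["status"] == "significant"]
    return pd.concat([sig["gene_a"], sig["gene_b"]]).value_counts()


def find_hubs(
    pre: pd.DataFrame,
    post: pd.DataFrame,
    min_degree: int = 4,
) -> list[str]:
    """Genes with degree >= ``min_degree`` in the pre- or the post-condition
    network (each condition judged on its own; degrees are not summed)."""
    deg_pre, deg_post = degrees(pre), degrees(post)
    hubs = set(deg_pre[deg_pre >= min_degree].index)
    hubs |= set(deg_post[deg_post >= min_degree].index)
    return sorted(hubs)


def receptor_coexpression(
    X,
    genes: pd.Index,
    receptor: str,
    *,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Genes significantly correlated with a receptor in one cell stratum.

    Pearson correlation of the receptor with every other expressed gene,
    two-sided p from the t-transform, BH across genes.  Returns a table
    (gene, r, p, q, significant); empty with a reason attribute if the
    receptor has no variance in the stratum.
    """
    Xd = _dense(X)
    genes = pd.Index(genes)
    if receptor not in genes:
        raise ValueError(f"receptor {receptor!r} absent from matrix")
    r_idx = genes.get_loc(receptor)
    x = Xd[:, r_idx].astype(np.float64)
    n = len(x)
    out_cols = ["gene", "r", "p", "q", "significant"]
    if np.ptp(x) == 0:
        empty = pd.DataFrame(columns=out_cols)
        empty.attrs["reason"] = "receptor has zero variance in stratum"
        return empty

    others = np.array([j for j in range(Xd.shape[1])
                       if j != r_idx and np.ptp(Xd[:, j]) > 0])
    Y = Xd[:, others].astype(np.float64)
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=0)
    r = (Yc.T @ xc) / np.sqrt((Yc ** 2).sum(axis=0) * (xc ** 2).sum())
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1 - r ** 2))
    p = np.where(np.abs(r) >= 1.0, 0.0,
                 2 * scipy.stats.t.sf(np.abs(t), df=n - 2))
    q = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame({
        "gene": genes[others], "r": r, "p": p, "q": q,
        "significant": q < fdr,
    }).sort_values("p").reset_index(drop=True)
    return table


@dataclass(frozen=True)
class OverlapResult:
    """Exact hypergeometric overlap statistic for two gene lists."""

    n_a: int
    n_b: int
    universe: int
    overlap: int
    expected: float
    representation_factor: float
    p: float


def overlap_test(
    list_a: list[str] | set[str],
    list_b: list[str] | set[str],
    universe_size: int,
) -> OverlapResult:
    """Significance of the overlap of two gene lists drawn from a universe.

    Expected overlap is |A||B|/N, the representation factor is
    observed/expected, and p is the exact hypergeometric upper tail
    P[X >= k] with X ~ Hypergeom(N, |A|, |B|).
    """
    a, b = set(list_a), set(list_b)
    if universe_size < len(a | b):
        raise ValueError(
            f"universe ({universe_size}) smaller than the union ({len(a | b)})"
        )
    k = len(a & b)
    expected = len(a) * len(b) / universe_size if universe_size else 0.0
    rf = k / expected if expected > 0 else 0.0
    p = float(scipy.stats.hypergeom.sf(k - 1, universe_size, len(a), len(b)))
    return OverlapResult(
        n_a=len(a), n_b=len(b), universe=universe_size, overlap=k,
        expected=expected, representation_factor=rf, p=min(p, 1.0),
    )


def gene_set_enrichment(
    candidates: list[str] | set[str],
    gene_sets: dict[str, set[str]],
    universe: list[str] | set[str],
    *,
    min_set_size: int = 5,
) -> pd.DataFrame:
    """Hypergeometric enrichment of a candidate list over GMT gene sets.

    Sets are intersected with the universe; sets smaller than
    ``min_set_size`` within it are skipped.  Per set, p is the upper-tail
    probability of observing at least the seen number of candidate hits;
    BH is applied across tested sets.
    """
    universe = set(universe)
    cand = set(candidates) & universe
    N, n_draw = len(universe), len(cand)
    rows = []
    for name, members in gene_sets.items():
        in_universe = members & universe
        if len(in_universe) < min_set_size:
            continue
        k = len(in_universe & cand)
        if n_draw == 0:
            p = 1.0
        else:
            p = float(scipy.stats.hypergeom.sf(k - 1, N, len(in_universe), n_draw))
        rows.append({"gene_set": name, "set_size": len(in_universe),
                     "hits": k, "p": min(p, 1.0)})
    table = pd.DataFrame(rows, columns=["gene_set", "set_size", "hits", "p"])
    if len(table):
        table["q"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
        table = table.sort_values(["p", "gene_set"]).reset_index(drop=True)
    else:
        table["q"] = pd.Series(dtype=float)
    return table
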