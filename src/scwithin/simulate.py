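"""Synthetic single-cell UMI count data with planted ground truth.

The generator emulates a within-subject acute-drug design on PBMCs: each of
``n_participants`` contributes a pre- and a post-infusion sample, cells fall
into eight immune cell types with literature marker genes, and counts are
drawn from a Negative Binomial (Gamma-Poisson) model

    mu[g, cell] = lib_size_share * base_mean[g]
                  * marker_fold ** [g is a marker of the cell's type]
                  * 2 ** participant_shift[g, participant]
                  * 2 ** (condition_lfc[g, type] * [condition == post])

Per-participant per-gene shifts are drawn once per participant with a
standard deviation that by default exceeds the planted condition effects, so
unadjusted data clusters by participant rather than by condition — the
batch structure the adjustment stage must remove.  Cells destined to fail
quality control can be planted explicitly: high-mitochondrial cells (>10 %
of reads on mitochondrial genes) and doublets (summed two-type profiles
with inflated library size beyond the read-count cap).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["CellTypeSpec", "SyntheticConfig", "GroundTruth", "generate_counts",
           "default_cell_types", "default_mito_genes", "demo_config"]

#: mitochondrially encoded genes used as the default mito panel
_MITO_GENES = [
    "MT-ND1", "MT-ND2", "MT-CO1", "MT-CO2", "MT-ATP8", "MT-ATP6", "MT-CO3",
    "MT-ND3", "MT-ND4L", "MT-ND4", "MT-ND5", "MT-ND6", "MT-CYB",
]

#: PBMC cell types with proportions close to the usual composition of a
#: 10X PBMC run and disjoint literature marker genes.
_PBMC_TYPES: list[tuple[str, float, tuple[str, ...]]] = [
    ("CD4_T", 0.346, ("CD3D", "CD3E", "CD3G", "CD2", "TRAC", "LTB")),
    ("IL7R_CD4_T", 0.084, ("IL7R", "CCR7", "LEF1", "TCF7", "MAL", "LDHB")),
    ("CD8_T", 0.174, ("CD8A", "CD8B", "GZMK", "CD160", "KLRG1", "LAG3")),
    ("B", 0.132, ("MS4A1", "CD79A", "CD79B", "CD19", "IGHM", "HLA-DOB")),
    ("NK", 0.123, ("GNLY", "NKG7", "KLRD1", "KLRF1", "NCR1", "PRF1")),
    ("CD14_Mono", 0.100, ("CD14", "LYZ", "S100A8", "S100A9", "FCN1", "VCAN")),
    ("FCGR3A_Mono", 0.038, ("FCGR3A", "MS4A7", "CDKN1C", "LST1", "AIF1", "IFITM3")),
    ("DC", 0.003, ("FCER1A", "CST3", "CLEC10A", "ITGAX", "IRF8", "LILRA4")),
]


@dataclass(frozen=True)
class CellTypeSpec:
    name: str
    proportion: float
    markers: tuple[str, ...]


def default_cell_types() -> list[CellTypeSpec]:
    return [CellTypeSpec(n, p, m) for n, p, m in _PBMC_TYPES]


def default_mito_genes() -> list[str]:
    return list(_MITO_GENES)


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic design.

    Defaults mirror the emulated study: 2 participants sampled pre and post
    infusion, ~4,000 cells per sample, a 20,000-gene transcriptome, eight
    PBMC types, and per-participant expression shifts (SD 0.5 log2) larger
    than typical planted condition effects.
    """

    n_participants: int = 2
    n_cells_per_sample: int = 4000
    n_genes: int = 20000
    cell_types: list[CellTypeSpec] = field(default_factory=default_cell_types)
    lib_size_log_mean: float = float(np.log(2500.0))  # log of expected UMIs/cell
    lib_size_log_sd: float = 0.35
    nb_dispersion: float = 0.5          # alpha in var = mu + alpha * mu^2
    marker_fold: float = 4.0            # expression multiplier in own type
    # real cell types differ in broad expression programs beyond the curated
    # markers; each type additionally up-regulates this many non-marker genes
    # by program_fold (the mapping stage never sees which)
    program_genes_per_type: int = 50
    program_fold: float = 3.0
    participant_effect_sd: float = 0.5  # SD of per-participant log2 shifts
    # (gene, log2 fold-change, affected types) with types a tuple of names
    # or the string "all"
    condition_effects: list[tuple[str, float, object]] = field(default_factory=list)
    mito_gene_ids: list[str] = field(default_factory=default_mito_genes)
    mito_base_frac: float = 0.02        # expected mito share in normal cells
    planted_high_mito_cells: int = 0
    planted_high_mito_frac: float = 0.30   # mito share given to planted cells
    planted_doublet_cells: int = 0
    doublet_total_reads: int = 110000   # above the doublet read cap
    allow_marker_overlap: bool = False
    seed: int = 0

    def validate(self) -> None:
        props = [ct.proportion for ct in self.cell_types]
        if abs(sum(props) - 1.0) > 1e-9:
            raise ValueError(f"cell type proportions sum to {sum(props)}, not 1")
        all_markers = [g for ct in self.cell_types for g in ct.markers]
        if not self.allow_marker_overlap and len(all_markers) != len(set(all_markers)):
            raise ValueError("marker gene sets overlap between cell types")
        n_named = len(set(all_markers) | set(self.mito_gene_ids)) + len(
            {g for g, _, _ in self.condition_effects}
            - set(all_markers) - set(self.mito_gene_ids)
        )
        if self.n_genes < n_named:
            raise ValueError(
                f"n_genes={self.n_genes} smaller than the {n_named} named "
                "marker/mito/effect genes"
            )
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.marker_fold <= 1:
            raise ValueError("marker_fold must be > 1")
        n_cells = self.n_participants * 2 * self.n_cells_per_sample
        n_planted = self.planted_high_mito_cells + self.planted_doublet_cells
        if n_planted > n_cells // 2:
            raise ValueError("too many planted QC-failure cells")


@dataclass
class GroundTruth:
    """Planted truth accompanying a synthetic dataset."""

    cells: pd.DataFrame        # index barcode: true_type, participant, condition,
    #                            sample, is_doublet, is_high_mito
    lfc: pd.DataFrame          # genes x cell types, true condition log2 FC
    markers: dict[str, list[str]]   # cell type -> marker genes
    programs: dict[str, list[str]] = field(default_factory=dict)  # type -> program genes

    def marker_panel(self) -> pd.DataFrame:
        """Binary genes x cell-types marker matrix for the mapping stage."""
        genes = [g for gs in self.markers.values() for g in gs]
        panel = pd.DataFrame(
            0, index=pd.Index(sorted(set(genes)), name="gene"),
            columns=list(self.markers), dtype=np.int8,
        )
        for ct, gs in self.markers.items():
            panel.loc[[g for g in gs if g in panel.index], ct] = 1
        return panel


def _gene_universe(config: SyntheticConfig) -> pd.Index:
    named: list[str] = []
    for ct in config.cell_types:
        for g in ct.markers:
            if g not in named:
                named.append(g)
    for g in config.mito_gene_ids:
        if g not in named:
            named.append(g)
    for g, _, _ in config.condition_effects:
        if g not in named:
            named.append(g)
    fillers = [f"GENE{i:05d}" for i in range(config.n_genes - len(named))]
    return pd.Index(named + fillers, name="gene")


def _pick_programs(config: SyntheticConfig, genes: pd.Index,
                   rng: np.random.Generator) -> dict[str, list[str]]:
    """Disjoint per-type sets of non-marker 'program' genes drawn from the
    unnamed part of the gene universe."""
    if config.program_genes_per_type == 0:
        return {}
    fillers = [g for g in genes if g.startswith("GENE")]
    need = config.program_genes_per_type * len(config.cell_types)
    if need > len(fillers):
        raise ValueError(
            f"program_genes_per_type={config.program_genes_per_type} needs "
            f"{need} unnamed genes but only {len(fillers)} exist"
        )
    chosen = rng.choice(fillers, size=need, replace=False)
    return {
        ct.name: sorted(chosen[i * config.program_genes_per_type:
                               (i + 1) * config.program_genes_per_type])
        for i, ct in enumerate(config.cell_types)
    }


def _base_weights(config: SyntheticConfig, genes: pd.Index,
                  programs: dict[str, list[str]],
                  rng: np.random.Generator) -> np.ndarray:
    """Relative expression weights; markers, program and planted-effect genes
    sit in the well-expressed range so their signal is detectable, mito genes
    carry a fixed small share of the library."""
    w = rng.lognormal(mean=0.0, sigma=1.5, size=len(genes))
    hi = float(np.quantile(w, 0.85))
    mid = float(np.quantile(w, 0.70))
    marker_set = {g for ct in config.cell_types for g in ct.markers}
    effect_set = {g for g, _, _ in config.condition_effects}
    program_set = {g for gs in programs.values() for g in gs}
    for i, g in enumerate(genes):
        if g in marker_set or g in effect_set:
            w[i] = hi
        elif g in program_set:
            w[i] = mid
    mito_mask = genes.isin(config.mito_gene_ids)
    if mito_mask.any():
        w[mito_mask] = 0.0
        non_mito_total = w.sum()
        mito_total = config.mito_base_frac / (1 - config.mito_base_frac) * non_mito_total
        w[mito_mask] = mito_total / mito_mask.sum()
    return w / w.sum()


def _nb_sample(mu: np.ndarray, alpha: float, rng: np.random.Generator) -> np.ndarray:
    """Gamma-Poisson draw with var = mu + alpha * mu^2."""
    shape = 1.0 / alpha
    lam = rng.gamma(shape=shape, scale=np.maximum(mu, 1e-12) / shape)
    return rng.poisson(lam)


def generate_counts(config: SyntheticConfig) -> tuple[ad.AnnData, GroundTruth]:
    """Draw a synthetic count matrix plus its ground truth.

    Returns an AnnData (cells x genes, CSR integer counts in ``X`` and
    ``layers['counts']``) with sample/participant/condition in ``obs`` and
    a :class:`GroundTruth` holding true types, planted fold-changes and
    marker membership.  Fixing ``config.seed`` makes the output
    reproducible; all randomness flows from a single generator.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = _gene_universe(config)
    programs = _pick_programs(config, genes, rng)
    weights = _base_weights(config, genes, programs, rng)
    type_names = [ct.name for ct in config.cell_types]
    props = np.array([ct.proportion for ct in config.cell_types])

    # per-type fold multipliers (genes x types): markers and program genes
    # of the cell's own type
    fold = np.ones((len(genes), len(type_names)))
    gene_pos = {g: i for i, g in enumerate(genes)}
    for j, ct in enumerate(config.cell_types):
        for g in ct.markers:
            fold[gene_pos[g], j] = config.marker_fold
        for g in programs.get(ct.name, []):
            fold[gene_pos[g], j] = config.program_fold

    # planted condition log2 fold-changes (genes x types)
    lfc = np.zeros((len(genes), len(type_names)))
    for g, effect, types in config.condition_effects:
        cols = range(len(type_names)) if types == "all" else [
            type_names.index(t) for t in types
        ]
        for j in cols:
            lfc[gene_pos[g], j] = effect

    participants = [f"S{i + 1}" for i in range(config.n_participants)]
    shifts = {
        p: rng.normal(0.0, config.participant_effect_sd, size=len(genes))
        for p in participants
    }

    blocks: list[sp.csr_matrix] = []
    obs_rows: list[dict] = []
    type_codes_all: list[np.ndarray] = []
    for p in participants:
        for cond in ("pre", "post"):
            n = config.n_cells_per_sample
            codes = rng.choice(len(type_names), size=n, p=props)
            lib = rng.lognormal(config.lib_size_log_mean, config.lib_size_log_sd, n)
            # mean matrix for this sample, cells x genes
            log2_mu = (
                np.log2(np.maximum(weights, 1e-300))[None, :]
                + np.log2(fold.T)[codes, :]
                + shifts[p][None, :]
            )
            if cond == "post":
                log2_mu = log2_mu + lfc.T[codes, :]
            mu = np.exp2(log2_mu)
            mu *= (lib / mu.sum(axis=1))[:, None]
            counts = _nb_sample(mu, config.nb_dispersion, rng)
            blocks.append(sp.csr_matrix(counts))
            sample = f"{cond}-{p}"
            for i in range(n):
                obs_rows.append({
                    "barcode": f"{sample}-{i:05d}", "sample": sample,
                    "participant": p, "condition": cond,
                })
            type_codes_all.append(codes)

    X = sp.vstack(blocks).tocsr()
    obs = pd.DataFrame(obs_rows).set_index("barcode")
    codes = np.concatenate(type_codes_all)
    true_type = np.array(type_names, dtype=object)[codes]
    n_cells = X.shape[0]

    is_high_mito = np.zeros(n_cells, dtype=bool)
    is_doublet = np.zeros(n_cells, dtype=bool)
    n_plant = config.planted_high_mito_cells + config.planted_doublet_cells
    if n_plant:
        planted = rng.choice(n_cells, size=n_plant, replace=False)
        hm_idx = planted[: config.planted_high_mito_cells]
        db_idx = planted[config.planted_high_mito_cells:]
        is_high_mito[hm_idx] = True
        is_doublet[db_idx] = True
        X = X.tolil()
        mito_cols = np.flatnonzero(genes.isin(config.mito_gene_ids))
        if len(mito_cols) == 0 and config.planted_high_mito_cells:
            raise ValueError("cannot plant high-mito cells without mito genes")
        f = config.planted_high_mito_frac
        for i in hm_idx:
            row = np.asarray(X[i, :].todense()).ravel()
            non_mito = row.sum() - row[mito_cols].sum()
            target = int(np.ceil(f / (1 - f) * non_mito)) + 1
            new_mito = rng.multinomial(target, np.full(len(mito_cols),
                                                       1 / len(mito_cols)))
            row[mito_cols] = new_mito
            X[i, :] = row
        # doublets: summed profiles of two unplanted cells of different types,
        # inflated so total reads exceed the read-count doublet cap
        clean = np.setdiff1d(np.arange(n_cells), planted)
        for i in db_idx:
            a = rng.choice(clean)
            others = clean[true_type[clean] != true_type[a]]
            b = rng.choice(others)
            prof = np.asarray((X[a, :] + X[b, :]).todense()).ravel()
            factor = int(np.ceil(config.doublet_total_reads / max(prof.sum(), 1)))
            X[i, :] = prof * max(factor, 1)
            true_type[i] = f"doublet:{true_type[a]}+{true_type[b]}"
        X = X.tocsr()

    adata = ad.AnnData(
        X=X.astype(np.float32),
        obs=obs,
        var=pd.DataFrame(index=genes),
    )
    adata.layers["counts"] = adata.X.copy()
    adata.var["is_mito"] = adata.var_names.isin(config.mito_gene_ids)
    adata.uns["synthetic_seed"] = config.seed

    cells = obs.copy()
    cells["true_type"] = true_type
    cells["is_doublet"] = is_doublet
    cells["is_high_mito"] = is_high_mito
    truth = GroundTruth(
        cells=cells,
        lfc=pd.DataFrame(lfc, index=genes, columns=type_names),
        markers={ct.name: list(ct.markers) for ct in config.cell_types},
        programs=programs,
    )
    return adata, truth


def demo_config(seed: int = 0, *, n_cells_per_sample: int = 600,
                n_genes: int = 1500, n_shared: int = 10,
                n_specific_per_type: int = 3,
                shared_lfc: float = 0.8, specific_lfc: float = 1.0) -> SyntheticConfig:
    """A desk-scale demonstration design with planted truth.

    Plants ``n_shared`` genes whose condition effect (alternating sign,
    |log2 FC| = ``shared_lfc``) is common to every cell type, plus
    ``n_specific_per_type`` genes per major cell type affected in that type
    only — the shared/cell-type-specific split the sharing report should
    recover.
    """
    types = default_cell_types()
    effects: list[tuple[str, float, object]] = []
    for i in range(n_shared):
        sign = 1.0 if i % 2 == 0 else -1.0
        effects.append((f"DEG-SHARED-{i:02d}", sign * shared_lfc, "all"))
    major = [ct.name for ct in types if ct.proportion >= 0.05]
    for t in major:
        for i in range(n_specific_per_type):
            sign = 1.0 if i % 2 == 0 else -1.0
            effects.append((f"DEG-{t}-{i:02d}", sign * specific_lfc, (t,)))
    return SyntheticConfig(
        n_cells_per_sample=n_cells_per_sample,
        n_genes=n_genes,
        condition_effects=effects,
        seed=seed,
    )
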