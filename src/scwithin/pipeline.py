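"""End-to-end orchestration of the analysis stages.

Stages run in a fixed order — ingest/simulate, QC + normalization + batch
adjustment, embedding + clustering, marker-based cell typing, mixed-model
differential expression, networks + enrichment — and communicate only
through declared on-disk artifacts inside the output directory, so any
stage can be re-run from its predecessors' outputs.  A manifest records
per-stage wall times, parameter snapshots, and SHA-256 hashes of every
artifact; one global seed derives independent per-stage seeds.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd

from . import cellmap, cluster, de, io, networks, qc, simulate
from .config import PipelineConfig

__all__ = ["run_pipeline", "STAGE_NAMES"]

STAGE_NAMES = ["ingest", "qc_norm", "embed_cluster", "cellmap", "de_lmm",
               "netsets"]


def stage_seed(base_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31, derived from the global seed."""
    idx = STAGE_NAMES.index(stage)
    return int(np.random.SeedSequence((base_seed, idx)).generate_state(1)[0]
               % (2 ** 31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _synthetic_config(cfg: PipelineConfig) -> simulate.SyntheticConfig:
    s = cfg.synthetic
    base = simulate.demo_config(
        seed=stage_seed(cfg.seed, "ingest"),
        n_cells_per_sample=s.n_cells_per_sample,
        n_genes=s.n_genes,
        n_shared=s.n_shared_degs,
        n_specific_per_type=s.n_specific_degs_per_type,
        shared_lfc=s.shared_lfc,
        specific_lfc=s.specific_lfc,
    )
    base.n_participants = s.n_participants
    base.marker_fold = s.marker_fold
    base.program_genes_per_type = s.program_genes_per_type
    base.program_fold = s.program_fold
    base.participant_effect_sd = s.participant_effect_sd
    base.planted_high_mito_cells = s.planted_high_mito_cells
    base.planted_doublet_cells = s.planted_doublet_cells
    return base


def _synthetic_priors(outdir: Path, truth: simulate.GroundTruth,
                      adata: ad.AnnData, rng: np.random.Generator) -> None:
    """Write a prior edge list and GMT gene sets derived from the planted
    design plus random filler, so the network/enrichment stages have
    realistic inputs."""
    effect_genes = sorted(truth.lfc.index[(truth.lfc != 0).any(axis=1)])
    fillers = [g for g in adata.var_names if g.startswith("GENE")]
    edges: list[tuple[str, str]] = []
    for i, a in enumerate(effect_genes):
        for b in effect_genes[i + 1:]:
            edges.append((a, b))
    for _ in range(60):
        a, b = rng.choice(fillers, size=2, replace=False)
        edges.append((min(a, b), max(a, b)))
    pd.DataFrame(edges).to_csv(outdir / "edges.tsv", sep="\t",
                               header=False, index=False)

    shared = [g for g in effect_genes if g.startswith("DEG-SHARED")]
    sets: dict[str, list[str]] = {}
    if len(shared) >= 2:
        sets["planted_shared_response"] = shared
    specific = [g for g in effect_genes if g not in shared]
    if len(specific) >= 2:
        sets["planted_specific_response"] = specific
    for i in range(5):
        sets[f"random_set_{i}"] = list(
            rng.choice(fillers, size=20, replace=False))
    with open(outdir / "gene_sets.gmt", "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "synthetic"] + list(members)) + "\n")


def stage_ingest(cfg: PipelineConfig, outdir: Path) -> None:
    """Simulate (or copy in) counts, sample sheet, marker panel, priors."""
    if cfg.synthetic is not None and cfg.synthetic.enabled:
        sim_cfg = _synthetic_config(cfg)
        adata, truth = simulate.generate_counts(sim_cfg)
        io.write_10x_mtx(adata, outdir / "counts")
        sheet = adata.obs[["sample", "participant", "condition"]].copy()
        sheet.index.name = "barcode"
        sheet.to_csv(outdir / "sample_sheet.tsv", sep="\t")
        panel = truth.marker_panel()
        panel.to_csv(outdir / "marker_panel.tsv", sep="\t")
        truth.cells.to_csv(outdir / "truth_cells.tsv", sep="\t")
        truth.lfc.to_csv(outdir / "truth_lfc.tsv", sep="\t")
        rng = np.random.default_rng(stage_seed(cfg.seed, "ingest") + 1)
        _synthetic_priors(outdir, truth, adata, rng)
    else:
        adata = io.read_10x_mtx(cfg.inputs.matrix_dir)
        sheet = io.read_sample_sheet(cfg.inputs.sample_sheet)
        io.attach_sample_sheet(adata, sheet)
        io.write_10x_mtx(adata, outdir / "counts")
        sheet.to_csv(outdir / "sample_sheet.tsv", sep="\t")
        panel = io.read_marker_panel(cfg.inputs.marker_panel)
        panel.to_csv(outdir / "marker_panel.tsv", sep="\t")
        if cfg.inputs.edge_list is not None:
            edges = io.read_edge_list(cfg.inputs.edge_list)
            pd.DataFrame(edges).to_csv(outdir / "edges.tsv", sep="\t",
                                       header=False, index=False)
        if cfg.inputs.gene_sets is not None:
            sets = io.read_gmt(cfg.inputs.gene_sets)
            with open(outdir / "gene_sets.gmt", "w") as fh:
                for name, members in sets.items():
                    fh.write("\t".join([name, ""] + sorted(members)) + "\n")


def stage_qc_norm(cfg: PipelineConfig, outdir: Path) -> None:
    adata = io.read_10x_mtx(outdir / "counts")
    sheet = io.read_sample_sheet(outdir / "sample_sheet.tsv")
    io.attach_sample_sheet(adata, sheet)
    thr = qc.QCThresholds(
        min_genes_per_cell=cfg.qc.min_genes_per_cell,
        max_mito_fraction=cfg.qc.max_mito_fraction,
        max_reads_per_cell=cfg.qc.max_reads_per_cell,
        min_cells_per_gene_with_umi=cfg.qc.min_cells_per_gene_with_umi,
    )
    adata = qc.filter_genes(adata, thr)
    adata, report = qc.filter_cells(adata, thr=thr)
    report.to_csv(outdir / "qc_report.tsv", sep="\t")
    adata = qc.normalize(adata)
    if adata.obs[cfg.qc.batch_key].nunique() > 1:
        adata = qc.eb_batch_adjust(
            adata, batch_key=cfg.qc.batch_key,
            covariate_keys=cfg.qc.combat_covariates,
        )
    adata.write_h5ad(outdir / "adjusted.h5ad")


def stage_embed_cluster(cfg: PipelineConfig, outdir: Path) -> None:
    adata = ad.read_h5ad(outdir / "adjusted.h5ad")
    seed = stage_seed(cfg.seed, "embed_cluster")
    emb = cluster.embed(
        adata.X, n_pcs=cfg.cluster.n_pcs, perplexity=cfg.cluster.perplexity,
        n_iter=cfg.cluster.n_iter, seed=seed,
    )
    graph = cluster.build_graph(emb, k=cfg.cluster.knn_k)
    labels = cluster.louvain(graph, seed=seed)
    pd.DataFrame(
        {"tsne1": emb.coords[:, 0], "tsne2": emb.coords[:, 1]},
        index=adata.obs_names,
    ).rename_axis("barcode").to_csv(outdir / "embedding.tsv", sep="\t")
    pd.DataFrame({"cluster": labels.labels}, index=adata.obs_names) \
        .rename_axis("barcode").to_csv(outdir / "clusters.tsv", sep="\t")
    with open(outdir / "clustering.json", "w") as fh:
        json.dump({"n_clusters": labels.n_clusters,
                   "modularity": labels.modularity, "seed": seed}, fh)


def stage_cellmap(cfg: PipelineConfig, outdir: Path) -> None:
    adata = ad.read_h5ad(outdir / "adjusted.h5ad")
    panel = io.read_marker_panel(outdir / "marker_panel.tsv")
    clusters_df = pd.read_csv(outdir / "clusters.tsv", sep="\t", index_col=0)
    emb = pd.read_csv(outdir / "embedding.tsv", sep="\t", index_col=0)
    panel = panel.loc[panel.index.intersection(adata.var_names)]
    expr = pd.DataFrame(
        np.asarray(adata[:, panel.index].X.todense())
        if hasattr(adata.X, "todense") else adata[:, panel.index].X,
        index=adata.obs_names, columns=panel.index,
    )
    mapper = cellmap.MarkerMapper(
        expr, panel, clusters_df["cluster"].to_numpy(),
        emb[["tsne1", "tsne2"]].to_numpy(),
    )
    res = mapper.fit(p0=cfg.mapping.p0,
                     min_cluster_frac=cfg.mapping.min_cluster_frac)
    res.cell_table().rename_axis("barcode").to_csv(
        outdir / "assignment.tsv", sep="\t")
    res.profile.to_csv(outdir / "profile.tsv", sep="\t")
    res.assignment.merge_log.to_csv(outdir / "merge_log.tsv", sep="\t",
                                    index=False)
    res.summary().to_csv(outdir / "cluster_summary.tsv", sep="\t")


def stage_de_lmm(cfg: PipelineConfig, outdir: Path) -> None:
    adata = ad.read_h5ad(outdir / "adjusted.h5ad")
    assignment = pd.read_csv(outdir / "assignment.tsv", sep="\t", index_col=0)
    model = de.MixedDiffExpr.from_anndata(
        adata, assignment.loc[adata.obs_names, "final_type"].to_numpy(),
        min_cells=cfg.de.min_cells, min_frac=cfg.de.min_frac,
    )
    res = model.fit()
    res.table.to_csv(outdir / "de_table.tsv", sep="\t", index=False)
    res.summary(cfg.de.fdr).to_csv(outdir / "de_summary.tsv", sep="\t",
                                   index=False)
    res.sharing(cfg.de.fdr).to_csv(outdir / "sharing.tsv", sep="\t",
                                   index=False)
    with open(outdir / "de_status.json", "w") as fh:
        json.dump(res.type_status, fh)


def stage_netsets(cfg: PipelineConfig, outdir: Path) -> None:
    adata = ad.read_h5ad(outdir / "adjusted.h5ad")
    assignment = pd.read_csv(outdir / "assignment.tsv", sep="\t", index_col=0)
    de_tab = pd.read_csv(outdir / "de_table.tsv", sep="\t")
    edge_path = outdir / "edges.tsv"
    edge_list = io.read_edge_list(edge_path) if edge_path.exists() else []
    gmt_path = outdir / "gene_sets.gmt"
    gene_sets = io.read_gmt(gmt_path) if gmt_path.exists() else {}

    final_type = assignment.loc[adata.obs_names, "final_type"].to_numpy()
    condition = adata.obs["condition"].to_numpy()
    X = np.asarray(adata.X.todense()) if hasattr(adata.X, "todense") \
        else np.asarray(adata.X)

    edge_rows = []
    net_json: dict[str, dict] = {}
    enr_rows = []
    for ct in sorted(de_tab["cell_type"].unique()) if len(de_tab) else []:
        sub = de_tab[de_tab["cell_type"] == ct]
        candidates = networks.select_candidates(sub, cfg.network.p_nom)
        per_cond: dict[str, pd.DataFrame] = {}
        for cond in ("pre", "post"):
            mask = (final_type == ct) & (condition == cond)
            if candidates and edge_list and mask.sum() >= cfg.network.min_stratum_cells:
                tab = networks.test_edges(
                    candidates, edge_list, X[mask], adata.var_names,
                    fdr=cfg.network.fdr,
                    min_cells=cfg.network.min_stratum_cells,
                )
            else:
                tab = pd.DataFrame(columns=networks._EDGE_COLUMNS)
            per_cond[cond] = tab
            for _, r in tab.iterrows():
                edge_rows.append({"cell_type": ct, "condition": cond, **r})
        hubs = networks.find_hubs(per_cond["pre"], per_cond["post"],
                                  cfg.network.hub_min_degree)
        net_json[ct] = {
            "candidates": candidates,
            "hubs": hubs,
            "degrees": {
                cond: networks.degrees(per_cond[cond]).to_dict()
                for cond in ("pre", "post")
            },
        }
        if gene_sets:
            universe = sub["gene"].tolist()
            enr = networks.gene_set_enrichment(
                candidates, gene_sets, universe,
                min_set_size=cfg.network.min_set_size,
            )
            enr.insert(0, "cell_type", ct)
            enr_rows.append(enr)

    pd.DataFrame(edge_rows).to_csv(outdir / "edges_tested.tsv", sep="\t",
                                   index=False)
    with open(outdir / "networks.json", "w") as fh:
        json.dump(net_json, fh, indent=1)
    if enr_rows:
        pd.concat(enr_rows).to_csv(outdir / "enrichment.tsv", sep="\t",
                                   index=False)

    if cfg.network.receptor is not None:
        ct = cfg.network.receptor_cell_type or "B"
        lists = {}
        for cond in ("pre", "post"):
            mask = (final_type == ct) & (condition == cond)
            if mask.sum() >= cfg.network.min_stratum_cells and \
                    cfg.network.receptor in adata.var_names:
                tab = networks.receptor_coexpression(
                    X[mask], adata.var_names, cfg.network.receptor,
                    fdr=cfg.network.fdr,
                )
            else:
                tab = pd.DataFrame(
                    columns=["gene", "r", "p", "q", "significant"])
            tab.to_csv(outdir / f"receptor_{cond}.tsv", sep="\t", index=False)
            lists[cond] = tab.loc[tab["significant"] == True, "gene"].tolist()  # noqa: E712
        universe_n = int((X[final_type == ct] > 0).any(axis=0).sum())
        universe_n = max(universe_n, len(set(lists["pre"]) | set(lists["post"])))
        ov = networks.overlap_test(lists["pre"], lists["post"], universe_n)
        with open(outdir / "receptor_overlap.json", "w") as fh:
            json.dump({
                "receptor": cfg.network.receptor, "cell_type": ct,
                "n_pre": ov.n_a, "n_post": ov.n_b, "universe": ov.universe,
                "overlap": ov.overlap, "expected": ov.expected,
                "representation_factor": ov.representation_factor, "p": ov.p,
            }, fh)


_STAGES = {
    "ingest": stage_ingest,
    "qc_norm": stage_qc_norm,
    "embed_cluster": stage_embed_cluster,
    "cellmap": stage_cellmap,
    "de_lmm": stage_de_lmm,
    "netsets": stage_netsets,
}


def run_pipeline(cfg: PipelineConfig,
                 stages: list[str] | None = None) -> dict:
    """Execute the pipeline stages and return the run manifest.

    ``stages`` restricts execution (for resuming); each requested stage
    must find its predecessors' artifacts in ``cfg.outdir``.  The manifest
    is also written to ``<outdir>/manifest.json``.
    """
    todo = stages or STAGE_NAMES
    unknown = set(todo) - set(STAGE_NAMES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": cfg.seed,
        "parameters": json.loads(cfg.model_dump_json()),
        "stages": [],
    }
    before = {p for p in outdir.rglob("*") if p.is_file()}
    for name in STAGE_NAMES:
        if name not in todo:
            continue
        t0 = time.time()
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                _STAGES[name](cfg, outdir)
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        after = {p for p in outdir.rglob("*") if p.is_file()}
        new_or_touched = sorted(
            str(p.relative_to(outdir)) for p in after
            if p not in before or p.stat().st_mtime >= t0
        )
        manifest["stages"].append({
            "name": name,
            "seconds": round(time.time() - t0, 3),
            "seed": stage_seed(cfg.seed, name),
            "outputs": {
                rel: _sha256(outdir / rel) for rel in new_or_touched
                if rel != "manifest.json"
            },
            "warnings": [str(w.message) for w in caught],
        })
        before = after
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
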