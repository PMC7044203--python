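"""Shared fixtures: small synthetic datasets and one full pipeline run."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from scwithin import qc
from scwithin.config import NetworkSection, PipelineConfig, SyntheticSection
from scwithin.pipeline import run_pipeline
from scwithin.simulate import SyntheticConfig, generate_counts


@pytest.fixture(scope="session")
def small_dataset():
    """A small clean dataset (no planted QC failures), raw counts."""
    cfg = SyntheticConfig(
        n_cells_per_sample=120, n_genes=600, seed=11,
        lib_size_log_mean=float(np.log(5000)), lib_size_log_sd=0.2,
        program_genes_per_type=30,
    )
    return generate_counts(cfg)


@pytest.fixture(scope="session")
def qc_fixture():
    """Dataset with 50 planted high-mito cells and 20 planted doublets,
    disjoint, with library sizes generous enough that nothing else fails."""
    cfg = SyntheticConfig(
        n_cells_per_sample=150, n_genes=800, seed=3,
        lib_size_log_mean=float(np.log(6000)), lib_size_log_sd=0.2,
        planted_high_mito_cells=50, planted_doublet_cells=20,
        program_genes_per_type=40,
    )
    return generate_counts(cfg)


@pytest.fixture(scope="session")
def normalized_small(small_dataset):
    adata, truth = small_dataset
    adata = qc.filter_genes(adata)
    adata, _ = qc.filter_cells(adata)
    adata = qc.normalize(adata)
    return adata, truth


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One full pipeline run on the seeded 2,000-cell synthetic design.

    Serves the mapping-accuracy, clustering-quality, and end-to-end checks;
    returns (manifest, outdir, config).
    """
    outdir = tmp_path_factory.mktemp("demo_run")
    cfg = PipelineConfig(
        seed=1, outdir=outdir,
        synthetic=SyntheticSection(n_cells_per_sample=500),
        network=NetworkSection(receptor="CD79A", receptor_cell_type="B"),
    )
    manifest = run_pipeline(cfg)
    return manifest, outdir, cfg


@pytest.fixture(scope="session")
def demo_truth(demo_run):
    _, outdir, _ = demo_run
    cells = pd.read_csv(outdir / "truth_cells.tsv", sep="\t", index_col=0)
    lfc = pd.read_csv(outdir / "truth_lfc.tsv", sep="\t", index_col=0)
    return cells, lfc
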