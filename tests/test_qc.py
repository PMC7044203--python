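"""QC rules, normalization arithmetic, and batch adjustment."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from scwithin import qc


def _adata_from_counts(counts, genes=None, cells=None):
    counts = np.asarray(counts, dtype=np.float32)
    n_cells, n_genes = counts.shape
    adata = ad.AnnData(
        X=sp.csr_matrix(counts),
        obs=pd.DataFrame(index=cells or [f"c{i}" for i in range(n_cells)]),
        var=pd.DataFrame(index=genes or [f"g{i}" for i in range(n_genes)]),
    )
    adata.layers["counts"] = adata.X.copy()
    return adata


class TestFilters:
    def test_all_zero_genes_removed(self):
        counts = np.array([[1, 0, 2, 0, 5], [3, 0, 0, 0, 1]])
        adata = _adata_from_counts(counts)
        out = qc.filter_genes(adata)
        assert list(out.var_names) == ["g0", "g2", "g4"]

    def test_cell_boundaries_are_strict(self):
        """370 expressed genes, 10% mito, 100k reads are all retained."""
        n_genes = 400
        counts = np.zeros((4, n_genes))
        genes = [f"g{i}" for i in range(n_genes - 1)] + ["MT-X"]
        # cell 0: exactly 370 expressed genes, 5% mito, 50k reads
        counts[0, :369] = round(50_000 * 0.95 / 369)
        counts[0, -1] = 369 * counts[0, 0] * 0.05 / 0.95
        # cell 1: 369 expressed genes -> removed by the strict "< 370" rule
        counts[1, :369] = 10.0
        # cell 2: mito fraction exactly 0.10, 400 expressed genes
        counts[2, :399] = 9.0
        counts[2, -1] = 399.0  # 399 / 3990 = 0.10
        # cell 3: exactly 100,000 reads, 399 expressed genes
        counts[3, :399] = 1.0
        counts[3, 0] = 100_000 - 398
        adata = _adata_from_counts(np.round(counts), genes=genes)
        _, report = qc.filter_cells(adata)
        assert report.loc["c0", "n_genes"] == 370
        assert report.loc["c0", "removed_by"] == ""
        assert report.loc["c1", "removed_by"] == "low_genes"
        assert report.loc["c2", "mito_fraction"] == pytest.approx(0.10)
        assert report.loc["c2", "removed_by"] == ""
        assert report.loc["c3", "total_reads"] == 100_000
        assert report.loc["c3", "removed_by"] == ""

    def test_planted_failures_counted_and_attributed(self, qc_fixture):
        adata, truth = qc_fixture
        filtered, report = qc.filter_cells(adata)
        removed = report[report["removed_by"] != ""]
        assert len(removed) == 70
        hm = set(truth.cells.index[truth.cells["is_high_mito"]])
        db = set(truth.cells.index[truth.cells["is_doublet"]])
        assert set(removed.index[removed["removed_by"] == "high_mito"]) == hm
        assert set(removed.index[removed["removed_by"] == "high_reads"]) == db
        assert filtered.n_obs == adata.n_obs - 70

    def test_filters_commute(self, qc_fixture):
        adata, _ = qc_fixture
        a = qc.filter_genes(adata)
        a, _ = qc.filter_cells(a)
        b, _ = qc.filter_cells(adata)
        b = qc.filter_genes(b)
        assert list(a.obs_names) == list(b.obs_names)
        assert list(a.var_names) == list(b.var_names)
        assert (sp.csr_matrix(a.X) != sp.csr_matrix(b.X)).nnz == 0

    def test_all_cells_removed_is_hard_error(self):
        counts = np.ones((3, 5))
        adata = _adata_from_counts(counts)
        with pytest.raises(ValueError, match="every cell"):
            qc.filter_cells(adata)  # 5 expressed genes << 370


class TestNormalize:
    def test_hand_arithmetic(self):
        counts = np.array([[10, 90], [40, 160]])
        adata = _adata_from_counts(counts)
        out = qc.normalize(adata, scale=10_000)
        X = np.asarray(sp.csr_matrix(out.X).todense())
        assert X[0, 0] == pytest.approx(np.log(1 + 10 * 10_000 / 100), rel=1e-6)
        assert X[1, 1] == pytest.approx(np.log(1 + 160 * 10_000 / 200), rel=1e-6)

    def test_zero_count_maps_to_zero(self):
        adata = _adata_from_counts(np.array([[0, 5], [2, 3]]))
        X = np.asarray(sp.csr_matrix(qc.normalize(adata).X).todense())
        assert X[0, 0] == 0.0

    def test_depth_invariance(self):
        counts = np.array([[3, 7, 0, 2]])
        doubled = 2 * counts
        X1 = np.asarray(sp.csr_matrix(
            qc.normalize(_adata_from_counts(counts)).X).todense())
        X2 = np.asarray(sp.csr_matrix(
            qc.normalize(_adata_from_counts(doubled)).X).todense())
        np.testing.assert_allclose(X1, X2, rtol=1e-6)

    @given(
        counts=hnp.arrays(
            dtype=np.int64, shape=st.tuples(st.integers(1, 6), st.integers(2, 8)),
            elements=st.integers(0, 50),
        ).filter(lambda c: (c.sum(axis=1) > 0).all()),
        depth=st.integers(2, 9),
    )
    @settings(max_examples=40, deadline=None)
    def test_depth_invariance_property(self, counts, depth):
        """Multiplying any cell's counts by a constant leaves its
        normalized vector unchanged."""
        X1 = np.asarray(sp.csr_matrix(
            qc.normalize(_adata_from_counts(counts)).X).todense())
        X2 = np.asarray(sp.csr_matrix(
            qc.normalize(_adata_from_counts(counts * depth)).X).todense())
        np.testing.assert_allclose(X1, X2, rtol=1e-5, atol=1e-6)

    def test_per_cell_totals_hit_scale(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 20, (5, 50))
        X = np.asarray(sp.csr_matrix(
            qc.normalize(_adata_from_counts(counts), scale=10_000).X).todense())
        totals = (np.expm1(X)).sum(axis=1)
        np.testing.assert_allclose(totals, 10_000, rtol=1e-4)


class TestCombat:
    def test_identical_batches_nearly_unchanged(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (100, 1200))
        batch = np.array(["a", "b"] * 600)
        adj, _ = qc.combat(X, batch)
        assert np.abs(adj - X).mean() < 0.02

    def test_planted_shift_removed_and_grand_mean_kept(self):
        rng = np.random.default_rng(2)
        G, n = 200, 1000
        X = rng.normal(0, 1, (G, n))
        delta = rng.normal(0, 1.5, G)
        batch = np.array(["a"] * 500 + ["b"] * 500)
        X[:, 500:] += delta[:, None]
        adj, _ = qc.combat(X, batch)
        diff = adj[:, :500].mean(axis=1) - adj[:, 500:].mean(axis=1)
        assert np.abs(diff).mean() < 0.05
        np.testing.assert_allclose(adj.mean(axis=1), X.mean(axis=1),
                                   rtol=1e-6, atol=1e-9)

    def test_zero_variance_gene_passthrough(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (10, 100))
        X[4] = 2.5
        batch = np.array(["a"] * 50 + ["b"] * 50)
        adj, passthrough = qc.combat(X, batch)
        assert passthrough[4]
        np.testing.assert_array_equal(adj[4], X[4])

    def test_single_batch_identity_with_warning(self):
        X = np.random.default_rng(4).normal(size=(5, 20))
        with pytest.warns(UserWarning, match="single batch"):
            adj, _ = qc.combat(X, np.array(["a"] * 20))
        np.testing.assert_array_equal(adj, X)

    def test_agrees_with_reference_implementation(self):
        """Cross-check against scanpy's ComBat on shared settings (no
        covariates); per-gene centering removes the recentring offset."""
        scanpy = pytest.importorskip("scanpy")
        rng = np.random.default_rng(5)
        G, n = 80, 400
        X = rng.normal(0, 1, (G, n))
        X[:, 200:] += rng.normal(0, 1, G)[:, None]
        batch = np.array(["a"] * 200 + ["b"] * 200)
        ours, _ = qc.combat(X, batch)
        adata = ad.AnnData(X=X.T.copy(),
                           obs=pd.DataFrame({"batch": batch}))
        scanpy.pp.combat(adata, key="batch")
        theirs = adata.X.T
        ours_c = ours - ours.mean(axis=1, keepdims=True)
        theirs_c = theirs - theirs.mean(axis=1, keepdims=True)
        assert np.abs(ours_c - theirs_c).mean() < 0.02

    def test_condition_covariate_protects_signal(self):
        """A true condition effect confounded partially with batch survives
        adjustment when condition is in the model."""
        rng = np.random.default_rng(6)
        G, n = 100, 800
        X = rng.normal(0, 1, (G, n))
        batch = np.repeat(["a", "b"], n // 2)
        cond = np.tile(np.repeat(["pre", "post"], n // 4), 2)
        X[:10][:, cond == "post"] += 1.0
        adj, _ = qc.combat(X, batch, pd.DataFrame({"condition": cond}))
        eff = adj[:10][:, cond == "post"].mean() - adj[:10][:, cond == "pre"].mean()
        assert eff > 0.8

    def test_adjust_wrapper_sets_flags(self, normalized_small):
        adata, _ = normalized_small
        out = qc.eb_batch_adjust(adata)
        assert out.uns["batch_adjusted"]
        assert "combat_passthrough" in out.var
        assert np.isfinite(np.asarray(out.X)).all()
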