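"""Edge testing, hubs, receptor co-expression, overlap and enrichment."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from scwithin import networks


class TestSelectCandidates:
    def test_strict_boundary_and_ordering(self):
        table = pd.DataFrame({
            "gene": ["a", "b", "c", "d"],
            "p": [2e-3, 1e-4, 1e-3, 5e-4],
        })
        assert networks.select_candidates(table) == ["b", "d"]  # 1e-3 excluded


def _stratum(rng, n, n_genes, corr_pairs=()):
    X = rng.normal(0, 1, (n, n_genes))
    for (i, j, r) in corr_pairs:
        X[:, j] = r * X[:, i] + np.sqrt(1 - r ** 2) * rng.normal(0, 1, n)
    return X


class TestEdges:
    def test_perfect_linear_pair_retained(self):
        rng = np.random.default_rng(0)
        X = _stratum(rng, 50, 2)
        X[:, 1] = 2 * X[:, 0]
        genes = pd.Index(["a", "b"])
        tab = networks.test_edges(["a", "b"], [("a", "b")], X, genes)
        assert tab.loc[0, "status"] == "significant"
        assert tab.loc[0, "p"] == 0.0
        assert tab.loc[0, "slope"] == pytest.approx(2.0)

    def test_swap_changes_slope_not_decision(self):
        rng = np.random.default_rng(1)
        X = _stratum(rng, 120, 2, [(0, 1, 0.5)])
        genes = pd.Index(["a", "b"])
        t1 = networks.test_edges(["a", "b"], [("a", "b")], X, genes)
        t2 = networks.test_edges(["a", "b"], [("b", "a")], X, genes)
        assert t1.loc[0, "p"] == pytest.approx(t2.loc[0, "p"], rel=1e-9)
        assert abs(t1.loc[0, "t"]) == pytest.approx(abs(t2.loc[0, "t"]),
                                                    rel=1e-9)
        assert t1.loc[0, "slope"] != t2.loc[0, "slope"]

    def test_zero_variance_gene_untestable(self):
        rng = np.random.default_rng(2)
        X = _stratum(rng, 30, 2)
        X[:, 1] = 3.3
        tab = networks.test_edges(["a", "b"], [("a", "b")], X,
                                  pd.Index(["a", "b"]))
        assert tab.loc[0, "status"] == "untestable"

    def test_power_at_r06_n300(self):
        rng = np.random.default_rng(3)
        hits = 0
        reps = 200
        for _ in range(reps):
            X = _stratum(rng, 300, 2, [(0, 1, 0.6)])
            tab = networks.test_edges(["a", "b"], [("a", "b")], X,
                                      pd.Index(["a", "b"]))
            hits += tab.loc[0, "status"] == "significant"
        assert hits / reps >= 0.95

    def test_null_retention_tracks_fdr(self):
        rng = np.random.default_rng(4)
        hits = 0
        reps = 200
        for _ in range(reps):
            X = _stratum(rng, 500, 2)
            tab = networks.test_edges(["a", "b"], [("a", "b")], X,
                                      pd.Index(["a", "b"]))
            hits += tab.loc[0, "status"] == "significant"
        assert 0.01 <= hits / reps <= 0.10

    def test_too_few_cells_rejected(self):
        X = np.zeros((5, 2))
        with pytest.raises(ValueError, match="min_cells"):
            networks.test_edges(["a"], [], X, pd.Index(["a", "b"]))


class TestHubs:
    def _edges(self, pairs):
        df = pd.DataFrame(pairs, columns=["gene_a", "gene_b"])
        df["slope"] = 1.0
        df["t"] = 5.0
        df["p"] = 1e-6
        df["q"] = 1e-5
        df["status"] = "significant"
        return df

    def test_degree_four_in_one_condition_is_hub(self):
        pre = self._edges([("h", f"x{i}") for i in range(4)])
        post = self._edges([])
        assert networks.find_hubs(pre, post) == ["h"]

    def test_no_summing_across_conditions(self):
        pre = self._edges([("h", f"x{i}") for i in range(3)])
        post = self._edges([("h", f"y{i}") for i in range(3)])
        assert networks.find_hubs(pre, post) == []

    def test_star_graph_center_only(self):
        post = self._edges([("center", f"leaf{i}") for i in range(5)])
        pre = self._edges([])
        assert networks.find_hubs(pre, post) == ["center"]


class TestReceptor:
    def test_identical_gene_has_r_one(self):
        rng = np.random.default_rng(5)
        X = rng.normal(0, 1, (60, 3))
        X[:, 1] = X[:, 0]
        tab = networks.receptor_coexpression(
            X, pd.Index(["rec", "twin", "other"]), "rec")
        row = tab.set_index("gene").loc["twin"]
        assert row["r"] == pytest.approx(1.0)
        assert row["significant"]

    def test_zero_variance_receptor_empty_with_reason(self):
        X = np.ones((30, 2))
        tab = networks.receptor_coexpression(X, pd.Index(["rec", "g"]), "rec")
        assert len(tab) == 0
        assert "zero variance" in tab.attrs["reason"]

    def test_null_fdr_consistent(self):
        rng = np.random.default_rng(6)
        m = 300
        counts = []
        for _ in range(20):
            X = rng.normal(0, 1, (200, m + 1))
            tab = networks.receptor_coexpression(
                X, pd.Index([f"g{i}" for i in range(m + 1)]), "g0")
            counts.append(int(tab["significant"].sum()))
        assert np.mean(counts) <= 0.05 * m * 1.5

    def test_planted_module_recovered(self):
        rng = np.random.default_rng(7)
        n, n_null = 400, 200
        rec = rng.normal(0, 1, n)
        module = 0.5 * rec[:, None] + np.sqrt(0.75) * rng.normal(0, 1, (n, 30))
        X = np.column_stack([rec, module, rng.normal(0, 1, (n, n_null))])
        genes = pd.Index(["rec"] + [f"m{i}" for i in range(30)]
                         + [f"n{i}" for i in range(n_null)])
        tab = networks.receptor_coexpression(X, genes, "rec")
        hits = set(tab.loc[tab["significant"], "gene"])
        assert len(hits & {f"m{i}" for i in range(30)}) >= 27


def _hyper_tail_exact(N, a, b, k):
    """Exact upper-tail P[X >= k] by pmf enumeration (Fraction arithmetic)."""
    total = Fraction(0)
    for i in range(k, min(a, b) + 1):
        total += Fraction(comb(a, i) * comb(N - a, b - i), comb(N, b))
    return float(total)


class TestOverlap:
    def test_disjoint_lists(self):
        res = networks.overlap_test(["a", "b"], ["c", "d"], 20)
        assert res.overlap == 0
        assert res.representation_factor == 0.0
        assert res.p == 1.0

    def test_hand_enumeration_5_5_20_3(self):
        A = [f"g{i}" for i in range(5)]
        B = [f"g{i}" for i in range(2, 7)]
        res = networks.overlap_test(A, B, 20)
        assert res.overlap == 3
        assert res.expected == pytest.approx(25 / 20)
        assert res.p == pytest.approx(_hyper_tail_exact(20, 5, 5, 3), abs=1e-12)

    def test_identical_lists_minimal_tail(self):
        A = [f"g{i}" for i in range(6)]
        res = networks.overlap_test(A, A, 25)
        assert res.overlap == 6
        assert res.p == pytest.approx(_hyper_tail_exact(25, 6, 6, 6), abs=1e-14)

    def test_universe_smaller_than_union_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            networks.overlap_test(["a", "b"], ["c"], 2)

    def test_exhaustive_small_instances(self):
        """Match exact enumeration for every (N <= 30, |A|,|B| <= 10, k)."""
        for N in range(2, 31, 4):
            for a in range(1, min(10, N) + 1, 2):
                for b in range(1, min(10, N) + 1, 3):
                    for k in range(max(0, a + b - N), min(a, b) + 1):
                        A = [f"g{i}" for i in range(a)]
                        B = [f"g{i}" for i in range(a - k, a - k + b)]
                        if len(set(A) | set(B)) > N:
                            continue
                        res = networks.overlap_test(A, B, N)
                        assert res.overlap == k
                        assert res.p == pytest.approx(
                            _hyper_tail_exact(N, a, b, k), abs=1e-12)


class TestEnrichment:
    def test_closed_form_fully_contained_set(self):
        universe = [f"g{i}" for i in range(100)]
        cand = universe[:10]
        sets = {"hit_set": set(universe[:5])}
        tab = networks.gene_set_enrichment(cand, sets, universe)
        expected = comb(5, 5) * comb(95, 5) / comb(100, 10)
        assert tab.loc[0, "p"] == pytest.approx(expected, rel=1e-9)

    def test_disjoint_set_p_one(self):
        universe = [f"g{i}" for i in range(50)]
        tab = networks.gene_set_enrichment(
            universe[:5], {"other": set(universe[40:])}, universe)
        assert tab.loc[0, "p"] == 1.0

    def test_whole_universe_set_uninformative(self):
        universe = [f"g{i}" for i in range(30)]
        tab = networks.gene_set_enrichment(
            universe[:4], {"all": set(universe)}, universe)
        assert tab.loc[0, "p"] == pytest.approx(1.0)

    def test_small_sets_skipped_and_order_invariant(self):
        rng = np.random.default_rng(8)
        universe = [f"g{i}" for i in range(60)]
        cand = list(rng.choice(universe, 15, replace=False))
        sets = {"tiny": set(universe[:3]), "ok": set(universe[10:25])}
        t1 = networks.gene_set_enrichment(cand, sets, universe)
        t2 = networks.gene_set_enrichment(cand[::-1], sets, universe)
        assert list(t1["gene_set"]) == ["ok"]
        pd.testing.assert_frame_equal(t1, t2)

    def test_null_significant_sets_bounded(self):
        rng = np.random.default_rng(9)
        universe = [f"g{i}" for i in range(300)]
        n_sets = 40
        counts = []
        for _ in range(20):
            cand = list(rng.choice(universe, 20, replace=False))
            sets = {
                f"s{j}": set(rng.choice(universe, 15, replace=False))
                for j in range(n_sets)
            }
            tab = networks.gene_set_enrichment(cand, sets, universe)
            counts.append(int((tab["q"] < 0.05).sum()))
        assert np.mean(counts) <= 0.05 * n_sets
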