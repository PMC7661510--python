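"""Allele frequencies, Hellinger/PCA, dbMEM and permutation RDA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import pdist, squareform

from reefadapt import structure


class TestSiteFrequencies:
    def test_copy_counting(self):
        calls = pd.DataFrame({"snp": [0, 1, 2, 1, 1]})
        sfm = structure.site_allele_frequencies(calls, ["a"] * 5, min_samples=5)
        assert sfm.freq.loc["a", "snp"] == pytest.approx(0.5)

    def test_small_site_dropped(self):
        calls = pd.DataFrame({"snp": [0, 1, 2, 1, 1, 0, 0, 0, 0]})
        sites = ["a"] * 5 + ["b"] * 4
        sfm = structure.site_allele_frequencies(calls, sites, min_samples=5)
        assert sfm.dropped == ["b"]
        assert list(sfm.freq.index) == ["a"]

    def test_monomorphic_snp_zero_everywhere(self):
        calls = pd.DataFrame({"fixed": [2] * 10, "poly": [0, 1] * 5})
        sites = ["a"] * 5 + ["b"] * 5
        sfm = structure.site_allele_frequencies(calls, sites, min_samples=5)
        assert (sfm.freq["fixed"] == 0).all()

    def test_global_minor_orientation(self):
        # allele '1' is globally major for snp1: frequencies report the flip
        calls = pd.DataFrame({"snp1": [0, 1, 2, 1, 1, 2, 2, 2, 1, 2],
                              "snp2": [0, 0, 0, 0, 0, 1, 1, 0, 0, 0]})
        sfm = structure.site_allele_frequencies(calls, ["a"] * 5 + ["b"] * 5,
                                                min_samples=5)
        assert sfm.freq.loc["b", "snp1"] == pytest.approx(0.1)
        assert sfm.freq.loc["b", "snp2"] == pytest.approx(0.2)

    def test_all_sites_too_small(self):
        calls = pd.DataFrame({"snp": [0, 1]})
        with pytest.raises(ValueError):
            structure.site_allele_frequencies(calls, ["a", "b"], min_samples=5)


class TestHellinger:
    @pytest.mark.parametrize("row,expected", [
        ([4.0, 0.0], [1.0, 0.0]),
        ([1.0, 1.0, 2.0], [0.5, 0.5, np.sqrt(0.5)]),
    ])
    def test_known_rows(self, row, expected):
        out = structure.hellinger_transform(np.array([row]))
        np.testing.assert_allclose(out[0], expected)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(0, 10_000))
    def test_rows_have_unit_sum_of_squares(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.uniform(0.0, 1.0, size=(5, 8))
        y[0, :] += 0.01  # keep rows nonzero
        y[1:, rng.integers(8)] += 0.01
        out = structure.hellinger_transform(y)
        np.testing.assert_allclose((out ** 2).sum(axis=1), 1.0)

    def test_zero_row_named(self):
        f = pd.DataFrame([[0.0, 0.0], [1.0, 1.0]], index=["dead", "ok"])
        with pytest.raises(ValueError, match="dead"):
            structure.hellinger_transform(f)


class TestPca:
    def test_keeps_minimal_leading_set(self):
        rng = np.random.default_rng(0)
        basis, _ = np.linalg.qr(rng.normal(size=(40, 3)))
        # component variances 0.6 / 0.2 / 0.2: two PCs reach 80%
        X = basis * np.sqrt(np.array([0.6, 0.2, 0.2]) * 40)
        scores = structure.pca_cumulative(X, 0.80)
        assert scores.shape[1] == 2
        dominant = basis[:, :1] * 30 + 0.01 * rng.normal(size=(40, 1))
        X2 = np.column_stack([dominant, 0.1 * basis[:, 1:]])
        assert structure.pca_cumulative(X2, 0.80).shape[1] == 1

    def test_all_pcs_reconstruct_centered_matrix(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 4))
        scores = structure.pca_cumulative(X, 1.0)
        Xc = X - X.mean(axis=0)
        # scores carry all the variance: squared norms match exactly
        assert (scores ** 2).sum() == pytest.approx((Xc ** 2).sum())

    def test_bad_threshold(self):
        with pytest.raises(ValueError):
            structure.pca_cumulative(np.eye(3), 1.5)


class TestSiteCostDistances:
    def test_symmetrization_mean(self, small_grid):
        # an asymmetric pair d(A->B)=x, d(B->A)=y is reconciled to (x+y)/2
        from reefadapt import graph, synthetic

        u, v = synthetic.gen_current_field(small_grid, 0.08, 0.0, 0.0, 2, seed=0)
        f = graph.temporal_mean_field(u, v, small_grid.resolution_km)
        tg = graph.build_transition_graph(f, 8, 0.01)
        coords = np.array([[2.5, 2.5], [22.5, 2.5]])
        from scipy.sparse.csgraph import dijkstra

        nodes = tg.nearest_nodes(coords)
        directed = dijkstra(tg.costs, directed=True, indices=nodes)[:, nodes]
        sym = structure.site_cost_distances(tg, coords)
        assert sym[0, 1] == pytest.approx(0.5 * (directed[0, 1] + directed[1, 0]))
        assert directed[0, 1] != pytest.approx(directed[1, 0])  # genuinely directed

    def test_zero_current_already_symmetric(self, small_grid):
        from reefadapt import graph, synthetic

        u, v = synthetic.gen_current_field(small_grid, 0.0, 0.0, 0.0, 3, seed=0)
        f = graph.temporal_mean_field(u, v, small_grid.resolution_km)
        tg = graph.build_transition_graph(f, 8, 0.01)
        coords = np.array([[2.5, 2.5], [12.5, 7.5], [22.5, 12.5]])
        d = structure.site_cost_distances(tg, coords)
        np.testing.assert_allclose(d, d.T)
        assert np.all(np.diag(d) == 0)


class TestDbMem:
    def test_three_collinear_points_match_direct_pcoa(self):
        D = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 1.0], [2.0, 1.0, 0.0]])
        basis = structure.dbmem(D)
        # oracle: truncate at the longest MST edge (1), replace 2 by 4,
        # Gower double-centering, direct eigendecomposition
        Dt = np.array([[0.0, 1.0, 4.0], [1.0, 0.0, 1.0], [4.0, 1.0, 0.0]])
        A = -0.5 * Dt ** 2
        J = np.eye(3) - np.ones((3, 3)) / 3
        vals, vecs = np.linalg.eigh(J @ A @ J)
        keep = vals > 1e-10
        expected = vecs[:, keep] * np.sqrt(vals[keep])
        assert basis.truncation == pytest.approx(1.0)
        assert basis.vectors.shape == expected.shape
        for col in range(expected.shape[1]):
            got = basis.vectors[:, col]
            want = expected[:, ::-1][:, col]
            assert (np.allclose(got, want, atol=1e-8)
                    or np.allclose(got, -want, atol=1e-8))

    def test_columns_centered_orthogonal(self):
        rng = np.random.default_rng(2)
        D = squareform(pdist(rng.uniform(0, 10, size=(15, 2))))
        basis = structure.dbmem(D)
        np.testing.assert_allclose(basis.vectors.mean(axis=0), 0, atol=1e-10)
        gram = basis.vectors.T @ basis.vectors
        np.testing.assert_allclose(gram - np.diag(np.diag(gram)), 0, atol=1e-8)
        assert (basis.eigenvalues > 0).all()

    def test_scaling_distances_preserves_directions(self):
        rng = np.random.default_rng(3)
        D = squareform(pdist(rng.uniform(0, 10, size=(12, 2))))
        b1 = structure.dbmem(D)
        b2 = structure.dbmem(2 * D)
        for c in range(min(b1.vectors.shape[1], b2.vectors.shape[1])):
            v1 = b1.vectors[:, c] / np.linalg.norm(b1.vectors[:, c])
            v2 = b2.vectors[:, c] / np.linalg.norm(b2.vectors[:, c])
            assert abs(abs(v1 @ v2) - 1) < 1e-8

    def test_too_few_sites(self):
        with pytest.raises(ValueError):
            structure.dbmem(np.zeros((2, 2)))


class TestRda:
    @pytest.fixture(scope="class")
    @staticmethod
    def basis():
        rng = np.random.default_rng(4)
        D = squareform(pdist(rng.uniform(0, 10, size=(25, 2))))
        return structure.dbmem(D)

    def test_planted_predictor_selected_exactly(self, basis):
        planted = 2
        Y = np.column_stack([1.5 * basis.vectors[:, planted],
                             -0.7 * basis.vectors[:, planted]])
        sel = structure.forward_select_rda(Y, basis, n_perm=199, seed=0)
        assert sel == [planted]

    def test_null_rarely_selects(self, basis):
        picks = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            Y = rng.normal(size=(25, 2))
            if structure.forward_select_rda(Y, basis, n_perm=99, seed=seed):
                picks += 1
        assert picks <= 4  # about alpha-level selection on pure noise

    def test_selection_deterministic(self, basis):
        rng = np.random.default_rng(5)
        Y = basis.vectors[:, [1]] + 0.3 * rng.normal(size=(25, 1))
        a = structure.forward_select_rda(Y, basis, n_perm=199, seed=42)
        b = structure.forward_select_rda(Y, basis, n_perm=199, seed=42)
        assert a == b

    def test_exact_fit_minimal_p(self, basis):
        X = basis.vectors[:, :2]
        B = np.array([[1.0, -0.5], [0.3, 0.8]])
        Y = X @ B
        res = structure.rda_anova(Y, X, n_perm=199, seed=1)
        assert res.r2 == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 200)

    def test_adjusted_r2_closed_form(self, basis):
        rng = np.random.default_rng(6)
        Y = basis.vectors[:, [0]] + rng.normal(size=(25, 3))
        X = basis.vectors[:, :2]
        res = structure.rda_anova(Y, X, n_perm=99, seed=2)
        n, m = 25, 2
        assert res.adj_r2 == pytest.approx(1 - (1 - res.r2) * (n - 1) / (n - m - 1))

    def test_saturated_model_rejected(self):
        with pytest.raises(ValueError):
            structure.rda_anova(np.random.default_rng(0).normal(size=(4, 2)),
                                np.eye(4)[:, :3], n_perm=9)

    def test_pipeline_invariant_to_snp_order(self):
        rng = np.random.default_rng(7)
        calls = pd.DataFrame(rng.integers(0, 3, size=(30, 12)),
                             columns=[f"snp{i}" for i in range(12)]).astype(float)
        sites = np.repeat([f"s{i}" for i in range(6)], 5)
        perm = rng.permutation(12)
        out1 = structure.site_allele_frequencies(calls, sites)
        out2 = structure.site_allele_frequencies(calls.iloc[:, perm], sites)
        h1 = structure.hellinger_transform(out1.freq)
        h2 = structure.hellinger_transform(out2.freq[out1.freq.columns])
        np.testing.assert_allclose(h1, h2)
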