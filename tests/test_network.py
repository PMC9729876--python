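"""Co-expression network stack: adjacency, soft threshold, TOM, modules, hubs."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirdsd import (
    CohortSpec,
    ModulePlan,
    adjacency_matrix,
    detect_modules,
    generate_cohort,
    hub_gene,
    module_eigengene,
    module_trait_correlation,
    pick_soft_threshold,
    topological_overlap,
)
from mirdsd.cohort import inv_log2p1, log2p1


def _expr(log2_values, gene_ids=None):
    arr = np.atleast_2d(log2_values)
    gene_ids = gene_ids or [f"g{i}" for i in range(arr.shape[0])]
    df = pd.DataFrame(inv_log2p1(arr), index=gene_ids,
                      columns=[f"s{i}" for i in range(arr.shape[1])])
    df.index.name = "gene_id"
    return df


class TestAdjacency:
    def test_perfectly_correlated_pair_is_one_for_any_beta(self):
        x = np.linspace(3, 5, 8)
        expr = _expr([x, 2 * x - 1])
        for beta in (1, 7, 20):
            assert adjacency_matrix(expr, beta).iloc[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_zero_diagonal(self):
        rng = np.random.default_rng(0)
        expr = _expr(rng.normal(4, 1, (5, 8)))
        assert np.all(np.diag(adjacency_matrix(expr, 7).values) == 0)

    def test_half_correlation_to_the_seventh(self):
        assert 0.5**7 == pytest.approx(0.0078125)  # the arithmetic the matrix must hit
        rng = np.random.default_rng(1)
        expr = _expr(rng.normal(4, 1, (6, 10)))
        A = adjacency_matrix(expr, 7)
        C = np.corrcoef(log2p1(expr.values))
        i, j = 2, 4
        assert A.iloc[i, j] == pytest.approx(abs(C[i, j]) ** 7, abs=1e-14)

    def test_matches_naive_double_loop_oracle(self):
        rng = np.random.default_rng(2)
        expr = _expr(rng.normal(4, 1, (5, 8)))
        A = adjacency_matrix(expr, 6).values
        L = log2p1(expr.values)
        for i in range(5):
            for j in range(5):
                expected = 0.0 if i == j else abs(stats.pearsonr(L[i], L[j])[0]) ** 6
                assert A[i, j] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_gene_warns_and_zeroes(self):
        rng = np.random.default_rng(3)
        L = rng.normal(4, 1, (4, 8))
        L[0] = 4.0
        expr = _expr(L)
        with pytest.warns(UserWarning, match="zero-variance"):
            A = adjacency_matrix(expr, 3)
        assert np.all(A.values[0] == 0)


class TestSoftThreshold:
    def test_unreachable_target_falls_back_to_argmax_with_warning(self):
        rng = np.random.default_rng(4)
        expr = _expr(rng.normal(4, 1, (30, 12)))
        with pytest.warns(UserWarning, match="no power"):
            res = pick_soft_threshold(expr, r2_target=1.0)
        assert res.warning
        assert res.beta == int(res.fit_table.loc[res.fit_table.fit_r2.idxmax(), "power"])

    def test_all_constant_expression_rejected(self):
        expr = _expr(np.full((5, 8), 4.0))
        with pytest.raises(ValueError, match="constant"):
            pick_soft_threshold(expr)

    def test_scale_free_modular_data_reaches_target(self):
        from mirdsd import scale_free_module_cohort

        spec, _, _ = scale_free_module_cohort(seed=0)
        expr, _ = generate_cohort(spec)
        res = pick_soft_threshold(expr)
        assert not res.warning
        assert res.fit_r2 >= 0.8
        assert 1 <= res.beta <= 20


class TestTopologicalOverlap:
    def test_disconnected_pair_without_shared_neighbors_is_zero(self):
        A = pd.DataFrame(np.zeros((3, 3)))
        A.iloc[0, 1] = A.iloc[1, 0] = 0.0
        T = topological_overlap(A)
        assert T.iloc[0, 1] == 0.0

    def test_full_clique_has_unit_overlap(self):
        A = pd.DataFrame(np.ones((4, 4)) - np.eye(4))
        T = topological_overlap(A).values
        assert np.allclose(T, 1.0)

    def test_three_node_hand_evaluation(self):
        A = pd.DataFrame([[0, 0.5, 0.2], [0.5, 0, 0.4], [0.2, 0.4, 0]])
        T = topological_overlap(A)
        # direct evaluation: (sum_u a_0u a_u1 + a_01) / (min(k0,k1) + 1 - a_01)
        expected_01 = (0.2 * 0.4 + 0.5) / (min(0.7, 0.9) + 1 - 0.5)
        assert T.iloc[0, 1] == pytest.approx(expected_01, abs=1e-12)

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(6)
        M = rng.uniform(0, 1, (6, 6))
        A = (M + M.T) / 2
        np.fill_diagonal(A, 0)
        T = topological_overlap(pd.DataFrame(A)).values
        k = A.sum(axis=1)
        for i in range(6):
            for j in range(6):
                if i == j:
                    assert T[i, j] == 1.0
                    continue
                num = sum(A[i, u] * A[u, j] for u in range(6)) + A[i, j]
                den = min(k[i], k[j]) + 1 - A[i, j]
                assert T[i, j] == pytest.approx(num / den, abs=1e-12)

    def test_values_in_unit_interval_and_symmetric(self):
        rng = np.random.default_rng(7)
        M = rng.uniform(0, 1, (20, 20))
        A = (M + M.T) / 2
        np.fill_diagonal(A, 0)
        T = topological_overlap(pd.DataFrame(A)).values
        assert np.all((T >= 0) & (T <= 1))
        assert np.allclose(T, T.T, atol=1e-10)


class TestDetectModules:
    def _block_tom(self, sizes, within=0.9, across=0.02):
        n = sum(sizes)
        T = np.full((n, n), across)
        start = 0
        for s in sizes:
            T[start:start + s, start:start + s] = within
            start += s
        np.fill_diagonal(T, 1.0)
        return pd.DataFrame(T)

    def test_separable_blocks_recovered_exactly(self):
        T = self._block_tom([6, 6])
        labels = detect_modules(T, cut_height=0.5, min_module_size=3)
        assert len(set(labels[:6])) == 1 and len(set(labels[6:])) == 1
        assert labels.iloc[0] != labels.iloc[6]
        assert (labels > 0).all()

    def test_min_size_larger_than_clusters_makes_all_grey(self):
        T = self._block_tom([6, 6])
        labels = detect_modules(T, cut_height=0.5, min_module_size=7)
        assert (labels == 0).all()

    def test_invalid_cut_height_rejected(self):
        T = self._block_tom([4])
        for bad in (0.0, 1.5, -0.2):
            with pytest.raises(ValueError, match="cut_height"):
                detect_modules(T, cut_height=bad)

    def test_planted_modules_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        from mirdsd import scale_free_module_cohort
        from mirdsd.scenarios import MODULE_CUT_HEIGHT, MODULE_MIN_SIZE

        spec, planted, _ = scale_free_module_cohort(seed=1)
        expr, _ = generate_cohort(spec)
        res = pick_soft_threshold(expr)
        tom = topological_overlap(adjacency_matrix(expr, res.beta))
        labels = detect_modules(tom, MODULE_CUT_HEIGHT, MODULE_MIN_SIZE)
        assert adjusted_rand_score(planted, labels.values) >= 0.8


class TestEigengene:
    def test_identical_genes_give_their_zscored_profile(self):
        x = np.array([3.0, 4.0, 5.0, 4.5, 3.5, 6.0])
        expr = _expr([x, x, x])
        labels = pd.Series([1, 1, 1], index=expr.index)
        eig = module_eigengene(expr, labels).loc["ME1"].values
        z = (x - x.mean()) / x.std()
        r = np.corrcoef(eig, z)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-10)

    def test_orientation_mean_member_correlation_positive(self):
        rng = np.random.default_rng(8)
        f = rng.normal(0, 1, 20)
        L = 4 + np.outer(rng.uniform(0.5, 1, 6), f) + rng.normal(0, 0.2, (6, 20))
        expr = _expr(L)
        labels = pd.Series([1] * 6, index=expr.index)
        eig = module_eigengene(expr, labels).loc["ME1"].values
        cors = [np.corrcoef(eig, log2p1(expr.values)[i])[0, 1] for i in range(6)]
        assert np.mean(cors) > 0
        # global sign flip of the latent structure cannot break the contract
        expr2 = _expr(8 - L + 8)  # mirrored profiles
        eig2 = module_eigengene(expr2, labels).loc["ME1"].values
        cors2 = [np.corrcoef(eig2, log2p1(expr2.values)[i])[0, 1] for i in range(6)]
        assert np.mean(cors2) > 0

    def test_recovers_planted_factor(self):
        rng = np.random.default_rng(9)
        f = rng.normal(0, 1, 40)
        L = 4 + np.outer(np.linspace(0.6, 1.0, 10), f) + rng.normal(0, 0.3, (10, 40))
        expr = _expr(L)
        labels = pd.Series([1] * 10, index=expr.index)
        eig = module_eigengene(expr, labels).loc["ME1"].values
        assert abs(np.corrcoef(eig, f)[0, 1]) >= 0.95

    def test_unit_variance(self):
        rng = np.random.default_rng(10)
        expr = _expr(rng.normal(4, 1, (5, 15)))
        labels = pd.Series([1] * 5, index=expr.index)
        eig = module_eigengene(expr, labels).loc["ME1"]
        assert eig.std(ddof=1) == pytest.approx(1.0, rel=1e-10)


class TestModuleTrait:
    def _clin(self, cols, **traits):
        d = {"sample_id": cols, "group": "tumor"}
        d.update(traits)
        return pd.DataFrame(d)

    def test_trait_equal_to_eigengene_gives_r_one(self):
        rng = np.random.default_rng(11)
        eig = pd.DataFrame(rng.normal(0, 1, (1, 12)), index=["ME1"],
                           columns=[f"s{i}" for i in range(12)])
        clin = self._clin(eig.columns, lymph_node_count=eig.loc["ME1"].values)
        res = module_trait_correlation(eig, clin, traits=["lymph_node_count"])
        assert res["pearson_r"].iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_independent_pairs_rarely_correlate(self):
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            a, b = rng.normal(0, 1, 1000), rng.normal(0, 1, 1000)
            r = stats.pearsonr(a, b)[0]
            hits += abs(r) < 0.1
        assert hits >= 38

    def test_constant_trait_reports_zero_with_warning(self):
        eig = pd.DataFrame([[1.0, -1.0, 0.5]], index=["ME1"], columns=["a", "b", "c"])
        clin = self._clin(["a", "b", "c"], tissue_indicator=[1, 1, 1])
        with pytest.warns(UserWarning, match="constant"):
            res = module_trait_correlation(eig, clin, traits=["tissue_indicator"])
        assert res["pearson_r"].iloc[0] == 0.0 and res["p_value"].iloc[0] == 1.0

    def test_negative_sign_module_yields_negative_r(self):
        mod = ModulePlan(members=tuple(range(8)), loadings=(0.9,) * 8,
                         trait_name="lymph_node_count", trait_sign=-1)
        spec = CohortSpec(n_genes=12, n_case=40, n_control=40, baseline_mu=4.0,
                          sigma=0.2, modules=(mod,), seed=12)
        expr, clin = generate_cohort(spec)
        labels = pd.Series([1] * 8 + [0] * 4, index=expr.index)
        eig = module_eigengene(expr, labels)
        res = module_trait_correlation(eig, clin, traits=["lymph_node_count"])
        assert res["pearson_r"].iloc[0] < 0


class TestHubGene:
    def test_star_topology_center_is_hub(self):
        n = 5
        A = np.full((n, n), 0.1)
        A[0, :] = A[:, 0] = 0.9
        np.fill_diagonal(A, 0)
        adj = pd.DataFrame(A, index=[f"g{i}" for i in range(n)], columns=[f"g{i}" for i in range(n)])
        labels = pd.Series([1] * n, index=adj.index)
        assert hub_gene(adj, labels, 1) == "g0"

    def test_matches_row_sum_oracle(self):
        rng = np.random.default_rng(13)
        M = rng.uniform(0, 1, (4, 4))
        A = (M + M.T) / 2
        np.fill_diagonal(A, 0)
        adj = pd.DataFrame(A, index=list("abcd"), columns=list("abcd"))
        labels = pd.Series([1] * 4, index=adj.index)
        expected = adj.index[int(np.argmax(A.sum(axis=1)))]
        assert hub_gene(adj, labels, 1) == expected

    def test_trait_weighting_can_change_the_winner(self):
        A = np.array([[0, 0.9, 0.9], [0.9, 0, 0.5], [0.9, 0.5, 0]])
        adj = pd.DataFrame(A, index=list("xyz"), columns=list("xyz"))
        labels = pd.Series([1] * 3, index=adj.index)
        assert hub_gene(adj, labels, 1) == "x"  # plain kWithin winner
        cors = pd.Series({"x": 0.05, "y": 0.95, "z": 0.1})
        assert hub_gene(adj, labels, 1, trait_correlations=cors) == "y"

    def test_unknown_module_rejected(self):
        adj = pd.DataFrame(np.zeros((2, 2)), index=["a", "b"], columns=["a", "b"])
        labels = pd.Series([1, 1], index=adj.index)
        with pytest.raises(ValueError, match="unknown or empty"):
            hub_gene(adj, labels, 9)
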