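"""Weighted co-expression network: soft threshold, TOM, modules,
eigengenes, module-trait statistics, and hub extraction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from stalkscape import network
from stalkscape.network import (
    adjacency_matrix,
    compute_tom,
    detect_modules,
    gene_gene_correlation,
    hub_network,
    membership_significance,
    module_eigengene,
    module_trait,
    power_scan,
    scale_free_fit,
)


def brute_force_tom(a: np.ndarray) -> np.ndarray:
    """Triple-loop TOM oracle, straight from the definition."""
    n = a.shape[0]
    a = a.copy()
    np.fill_diagonal(a, 1.0)
    k = np.array([sum(a[i, u] for u in range(n) if u != i) for i in range(n)])
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            tom[i, j] = (l + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return tom


def correlated_triplet() -> pd.DataFrame:
    """Three genes with exact pairwise correlations 0.5, 0.2, 0.5."""
    u = np.array([1.0, -1.0, 0.0, 0.0]) / np.sqrt(2)
    v = np.array([0.0, 0.0, 1.0, -1.0]) / np.sqrt(2)
    w = np.array([1.0, 1.0, -1.0, -1.0]) / 2.0
    x = u
    y = 0.5 * u + np.sqrt(0.75) * v
    a13, a23 = 0.2, 0.5
    beta = (a23 - 0.5 * a13) / np.sqrt(0.75)
    z = a13 * u + beta * v + np.sqrt(1 - a13**2 - beta**2) * w
    return pd.DataFrame([x, y, z], index=["gx", "gy", "gz"])


class TestPowerScan:
    def test_connectivity_by_hand_on_printed_correlations(self):
        # |cor| off-diagonals (0.5, 0.2, 0.5) at beta=1: connectivities are
        # the adjacency row sums minus the diagonal: (0.7, 1.0, 0.7)
        x = correlated_triplet()
        c = network.correlation_matrix(x)
        np.testing.assert_allclose(
            c[np.triu_indices(3, 1)], [0.5, 0.2, 0.5], atol=1e-12
        )
        a = adjacency_matrix(x, beta=1)
        k = a.sum(axis=1) - 1.0
        np.testing.assert_allclose(k, [0.7, 1.0, 0.7], atol=1e-12)

    def test_planted_power_law_fits_scale_free(self):
        rng = np.random.default_rng(0)
        # degree sequence k ~ p(k) ∝ k^-2 over a decade
        k = (rng.pareto(1.0, 4000) + 1.0) * 1.0
        k = k[k < 1000]
        r2, slope = scale_free_fit(k)
        assert r2 > 0.9
        assert slope < 0

    def test_mean_connectivity_decreases_with_beta(self, module_sim):
        _, em, _, _, _ = module_sim
        scan = power_scan(em.data.iloc[:300], betas=(1, 2, 4, 6, 9))
        mk = scan.table["mean_k"].to_numpy()
        assert (np.diff(mk) < 0).all()

    def test_needs_four_samples(self):
        with pytest.raises(ValueError, match="4 samples"):
            power_scan(pd.DataFrame(np.ones((5, 3))))

    def test_constant_gene_warns_and_correlates_zero(self):
        x = pd.DataFrame(
            [[1.0, 1, 1, 1, 1], [0, 1, 2, 3, 4]], index=["const", "lin"]
        )
        with pytest.warns(UserWarning, match="constant"):
            c = network.correlation_matrix(x)
        assert c[0, 1] == 0.0 and c[0, 0] == 1.0


class TestTOM:
    def test_identity_adjacency_gives_identity(self):
        np.testing.assert_allclose(compute_tom(np.eye(6)), np.eye(6))

    def test_three_node_uniform_adjacency_by_formula(self):
        # all off-diagonals a: TOM = (a^2 + a) / (2a + 1 - a); a=0.5 -> 0.5
        a = np.full((3, 3), 0.5)
        np.fill_diagonal(a, 1.0)
        tom = compute_tom(a)
        expected = (0.25 + 0.5) / (2 * 0.5 + 1 - 0.5)
        assert expected == pytest.approx(0.5)
        np.testing.assert_allclose(tom[np.triu_indices(3, 1)], expected)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(0, 1, (20, 20))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        np.testing.assert_allclose(
            compute_tom(a), brute_force_tom(a), atol=1e-12, rtol=0
        )

    def test_bounded_and_symmetric_on_random_adjacencies(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            a = rng.uniform(0, 1, (15, 15))
            a = (a + a.T) / 2
            tom = compute_tom(a)
            assert (tom >= 0).all() and (tom <= 1).all()
            np.testing.assert_allclose(tom, tom.T)


def block_tom(sizes, intra=0.4, inter=0.01, seed=0):
    rng = np.random.default_rng(seed)
    n = sum(sizes)
    tom = rng.uniform(0, inter, (n, n))
    start = 0
    for s in sizes:
        tom[start : start + s, start : start + s] = rng.uniform(
            intra, intra + 0.2, (s, s)
        )
        start += s
    tom = (tom + tom.T) / 2
    np.fill_diagonal(tom, 1.0)
    return tom


class TestDetectModules:
    def test_two_planted_blocks_recovered_block_perfect(self):
        tom = block_tom([60, 55], seed=1)
        labels = detect_modules(tom, min_module_size=50)
        truth = np.array([1] * 60 + [2] * 55)
        assert adjusted_rand_score(truth, labels) == 1.0
        assert labels.max() == 2

    def test_small_block_goes_to_unassigned_pool(self):
        tom = block_tom([60, 20], seed=2)
        labels = detect_modules(tom, min_module_size=50)
        assert labels.max() == 1
        assert (labels.iloc[60:] == 0).all()

    def test_permutation_invariance(self):
        tom = block_tom([55, 50], seed=3)
        labels = detect_modules(tom)
        rng = np.random.default_rng(4)
        perm = rng.permutation(tom.shape[0])
        permuted = detect_modules(tom[np.ix_(perm, perm)])
        assert adjusted_rand_score(labels.iloc[perm], permuted) == 1.0

    def test_single_branch_single_module(self):
        tom = block_tom([70], seed=5)
        labels = detect_modules(tom, min_module_size=50)
        assert set(labels) == {1}

    def test_recovers_planted_expression_modules(self, module_sim):
        _, em, truth, _, _ = module_sim
        tom = compute_tom(adjacency_matrix(em.data, 9))
        labels = detect_modules(tom, gene_ids=em.data.index)
        assert adjusted_rand_score(truth, labels) > 0.9


class TestModuleEigengene:
    def test_identical_genes_share_profile(self):
        prof = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        x = pd.DataFrame([prof] * 4, index=list("abcd"))
        labels = pd.Series([1] * 4, index=list("abcd"))
        me = module_eigengene(x, labels)["ME1"]
        z = (prof - prof.mean()) / prof.std()
        np.testing.assert_allclose(me, z / np.linalg.norm(z), atol=1e-10)

    def test_sign_fixed_to_mean_profile(self):
        rng = np.random.default_rng(6)
        f = rng.normal(size=10)
        x = pd.DataFrame([f + rng.normal(0, 0.1, 10) for _ in range(20)])
        labels = pd.Series([1] * 20)
        me = module_eigengene(x, labels)["ME1"]
        zmean = x.sub(x.mean(1), axis=0).div(x.std(1, ddof=0), axis=0).mean(0)
        assert np.corrcoef(me, zmean)[0, 1] > 0

    def test_balanced_opposite_genes_tie_break_documented(self):
        p = np.array([1.0, -2.0, 3.0, -1.0, 0.5, -1.5])
        x = pd.DataFrame([p, p, -p, -p], index=list("abcd"))
        labels = pd.Series([1] * 4, index=list("abcd"))
        me = module_eigengene(x, labels)["ME1"]
        # near-zero mean profile: aligned with the first gene instead
        first = x.iloc[0]
        z = (first - first.mean()) / first.std()
        assert float(me @ z) > 0

    def test_recovers_planted_factor(self, module_sim):
        _, em, truth, factors, _ = module_sim
        me = module_eigengene(em.data, truth)
        r = np.corrcoef(me["ME1"], factors.iloc[0])[0, 1]
        assert abs(r) > 0.95

    def test_eigengene_is_leading_variance_direction(self):
        rng = np.random.default_rng(7)
        x = pd.DataFrame(rng.normal(size=(12, 9)))
        labels = pd.Series([1] * 12)
        me = module_eigengene(x, labels)["ME1"].to_numpy()
        z = ((x.sub(x.mean(1), axis=0)).div(x.std(1, ddof=0), axis=0)).to_numpy()
        # compare explained variance against the full eigendecomposition
        cov = z.T @ z
        evals, evecs = np.linalg.eigh(cov)
        lead = evecs[:, -1]
        assert abs(float(me @ lead)) == pytest.approx(1.0, abs=1e-8)

    def test_rank_zero_module_warns(self):
        x = pd.DataFrame(np.ones((3, 5)), index=list("abc"))
        labels = pd.Series([1] * 3, index=list("abc"))
        with pytest.warns(UserWarning, match="rank-0"):
            me = module_eigengene(x, labels)
        np.testing.assert_allclose(me["ME1"], 0.0)


class TestModuleTrait:
    def test_trait_equal_to_eigengene_r_one(self):
        rng = np.random.default_rng(8)
        me = pd.DataFrame({"ME1": rng.normal(size=19)})
        traits = pd.DataFrame({"length": me["ME1"] * 2 + 5})
        res = module_trait(me, traits).correlations
        assert res["r"].iloc[0] == pytest.approx(1.0)

    def test_printed_significance_consistent_with_r(self):
        # r = 0.91 at n = 19 gives a two-sided p in the 1e-8..1e-7 decade,
        # and the bracket over the rounding interval of r covers 8e-8
        def p_of(r, n=19):
            t = r * np.sqrt((n - 2) / (1 - r**2))
            return 2 * stats.t.sf(t, n - 2)

        p = p_of(0.91)
        assert 1e-8 < p < 1e-7
        assert p_of(0.915) < 8e-8 < p_of(0.905)

    def test_analytic_p_matches_library_for_simulated_me(self):
        rng = np.random.default_rng(10)
        me = pd.DataFrame({"ME1": rng.normal(size=19)})
        traits = pd.DataFrame({"t": rng.normal(size=19)})
        res = module_trait(me, traits).correlations.iloc[0]
        r, p = stats.pearsonr(me["ME1"], traits["t"])
        assert res["r"] == pytest.approx(r)
        assert res["p"] == pytest.approx(p)

    def test_too_few_samples_error(self):
        me = pd.DataFrame({"ME1": [1.0, 2.0]})
        with pytest.raises(ValueError, match="3 samples"):
            module_trait(me, pd.DataFrame({"t": [1.0, 2.0]}))

    def test_membership_and_significance_ranges(self, module_sim):
        _, em, truth, _, traits = module_sim
        me = module_eigengene(em.data, truth)
        sub = em.data.iloc[:50]
        mmgs = membership_significance(
            sub, me, truth.iloc[:50], traits["length_cm"]
        )
        assert mmgs["MM"].abs().max() <= 1.0 + 1e-12
        assert mmgs["GS"].abs().max() <= 1.0 + 1e-12
        # planted module members are strongly membership-correlated
        assert mmgs["MM"].median() > 0.8


class TestHubNetwork:
    def star_tom(self, n=30):
        tom = np.full((n, n), 0.05)
        tom[0, :] = tom[:, 0] = 0.6
        np.fill_diagonal(tom, 1.0)
        return tom

    def test_star_hub_has_max_connectivity(self):
        tom = self.star_tom()
        labels = pd.Series([1] * 30, index=[f"g{i}" for i in range(30)])
        hn = hub_network(tom, labels, 1, top_n=10)
        assert hn.nodes.index[0] == "g0"

    def test_top_n_equal_module_size_returns_module(self):
        tom = self.star_tom(20)
        labels = pd.Series([1] * 20, index=[f"g{i}" for i in range(20)])
        hn = hub_network(tom, labels, 1, top_n=20)
        assert set(hn.nodes.index) == set(labels.index)

    def test_oversized_top_n_warns(self):
        tom = self.star_tom(10)
        labels = pd.Series([1] * 10, index=[f"g{i}" for i in range(10)])
        with pytest.warns(UserWarning, match="whole module"):
            hn = hub_network(tom, labels, 1, top_n=100)
        assert len(hn.nodes) == 10

    def test_flagged_genes_always_included_and_reported(self):
        tom = self.star_tom(30)
        labels = pd.Series([1] * 30, index=[f"g{i}" for i in range(30)])
        hn = hub_network(tom, labels, 1, top_n=5, flagged_genes=["g29", "g0"])
        assert {"g29", "g0"} <= set(hn.nodes.index)
        assert hn.top_flagged == "g0"

    def test_planted_hub_ranks_first_in_simulation(self, module_sim):
        _, em, truth, _, _ = module_sim
        x = em.data.copy()
        # strengthen one member into a hub: pull it to the module mean
        members = truth.index[truth == 1]
        x.loc[members[0]] = x.loc[members].mean(axis=0)
        tom = compute_tom(adjacency_matrix(x, 9))
        hn = hub_network(tom, truth, 1, top_n=100)
        assert hn.nodes.index[0] == members[0]

    def test_networkx_round_trip(self):
        tom = self.star_tom(12)
        labels = pd.Series([1] * 12, index=[f"g{i}" for i in range(12)])
        g = hub_network(tom, labels, 1, top_n=6).to_networkx()
        assert g.number_of_nodes() >= 6


class TestGeneGeneCorrelation:
    def test_self_and_negation(self):
        rng = np.random.default_rng(11)
        prof = rng.normal(size=19)
        x = pd.DataFrame({"a": prof, "b": -prof}).T
        res = gene_gene_correlation(x, ["a"], ["a", "b"])
        assert res.set_index("gene_b")["r"]["a"] == pytest.approx(1.0)
        assert res.set_index("gene_b")["r"]["b"] == pytest.approx(-1.0)

    def test_coregulated_pair_strongly_correlated(self, module_sim):
        _, em, truth, _, _ = module_sim
        members = truth.index[truth == 1][:4]
        res = gene_gene_correlation(em.data, members[:2], members[2:])
        assert (res["r"] > 0.5).all()
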