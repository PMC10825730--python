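"""Coexpression network core: adjacency, TOM, modules, eigengenes, scores."""

import numpy as np
import pandas as pd
import pytest

from methylpanel import network
from methylpanel.collapse import GeneMatrix


def _gm(values, gene_ids=None, sample_ids=None):
    n, s = values.shape
    gene_ids = gene_ids or [f"G{i:03d}" for i in range(n)]
    sample_ids = sample_ids or [f"s{i}" for i in range(s)]
    frame = pd.DataFrame(values, index=gene_ids, columns=sample_ids)
    return GeneMatrix(values=frame,
                      chosen_probe=pd.Series(gene_ids, index=gene_ids))


def _planted_blocks(rng, sizes, n_samples=60, loading=0.95, n_noise=0):
    rows = []
    for size in sizes:
        factor = rng.standard_normal(n_samples)
        for _ in range(size):
            rows.append(loading * factor +
                        np.sqrt(1 - loading ** 2) * rng.standard_normal(n_samples))
    for _ in range(n_noise):
        rows.append(rng.standard_normal(n_samples))
    return np.vstack(rows)


def brute_force_tom(adj):
    n = adj.shape[0]
    a0 = adj.copy()
    np.fill_diagonal(a0, 0.0)
    k = a0.sum(axis=1)
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a0[i, u] * a0[u, j] for u in range(n)
                         if u != i and u != j)
            tom[i, j] = (shared + a0[i, j]) / (min(k[i], k[j]) + 1 - a0[i, j])
    return tom


class TestBuildNetwork:
    def test_power_six_of_half(self):
        rng = np.random.default_rng(0)
        n = 40
        x = rng.standard_normal(n)
        y_target = -0.5
        # construct an exact correlation of -0.5 via Gram-Schmidt
        z = rng.standard_normal(n)
        x0 = (x - x.mean()) / x.std()
        z0 = z - z.mean()
        z0 -= (z0 @ x0) / (x0 @ x0) * x0
        z0 /= z0.std()
        y = y_target * x0 + np.sqrt(1 - y_target ** 2) * z0
        gm = _gm(np.vstack([x0, y]))
        net = network.build_network(gm, power=6)
        assert net.adjacency[0, 1] == pytest.approx(0.5 ** 6, abs=1e-12)

    def test_constant_gene_warns_and_zeroes(self):
        vals = np.vstack([np.ones(10), np.arange(10.0), np.arange(10.0)[::-1]])
        with pytest.warns(UserWarning):
            net = network.build_network(_gm(vals), power=2)
        assert net.adjacency[0, 1] == 0.0
        assert net.adjacency[0, 0] == 1.0

    def test_tom_matches_brute_force(self):
        rng = np.random.default_rng(1)
        gm = _gm(rng.standard_normal((10, 25)))
        net = network.build_network(gm, power=6)
        expected = brute_force_tom(net.adjacency)
        np.testing.assert_allclose(net.tom, expected, atol=1e-12)

    def test_matrix_properties(self):
        rng = np.random.default_rng(2)
        net = network.build_network(_gm(rng.standard_normal((15, 30))), 6)
        for mat in (net.adjacency, net.tom):
            assert np.allclose(mat, mat.T)
            assert np.allclose(np.diag(mat), 1.0)
            assert mat.min() >= 0 and mat.max() <= 1

    def test_isolated_pair_zero_overlap(self):
        # two genes uncorrelated with everything share no neighborhood
        vals = np.zeros((4, 8))
        vals[0] = [1, -1, 1, -1, 1, -1, 1, -1]
        vals[1] = [1, 1, -1, -1, 1, 1, -1, -1]
        vals[2] = [1, -1, -1, 1, 1, -1, -1, 1]
        vals[3] = [1, 1, 1, 1, -1, -1, -1, -1]
        net = network.build_network(_gm(vals), power=6)
        assert net.tom[0, 1] == pytest.approx(0.0, abs=1e-12)


class TestSoftThreshold:
    def test_fallback_when_nothing_fits(self):
        rng = np.random.default_rng(3)
        gm = _gm(rng.standard_normal((40, 20)))
        power, table = network.pick_soft_threshold(
            gm, candidate_powers=(1,), r2_threshold=0.999)
        assert power == 6
        assert len(table) == 1

    def test_single_candidate_meeting_threshold(self):
        rng = np.random.default_rng(4)
        gm = _gm(_planted_blocks(rng, [30], n_samples=50, loading=0.9,
                                 n_noise=30))
        power, table = network.pick_soft_threshold(
            gm, candidate_powers=(6,), r2_threshold=0.0)
        assert power == 6

    def test_exact_power_law_degree_sequence(self):
        # k proportional to 1/rank follows p(k) ~ k^-2 exactly
        k = 1000.0 / np.arange(1, 401)
        r2, slope = network.scale_free_fit(k, n_bins=10)
        assert r2 > 0.95
        assert slope < 0

    def test_increasing_law_gets_negative_r2(self):
        rng = np.random.default_rng(5)
        # k = u^(1/3) has density 3k^2, increasing: slope > 0, signed R2 < 0
        k = rng.random(400) ** (1 / 3)
        r2, slope = network.scale_free_fit(k, n_bins=8)
        assert slope > 0
        assert r2 <= 0

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            network.scale_free_fit(np.ones(5), n_bins=10)


class TestDetectModules:
    def test_two_planted_blocks_recovered(self):
        rng = np.random.default_rng(6)
        vals = _planted_blocks(rng, [20, 20], loading=0.98)
        net = network.build_network(_gm(vals), power=6)
        labels = network.detect_modules(net, min_size=5, cut_height=0.9)
        assert set(labels[:20]) == {labels[0]}
        assert set(labels[20:]) == {labels[20]}
        assert labels[0] != labels[20]
        assert sorted(set(labels)) == [1, 2]

    def test_independent_genes_all_unassigned(self):
        rng = np.random.default_rng(7)
        vals = rng.standard_normal((40, 200))
        net = network.build_network(_gm(vals), power=6)
        labels = network.detect_modules(net, min_size=5, cut_height=0.2)
        assert (labels == 0).all()

    def test_single_block_single_module(self):
        rng = np.random.default_rng(8)
        vals = _planted_blocks(rng, [25], loading=0.97)
        net = network.build_network(_gm(vals), power=6)
        labels = network.detect_modules(net, min_size=5, cut_height=0.9)
        assert set(labels) == {1}

    def test_label_one_is_largest(self):
        rng = np.random.default_rng(9)
        vals = _planted_blocks(rng, [30, 10], loading=0.98)
        net = network.build_network(_gm(vals), power=6)
        labels = network.detect_modules(net, min_size=5, cut_height=0.9)
        sizes = pd.Series(labels).value_counts()
        assert sizes[1] >= sizes[2]

    def test_permutation_invariance(self):
        rng = np.random.default_rng(10)
        vals = _planted_blocks(rng, [15, 15], n_noise=10, loading=0.95)
        perm = rng.permutation(vals.shape[0])
        net1 = network.build_network(_gm(vals), power=6)
        net2 = network.build_network(_gm(vals[perm]), power=6)
        lab1 = network.detect_modules(net1, min_size=5, cut_height=0.9)
        lab2 = network.detect_modules(net2, min_size=5, cut_height=0.9)
        # same partition up to relabeling
        for i in range(len(perm)):
            for j in range(len(perm)):
                assert (lab1[perm[i]] == lab1[perm[j]]) == (lab2[i] == lab2[j]) \
                    or {lab1[perm[i]], lab1[perm[j]]} <= {0} \
                    or (lab1[perm[i]] == 0) == (lab2[i] == 0)
        assert (lab1[perm] > 0).sum() == (lab2 > 0).sum()

    def test_min_size_validation(self):
        rng = np.random.default_rng(11)
        net = network.build_network(_gm(rng.standard_normal((10, 10))), 2)
        with pytest.raises(ValueError):
            network.detect_modules(net, min_size=1)


class TestModuleEigengene:
    def test_identical_genes_give_common_profile(self):
        profile = np.array([1.0, -2.0, 0.5, 3.0, -1.0, 0.2])
        vals = np.tile(profile, (5, 1))
        gm = _gm(vals)
        eig, ve = network.module_eigengene(gm, np.ones(5, dtype=int))
        e = eig[1].to_numpy()
        zp = (profile - profile.mean()) / profile.std()
        assert np.linalg.norm(e) == pytest.approx(1.0)
        cor = np.corrcoef(e, zp)[0, 1]
        assert cor == pytest.approx(1.0, abs=1e-10)
        assert ve[1] == pytest.approx(1.0)

    def test_variance_explained_matches_eigendecomposition(self):
        rng = np.random.default_rng(12)
        vals = rng.standard_normal((10, 30))
        gm = _gm(vals)
        eig, ve = network.module_eigengene(gm, np.ones(10, dtype=int))
        z = (vals - vals.mean(axis=1, keepdims=True)) / \
            vals.std(axis=1, keepdims=True)
        evals = np.linalg.eigvalsh(z @ z.T)
        assert ve[1] == pytest.approx(evals[-1] / evals.sum(), abs=1e-10)
        assert np.linalg.norm(eig[1]) == pytest.approx(1.0)

    def test_positive_orientation(self):
        rng = np.random.default_rng(13)
        vals = _planted_blocks(rng, [8], n_samples=40, loading=0.9)
        gm = _gm(vals)
        eig, _ = network.module_eigengene(gm, np.ones(8, dtype=int))
        z = (vals - vals.mean(axis=1, keepdims=True)) / \
            vals.std(axis=1, keepdims=True)
        assert np.dot(eig[1], z.mean(axis=0)) > 0


class TestModuleSignificance:
    def test_strong_signal_small_p(self):
        rng = np.random.default_rng(14)
        n = 150
        y = (rng.random(n) < 0.35).astype(float)
        eig = y + rng.normal(0, 0.25, n)
        covs = pd.DataFrame({"age": rng.normal(65, 10, n),
                             "sex": rng.choice(["F", "M"], n),
                             "epithelial": rng.beta(4, 6, n)})
        p = network.module_significance(eig, y, covs)
        assert p < 1e-6

    def test_pure_confounder_not_significant(self):
        # eigengene driven by age alone; diagnosis depends on age too
        rng = np.random.default_rng(15)
        n = 200
        age = rng.normal(65, 10, n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(age - 65) / 5))).astype(float)
        ps = []
        for _ in range(50):
            eig = (age - age.mean()) / age.std() + rng.normal(0, 0.5, n)
            covs = pd.DataFrame({"age": age,
                                 "sex": rng.choice(["F", "M"], n),
                                 "epithelial": rng.beta(4, 6, n)})
            ps.append(network.module_significance(eig, y, covs))
        # adjusted for age the eigengene carries nothing: p roughly uniform
        assert np.mean(np.array(ps) < 0.05) < 0.2
        assert np.median(ps) > 0.2

    def test_separation_handled(self):
        rng = np.random.default_rng(16)
        n = 60
        y = np.repeat([0.0, 1.0], n // 2)
        eig = np.where(y == 1, 2.0, -2.0) + rng.normal(0, 1e-6, n)
        covs = pd.DataFrame({"age": rng.normal(65, 10, n),
                             "sex": rng.choice(["F", "M"], n),
                             "epithelial": rng.beta(4, 6, n)})
        with pytest.warns(UserWarning):
            p = network.module_significance(eig, y, covs)
        assert 0 < p < 0.05

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            network.module_significance(
                np.zeros(10), np.zeros(10),
                pd.DataFrame({"age": np.zeros(10), "sex": ["F"] * 10,
                              "epithelial": np.zeros(10)}))


class TestGeneImportance:
    def _net(self, rng, sizes=(10,), loading=0.9):
        vals = _planted_blocks(rng, list(sizes), n_samples=50,
                               loading=loading)
        return network.build_network(_gm(vals), power=6)

    def test_hub_gets_module_p_value(self):
        rng = np.random.default_rng(17)
        net = self._net(rng)
        labels = np.ones(10, dtype=int)
        scores = network.gene_importance(net, labels, {1: 0.01})
        assert scores.min() == pytest.approx(0.01, abs=1e-15)
        a0 = net.adjacency.copy()
        np.fill_diagonal(a0, 0.0)
        hub = int(np.argmax(a0.sum(axis=1)))
        assert scores.iloc[hub] == scores.min()
        assert (scores.drop(scores.index[hub]) > 0.01).all()

    def test_half_connectivity_doubles_score(self):
        adj = np.eye(3)
        adj[0, 1] = adj[1, 0] = 0.4
        adj[0, 2] = adj[2, 0] = 0.4
        adj[1, 2] = adj[2, 1] = 0.0
        net = network.Network(adjacency=adj, tom=adj, power=1,
                              gene_ids=pd.Index(["a", "b", "c"]))
        scores = network.gene_importance(net, np.ones(3, dtype=int),
                                         {1: 0.01})
        assert scores["a"] == pytest.approx(0.01)      # hub, k = 0.8
        assert scores["b"] == pytest.approx(0.02)      # k-hat = 0.5
        assert scores["c"] == pytest.approx(0.02)

    def test_unassigned_default_200(self):
        rng = np.random.default_rng(18)
        net = self._net(rng, sizes=(6,))
        labels = np.array([1] * 6 + [0] * 4)
        vals = np.vstack([_planted_blocks(rng, [6], n_samples=50),
                          rng.standard_normal((4, 50))])
        net = network.build_network(_gm(vals), power=6)
        scores = network.gene_importance(net, labels, {1: 0.2})
        assert (scores.iloc[6:] == 200.0).all()

    def test_missing_module_p_rejected(self):
        rng = np.random.default_rng(19)
        net = self._net(rng)
        with pytest.raises(ValueError):
            network.gene_importance(net, np.ones(10, dtype=int), {})
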