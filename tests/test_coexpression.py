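import numpy as np
import pandas as pd
import pytest

from oracles import tom_brute_force

from uprnet import coexpression as cx
from uprnet.exceptions import DesignError, ParameterError


def _df(mat, prefix="g"):
    idx = [f"{prefix}{i}" for i in range(mat.shape[0])]
    return pd.DataFrame(mat, index=idx, columns=[f"c{j}" for j in range(mat.shape[1])])


class TestSignedAdjacency:
    def test_perfect_correlation_maps_to_one(self):
        base = np.arange(10.0)
        X = _df(np.vstack([base, base * 2 + 1]))
        a = cx.signed_adjacency(X, cx.NetworkParams(beta=18))
        assert a.iloc[0, 1] == pytest.approx(1.0)

    def test_perfect_anticorrelation_maps_to_zero(self):
        base = np.arange(10.0)
        X = _df(np.vstack([base, -base]))
        a = cx.signed_adjacency(X, cx.NetworkParams(beta=18))
        assert a.iloc[0, 1] == pytest.approx(0.0)

    def test_beta_one_uncorrelated_near_half(self):
        rng = np.random.default_rng(0)
        X = _df(rng.normal(size=(2, 2000)))
        a = cx.signed_adjacency(X, cx.NetworkParams(beta=1))
        assert a.iloc[0, 1] == pytest.approx(0.5, abs=0.05)

    def test_raising_beta_never_increases_adjacency(self):
        rng = np.random.default_rng(1)
        X = _df(rng.normal(size=(10, 30)))
        a1 = cx.signed_adjacency(X, cx.NetworkParams(beta=6)).to_numpy()
        a2 = cx.signed_adjacency(X, cx.NetworkParams(beta=18)).to_numpy()
        off = ~np.eye(10, dtype=bool)
        assert (a2[off] <= a1[off] + 1e-12).all()

    def test_too_few_conditions_raise(self):
        X = _df(np.ones((3, 3)))
        with pytest.raises(DesignError):
            cx.signed_adjacency(X)

    def test_zero_variance_genes_dropped_with_warning(self):
        rng = np.random.default_rng(2)
        mat = rng.normal(size=(4, 10))
        mat[2] = 5.0
        with pytest.warns(UserWarning):
            a = cx.signed_adjacency(_df(mat))
        assert a.shape == (3, 3)

    def test_spearman_matches_scipy(self):
        from scipy.stats import spearmanr

        rng = np.random.default_rng(3)
        X = _df(rng.normal(size=(6, 25)))
        a = cx.signed_adjacency(X, cx.NetworkParams(beta=1)).to_numpy()
        rho = spearmanr(X.to_numpy(), axis=1)[0]
        assert np.allclose(a, (1 + rho) / 2, atol=1e-12)


class TestTOM:
    def test_two_genes_full_adjacency(self):
        tom = cx.tom_similarity(np.array([[1.0, 1.0], [1.0, 1.0]]))
        assert tom[0, 1] == pytest.approx(1.0)

    def test_zero_adjacency_gives_zero_offdiagonal(self):
        tom = cx.tom_similarity(np.eye(5))
        assert np.allclose(tom - np.eye(5), 0.0)

    def test_asymmetric_input_rejected(self):
        bad = np.array([[1.0, 0.2], [0.4, 1.0]])
        with pytest.raises(ParameterError):
            cx.tom_similarity(bad)

    @pytest.mark.parametrize("n", [5, 20, 37])
    def test_matches_triple_loop_brute_force(self, n):
        rng = np.random.default_rng(n)
        a = rng.uniform(size=(n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        assert np.max(np.abs(cx.tom_similarity(a) - tom_brute_force(a))) < 1e-12


class TestDetectModules:
    def test_two_perfect_blocks_recovered(self):
        rng = np.random.default_rng(4)
        profile = rng.normal(size=30)
        X = _df(np.vstack([np.tile(profile, (30, 1)) + rng.normal(0, 1e-6, (30, 30)),
                           np.tile(-profile, (30, 1)) + rng.normal(0, 1e-6, (30, 30))]))
        tom = cx.tom_similarity(cx.signed_adjacency(X))
        labels, _ = cx.detect_modules(tom, cx.NetworkParams(min_module_size=25))
        groups = labels.groupby(labels).groups
        assert len(set(labels)) == 2
        sizes = sorted(len(v) for v in groups.values())
        assert sizes == [30, 30]
        # the two blocks are exactly the planted halves
        first = set(labels.index[:30])
        assert {frozenset(v) for v in groups.values()} == {
            frozenset(first), frozenset(set(labels.index) - first)}

    def test_independent_genes_all_unassigned(self):
        rng = np.random.default_rng(5)
        X = _df(rng.normal(size=(20, 30)))
        tom = cx.tom_similarity(cx.signed_adjacency(X))
        labels, _ = cx.detect_modules(tom, cx.NetworkParams(min_module_size=25))
        assert (labels == cx.UNASSIGNED).all()

    def test_largest_module_is_turquoise(self):
        from uprnet.simulate import SimulationConfig, ModuleSpec, simulate_lfc_matrix

        cfg = SimulationConfig(seed=3, module_spec=(
            ModuleSpec("A", 60, 2.0, 0.3), ModuleSpec("B", 30, 2.0, 0.3)),
            n_background_network=40)
        X, truth = simulate_lfc_matrix(cfg)
        tom = cx.tom_similarity(cx.signed_adjacency(X))
        labels, _ = cx.detect_modules(tom)
        sizes = labels[labels != cx.UNASSIGNED].value_counts()
        assert sizes.index[0] == "turquoise"
        assert sizes.iloc[0] >= sizes.iloc[-1]

    def test_planted_module_recovery_ari(self):
        from sklearn.metrics import adjusted_rand_score

        from uprnet.simulate import SimulationConfig, simulate_lfc_matrix

        cfg = SimulationConfig(seed=3)
        X, truth = simulate_lfc_matrix(cfg)
        tom = cx.tom_similarity(cx.signed_adjacency(X))
        labels, _ = cx.detect_modules(tom)
        labels = cx.merge_modules(X, labels)
        ari = adjusted_rand_score([truth.module_of_gene[g] for g in X.index],
                                  [labels[g] for g in X.index])
        assert ari >= 0.8

    def test_permuting_genes_permutes_labels_consistently(self):
        from uprnet.simulate import SimulationConfig, simulate_lfc_matrix

        cfg = SimulationConfig(seed=9, n_background_network=30)
        X, _ = simulate_lfc_matrix(cfg)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(X))
        Xp = X.iloc[perm]
        l1, _ = cx.detect_modules(cx.tom_similarity(cx.signed_adjacency(X)))
        l2, _ = cx.detect_modules(cx.tom_similarity(cx.signed_adjacency(Xp)))
        # same partition of gene ids, independent of row order
        p1 = {}
        p2 = {}
        for g in X.index:
            p1.setdefault(l1[g], set()).add(g)
            p2.setdefault(l2[g], set()).add(g)
        assert ({frozenset(v) for v in p1.values()}
                == {frozenset(v) for v in p2.values()})


class TestEigengene:
    def test_identical_profiles_fully_explained(self):
        profile = np.sin(np.arange(12))
        X = _df(np.tile(profile, (5, 1)))
        modules = pd.Series(["m"] * 5, index=X.index)
        E, varexp = cx.module_eigengene(X, modules)
        assert varexp["m"] == pytest.approx(1.0)
        z = (profile - profile.mean()) / profile.std(ddof=1)
        corr = np.corrcoef(E.loc["m"], z)[0, 1]
        assert abs(corr) == pytest.approx(1.0)
        assert np.linalg.norm(E.loc["m"]) == pytest.approx(1.0)

    def test_sign_oriented_to_mean_profile(self):
        rng = np.random.default_rng(6)
        X = _df(rng.normal(size=(8, 15)) + np.linspace(-2, 2, 15))
        modules = pd.Series(["m"] * 8, index=X.index)
        E, _ = cx.module_eigengene(X, modules)
        z = X.sub(X.mean(axis=1), axis=0).div(X.std(axis=1, ddof=1), axis=0)
        assert np.dot(E.loc["m"], z.mean(axis=0)) >= 0
        En, _ = cx.module_eigengene(-X, modules)
        zn = (-X).sub((-X).mean(axis=1), axis=0).div(X.std(axis=1, ddof=1), axis=0)
        assert np.dot(En.loc["m"], zn.mean(axis=0)) >= 0

    def test_latent_profile_recovered(self):
        rng = np.random.default_rng(7)
        latent = rng.normal(size=30)
        X = _df(2.0 * latent + rng.normal(0, 0.3, (50, 30)))
        modules = pd.Series(["m"] * 50, index=X.index)
        E, _ = cx.module_eigengene(X, modules)
        assert abs(np.corrcoef(E.loc["m"], latent)[0, 1]) >= 0.9


class TestMergeModules:
    def _planted(self, latents, sizes, noise=0.05, seed=0):
        rng = np.random.default_rng(seed)
        rows, labels = [], []
        for latent, size, name in zip(latents, sizes, "abcdef"):
            for _ in range(size):
                rows.append(latent + rng.normal(0, noise, len(latent)))
                labels.append(name)
        X = _df(np.array(rows))
        return X, pd.Series(labels, index=X.index)

    def test_identical_eigengenes_merge(self):
        rng = np.random.default_rng(8)
        latent = rng.normal(size=20)
        X, modules = self._planted([latent, latent], [10, 10])
        merged = cx.merge_modules(X, modules, 0.05)
        assert len(set(merged)) == 1

    def test_orthogonal_eigengenes_unchanged(self):
        rng = np.random.default_rng(9)
        l1 = rng.normal(size=40)
        l2 = rng.normal(size=40)
        l2 -= l2 @ l1 / (l1 @ l1) * l1
        X, modules = self._planted([l1, l2], [10, 10])
        merged = cx.merge_modules(X, modules, 0.05)
        assert len(set(merged)) == 2

    def test_three_similar_modules_collapse_regardless_of_labeling(self):
        rng = np.random.default_rng(10)
        latent = rng.normal(size=25)
        X, modules = self._planted([latent, latent, latent], [8, 6, 4])
        for perm_seed in range(3):
            order = np.random.default_rng(perm_seed).permutation(len(X))
            merged = cx.merge_modules(X.iloc[order], modules.iloc[order], 0.05)
            assert len(set(merged)) == 1


class TestExportNetwork:
    def _tom(self, n, seed=0):
        rng = np.random.default_rng(seed)
        t = rng.uniform(size=(n, n))
        t = (t + t.T) / 2
        np.fill_diagonal(t, 1.0)
        genes = [f"g{i}" for i in range(n)]
        return pd.DataFrame(t, index=genes, columns=genes)

    def test_cutoff_above_one_empty(self):
        tom = self._tom(6)
        modules = pd.Series(["m"] * 6, index=tom.index)
        edges, nodes = cx.export_network(tom, modules, edge_weight_cutoff=1.1)
        assert len(edges) == 0 and len(nodes) == 6

    def test_cutoff_zero_gives_complete_graph(self):
        tom = self._tom(7)
        modules = pd.Series(["m"] * 7, index=tom.index)
        edges, _ = cx.export_network(tom, modules, edge_weight_cutoff=0.0)
        assert len(edges) == 7 * 6 // 2

    def test_edge_count_matches_brute_force_threshold(self):
        tom = self._tom(15, seed=4)
        modules = pd.Series(["m"] * 15, index=tom.index)
        for cutoff in (0.2, 0.5, 0.8):
            edges, _ = cx.export_network(tom, modules, cutoff)
            t = tom.to_numpy()
            want = sum(1 for i in range(15) for j in range(i + 1, 15)
                       if t[i, j] >= cutoff)
            assert len(edges) == want
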