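import numpy as np
import pandas as pd
import pytest

import ecoassembly as ea
from ecoassembly.core import ValidationError

from conftest import community_from_array, oracle_beta_mntd


class TestNicheDistance:
    @staticmethod
    def _meta(matrix, elevations):
        tab = pd.DataFrame({
            "elevation": elevations,
            "slope": np.linspace(5, 30, len(matrix.sites)),
            "canopy": 0.5, "evi": 0.3, "near_dist": 100.0,
        }, index=matrix.sites)
        return ea.SiteMetadata(tab)

    def test_identical_profiles_zero_distance(self):
        m = community_from_array([[2, 2, 1], [5, 5, 0], [1, 1, 3]])
        meta = self._meta(m, [400, 600, 800])
        d = ea.niche_distance(m, meta, factors=("elevation", "slope"))
        assert d.iloc[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_confined_species_distance_is_standardized_gap(self):
        # sp0 only at the lowest site, sp1 only at the highest
        m = community_from_array([[4, 0], [0, 0], [0, 4]],
                                 sites=["lo", "mid", "hi"])
        meta = self._meta(m, [400.0, 600.0, 800.0])
        d = ea.niche_distance(m, meta, factors=("elevation",))
        z = (np.array([400, 600, 800]) - 600) / np.std([400, 600, 800])
        assert d.loc["sp0", "sp1"] == pytest.approx(abs(z[2] - z[0]))

    def test_symmetric_nonnegative_zero_diagonal(self, scenario_small):
        d = ea.niche_distance(scenario_small.matrix, scenario_small.meta)
        a = d.to_numpy()
        assert np.allclose(a, a.T)
        assert (a >= 0).all()
        assert np.allclose(np.diag(a), 0)


class TestMantelCorrelogram:
    def test_perfect_signal_positive_at_short_distances(self, scenario_small):
        tree = scenario_small.tree
        pdm = pd.DataFrame(tree.patristic, index=tree.tip_labels,
                           columns=tree.tip_labels)
        mc = ea.mantel_correlogram(pdm, pdm, permutations=199, seed=0)
        first = mc.classes.iloc[0]
        assert first["r"] > 0
        assert first["p"] < 0.05

    def test_zero_permutations_rejected(self, scenario_small):
        tree = scenario_small.tree
        pdm = pd.DataFrame(tree.patristic, index=tree.tip_labels,
                           columns=tree.tip_labels)
        with pytest.raises(ValidationError):
            ea.mantel_correlogram(pdm, pdm, permutations=0)

    def test_conserved_trait_shows_signal(self, scenario_small):
        """Brownian trait differences correlate with short phylo distances."""
        tree = scenario_small.tree
        pdm = pd.DataFrame(tree.patristic, index=tree.tip_labels,
                           columns=tree.tip_labels)
        tvals = scenario_small.traits.to_numpy()
        td = pd.DataFrame(np.abs(tvals[:, None] - tvals[None, :]),
                          index=tree.tip_labels, columns=tree.tip_labels)
        mc = ea.mantel_correlogram(pdm, td, permutations=199, seed=1)
        assert mc.classes.iloc[0]["r"] > 0
        assert mc.classes.iloc[0]["p"] < 0.05


class TestBetaMNTD:
    def test_identical_species_sets_zero(self, small_tree):
        assert ea.beta_mntd(small_tree, [1, 2, 0], [5, 1, 0]) == 0.0

    def test_single_species_pair_is_patristic_distance(self, small_tree):
        assert ea.beta_mntd(small_tree, [1, 0, 0], [0, 0, 3]) == \
            pytest.approx(4.0)

    def test_empty_community_rejected(self, small_tree):
        with pytest.raises(ValidationError):
            ea.beta_mntd(small_tree, [0, 0, 0], [1, 0, 0])

    @pytest.mark.parametrize("weighted", [True, False])
    def test_matches_double_loop_oracle(self, weighted, rng):
        tree = ea.simulate_tree(10, seed=8)
        for _ in range(15):
            x = rng.integers(0, 5, 10)
            y = rng.integers(0, 5, 10)
            if x.sum() == 0 or y.sum() == 0:
                continue
            got = ea.beta_mntd(tree, x, y, abundance_weighted=weighted)
            exp = oracle_beta_mntd(tree, x, y, tree.tip_labels,
                                   weighted=weighted)
            assert got == pytest.approx(exp, abs=1e-12)

    def test_pairwise_matrix_matches_single_pair_calls(self, scenario_small):
        m = scenario_small.matrix.subset_sites(scenario_small.matrix.sites[:6])
        tree = scenario_small.tree
        res = ea.beta_mntd_matrix(tree, m)
        x = m.counts[tree.tip_labels].to_numpy()
        for i in range(6):
            for j in range(i + 1, 6):
                assert res.data.iloc[i, j] == pytest.approx(
                    ea.beta_mntd(tree, x[i], x[j]), abs=1e-12)


class TestBetaNTI:
    def test_star_tree_degenerate_null(self, caplog):
        star = ea.tree_from_string(
            "(" + ",".join(f"t{i}:1" for i in range(8)) + ");")
        m = community_from_array(np.array([[3, 1, 0, 0, 2, 0, 1, 0],
                                           [0, 2, 1, 4, 0, 1, 0, 2],
                                           [1, 0, 3, 0, 1, 0, 2, 1]]),
                                 species=star.tip_labels)
        with caplog.at_level("WARNING", logger="ecoassembly"):
            res = ea.beta_nti(star, m, reps=99, seed=0)
        assert np.isnan(res.pair_values()).all()

    def test_deterministic_given_seed(self, scenario_small):
        m = scenario_small.matrix.subset_sites(scenario_small.matrix.sites[:8])
        a = ea.beta_nti(scenario_small.tree, m, reps=99, seed=5)
        b = ea.beta_nti(scenario_small.tree, m, reps=99, seed=5)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_branch_length_scale_invariance(self, scenario_small):
        import dendropy

        m = scenario_small.matrix.subset_sites(scenario_small.matrix.sites[:8])
        nwk = scenario_small.tree.tree.as_string(schema="newick")
        t2 = dendropy.Tree.get(data=nwk, schema="newick",
                               preserve_underscores=True)
        for node in t2.preorder_node_iter():
            if node.edge.length is not None:
                node.edge.length *= 3.5
        scaled = ea.Phylogeny(t2)
        a = ea.beta_nti(scenario_small.tree, m, reps=99, seed=5)
        b = ea.beta_nti(scaled, m, reps=99, seed=5)
        assert np.allclose(a.pair_values(), b.pair_values(), atol=1e-9)

    def test_too_few_reps_rejected(self, scenario_small):
        with pytest.raises(ValidationError):
            ea.beta_nti(scenario_small.tree, scenario_small.matrix, reps=10)


class TestRCBray:
    def test_bounds_and_symmetry(self, scenario_small):
        m = scenario_small.matrix.subset_sites(scenario_small.matrix.sites[:10])
        res = ea.rc_bray(m, reps=99, seed=0)
        a = res.data.to_numpy()
        off = a[np.triu_indices(10, 1)]
        assert (np.abs(off) <= 1).all()
        assert np.allclose(a, a.T, equal_nan=True)

    def test_extreme_divergence_scores_plus_one(self, rng):
        """Two sites far more dissimilar than any richness/abundance-
        preserving rearrangement of the pool get RCbray = +1."""
        n_sp = 50
        fillers = np.zeros((10, n_sp), dtype=int)
        fillers[:, :30] = rng.integers(1, 10, (10, 30))
        # the focal pair splits the pool into disjoint halves; each null
        # community redraws 25 of 50 species, so null pairs always overlap
        # heavily and are strictly less dissimilar than the observed 1.0
        s1 = np.r_[np.full(25, 4), np.zeros(25, dtype=int)]
        s2 = np.r_[np.zeros(25, dtype=int), np.full(25, 4)]
        counts = np.vstack([s1, s2, fillers])
        m = community_from_array(counts)
        res = ea.rc_bray(m, reps=199, seed=1)
        assert res.data.iloc[0, 1] == pytest.approx(1.0)

    def test_same_pool_sites_rarely_extreme(self, rng):
        w = rng.lognormal(0, 1.2, 120)
        w /= w.sum()
        counts = rng.multinomial(50, w, size=16)
        m = community_from_array(counts)
        v = ea.rc_bray(m, reps=299, seed=2).pair_values()
        assert np.mean(np.abs(v) <= 0.95) >= 0.9


class TestClassification:
    @pytest.mark.parametrize("bnti,rc,expected", [
        (3.0, 0.0, "heterogeneous_selection"),
        (-2.5, 0.0, "homogeneous_selection"),
        (0.0, 0.99, "dispersal_limitation"),
        (1.5, -0.99, "homogenizing_dispersal"),
        (0.5, 0.5, "undominated"),
        (2.0, 0.96, "dispersal_limitation"),  # boundary: |βNTI| ≤ 2
    ])
    def test_threshold_rules(self, bnti, rc, expected):
        assert ea.classify_pair(bnti, rc) == expected

    def test_fractions_partition(self, scenario_small):
        m = scenario_small.matrix
        bnti = ea.beta_nti(scenario_small.tree, m, reps=99, seed=1)
        rc = ea.rc_bray(m, reps=99, seed=1)
        out = ea.classify_processes(bnti, rc,
                                    groups=scenario_small.meta.bands())
        import ecoassembly.assembly as asm
        sums = out[list(asm.PROCESSES)].sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-12)


class TestCompareBands:
    def _pairwise(self, values, sites):
        n = len(sites)
        a = np.full((n, n), np.nan)
        iu = np.triu_indices(n, 1)
        a[iu] = values
        a[(iu[1], iu[0])] = values
        return ea.assembly.PairwiseResult(
            pd.DataFrame(a, index=sites, columns=sites), "beta_nti")

    def test_shifted_groups_detected(self, rng):
        sites = [f"s{i}" for i in range(12)]
        groups = pd.Series(["a"] * 6 + ["b"] * 6, index=sites)
        vals = rng.normal(size=66)
        pr = self._pairwise(vals, sites)
        a = pr.data.loc[groups == "b", groups == "b"]
        pr.data.loc[groups == "b", groups == "b"] = a + 3.0
        h, p = ea.compare_bands(pr, groups)
        assert p < 1e-3

    def test_identical_values_p_one(self):
        sites = [f"s{i}" for i in range(8)]
        groups = pd.Series(["a"] * 4 + ["b"] * 4, index=sites)
        pr = self._pairwise(np.ones(28), sites)
        h, p = ea.compare_bands(pr, groups)
        assert p == 1.0

    def test_single_group_rejected(self):
        sites = [f"s{i}" for i in range(6)]
        groups = pd.Series(["a"] * 6, index=sites)
        pr = self._pairwise(np.arange(15.0), sites)
        with pytest.raises(ValidationError):
            ea.compare_bands(pr, groups)


class TestCompareTrees:
    def test_identical_trees_no_difference(self, scenario_small):
        m = scenario_small.matrix.subset_sites(scenario_small.matrix.sites[:8])
        out = ea.compare_trees(m, scenario_small.tree, scenario_small.tree,
                               reps=99, seed=2)
        assert out.loc["overall", "mean_abs_diff"] == 0.0
        assert out.loc["overall", "p"] == 1.0

    def test_regrafted_clade_changes_bnti(self):
        """Moving one clade elsewhere on the tree perturbs β-NTI under a
        filtering scenario."""
        data = ea.generate_scenario(ea.ScenarioConfig(
            n_species=40, n_sites=12, community_size=60, regime="filtered",
            filter_strength=0.5, seed=13))
        import dendropy

        nwk = data.tree.tree.as_string(schema="newick")
        t2 = dendropy.Tree.get(data=nwk, schema="newick",
                               preserve_underscores=True)
        # swap two tip labels across the tree: same label set, new shape
        leaves = list(t2.leaf_node_iter())
        leaves[0].taxon.label, leaves[-1].taxon.label = \
            leaves[-1].taxon.label, leaves[0].taxon.label
        perturbed = ea.Phylogeny(t2)
        out = ea.compare_trees(data.matrix, data.tree, perturbed,
                               reps=99, seed=3)
        assert out.loc["overall", "mean_abs_diff"] > 0
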