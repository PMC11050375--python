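from itertools import combinations

import numpy as np
import pytest
from scipy import stats

import ecoassembly as ea
from ecoassembly.core import ValidationError

from conftest import oracle_faith_pd, oracle_mntd, oracle_patristic


class TestHillNumbers:
    @pytest.mark.parametrize("q", [0, 0.5, 1, 2, 3])
    def test_uniform_community_gives_richness(self, q):
        assert ea.hill_number([4, 4, 4, 4, 4], q) == pytest.approx(5.0)

    def test_inverse_simpson_direct_formula(self):
        # p = (1/6, 2/6, 3/6): 1/Σp² = 36/14
        assert ea.hill_number([1, 2, 3], 2) == pytest.approx(36 / 14)

    def test_shannon_limit_continuity(self, rng):
        counts = rng.integers(1, 50, size=30)
        assert ea.hill_number(counts, 0.999) == pytest.approx(
            ea.hill_number(counts, 1), rel=1e-3)

    def test_profile_monotone_nonincreasing(self, rng):
        for _ in range(20):
            counts = rng.integers(0, 40, size=25)
            if counts.sum() == 0:
                continue
            prof = [ea.hill_number(counts, q)
                    for q in (0, 0.5, 1, 1.5, 2, 3)]
            assert all(a >= b - 1e-9 for a, b in zip(prof, prof[1:]))

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            ea.hill_number([0, 0], 1)


class TestFaithPD:
    def test_full_community_equals_total_length(self, small_tree):
        assert ea.faith_pd(small_tree, ["A", "B", "C"]) == pytest.approx(5.0)

    def test_single_tip_rooted(self, small_tree):
        assert ea.faith_pd(small_tree, ["A"]) == pytest.approx(2.0)

    def test_pair_rooted(self, small_tree):
        assert ea.faith_pd(small_tree, ["A", "B"]) == pytest.approx(3.0)

    def test_unrooted_variant_drops_root_path(self, small_tree):
        assert ea.faith_pd(small_tree, ["A", "B"],
                           include_root=False) == pytest.approx(2.0)

    def test_empty_and_unknown_rejected(self, small_tree):
        with pytest.raises(ValidationError):
            ea.faith_pd(small_tree, [])
        with pytest.raises(ValidationError):
            ea.faith_pd(small_tree, ["Z"])

    def test_monotone_under_species_addition(self, random_tree6):
        tips = random_tree6.tip_labels
        for r in range(1, 6):
            for sub in combinations(tips, r):
                bigger = set(sub) | {tips[-1]}
                assert ea.faith_pd(random_tree6, list(bigger)) >= \
                    ea.faith_pd(random_tree6, list(sub)) - 1e-12

    def test_against_scikit_bio(self, random_tree6, tmp_path):
        """Independent cross-check of rooted PD on a library implementation."""
        skbio = pytest.importorskip("skbio")
        p = tmp_path / "t.nwk"
        random_tree6.write(p)
        sk_tree = skbio.TreeNode.read(str(p))
        tips = random_tree6.tip_labels
        for sub in [tips[:2], tips[:4], tips]:
            counts = [1 if t in sub else 0 for t in tips]
            expected = skbio.diversity.alpha.faith_pd(counts, taxa=tips,
                                                      tree=sk_tree)
            assert ea.faith_pd(random_tree6, sub) == pytest.approx(
                expected, abs=1e-9)


class TestMNTD:
    def test_two_species_is_their_distance(self, small_tree):
        for weighted in (False, True):
            assert ea.mntd(small_tree, [3, 0, 5],
                           abundance_weighted=weighted) == pytest.approx(4.0)

    def test_three_species_unweighted(self, small_tree):
        # nearest distances: A→B=2, B→A=2, C→A or B = 4
        assert ea.mntd(small_tree, [1, 1, 1]) == pytest.approx(8 / 3)

    def test_weighted_with_mass_on_cherry(self, small_tree):
        val = ea.mntd(small_tree, [5, 5, 1e-12], abundance_weighted=True)
        assert val == pytest.approx(2.0, abs=1e-9)

    def test_equal_abundance_matches_unweighted(self, small_tree):
        assert ea.mntd(small_tree, [2, 2, 2], abundance_weighted=True) == \
            pytest.approx(ea.mntd(small_tree, [2, 2, 2]))

    def test_single_species_undefined(self, small_tree):
        assert np.isnan(ea.mntd(small_tree, [1, 0, 0]))


class TestCoverage:
    def test_no_singletons_full_coverage(self):
        assert ea.sample_coverage([2, 3, 10]) == 1.0

    def test_all_singletons(self):
        assert ea.sample_coverage([1, 1, 1]) == pytest.approx(0.0)

    def test_large_even_counts_approach_one(self):
        assert ea.sample_coverage([100] * 20) == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            ea.sample_coverage([0, 0])


class TestBruteForceAgreement:
    """PD and MNTD agree with edge-path enumeration on every community
    of a random 6-tip tree."""

    def test_faith_pd_all_subsets(self, random_tree6):
        tips = random_tree6.tip_labels
        for r in range(1, 7):
            for sub in combinations(tips, r):
                for rooted in (True, False):
                    assert ea.faith_pd(random_tree6, list(sub),
                                       include_root=rooted) == pytest.approx(
                        oracle_faith_pd(random_tree6, sub, rooted), abs=1e-12)

    def test_mntd_all_subsets(self, random_tree6):
        tips = random_tree6.tip_labels
        for r in range(2, 7):
            for sub in combinations(tips, r):
                counts = [1 if t in sub else 0 for t in tips]
                assert ea.mntd(random_tree6, counts) == pytest.approx(
                    oracle_mntd(random_tree6, sub), abs=1e-12)

    def test_patristic_matrix_matches_path_sums(self, random_tree6):
        tips = random_tree6.tip_labels
        for a, b in combinations(tips, 2):
            i, j = tips.index(a), tips.index(b)
            assert random_tree6.patristic[i, j] == pytest.approx(
                oracle_patristic(random_tree6, a, b), abs=1e-12)


class TestElevationCorrelation:
    def test_perfect_negative_metric(self, scenario_small):
        tab = ea.alpha_table(scenario_small.matrix)
        tab["anti_elev"] = -scenario_small.meta.elevation().loc[tab.index]
        corr = ea.diversity_elevation_correlation(tab, scenario_small.meta)
        assert corr.loc["anti_elev", "r"] == pytest.approx(-1.0)

    def test_constant_metric_reported_missing(self, scenario_small):
        tab = ea.alpha_table(scenario_small.matrix)
        tab["flat"] = 1.0
        corr = ea.diversity_elevation_correlation(tab, scenario_small.meta)
        assert np.isnan(corr.loc["flat", "r"])

    def test_type_one_error_calibrated(self, rng):
        """Independent noise rejects at ≈ the nominal 5% rate."""
        n_rej = 0
        n_sims = 1000
        elev = np.linspace(0, 1, 20)
        for _ in range(n_sims):
            y = rng.normal(size=20)
            _, p = stats.pearsonr(elev, y)
            n_rej += p < 0.05
        assert abs(n_rej / n_sims - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n_sims)

    def test_filtered_scenario_richness_declines(self):
        data = ea.generate_scenario(ea.ScenarioConfig(
            regime="filtered", filter_strength=0.5, seed=2,
            n_species=120, n_sites=40))
        tab = ea.alpha_table(data.matrix)
        corr = ea.diversity_elevation_correlation(tab, data.meta)
        assert corr.loc["SR", "r"] < 0
        assert corr.loc["SR", "p"] < 0.05
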