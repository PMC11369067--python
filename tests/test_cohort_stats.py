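import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats as ss

from engraftkit import cohort_stats as cst
from engraftkit.engraftment import aitchison_distance_matrix


def _enumeration_fisher(a, b, c, d):
    """Independent oracle: explicit hypergeometric enumeration with floats."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    pmf = {k: ss.hypergeom.pmf(k, n, r1, c1) for k in range(lo, hi + 1)}
    obs = pmf[a]
    return sum(p for p in pmf.values() if p <= obs * (1 + 1e-7))


class TestFisherExact:
    def test_prior_anti_tnf_table(self):
        # budesonide 8/13 vs placebo 2/11 with prior anti-TNF exposure
        res = cst.fisher_exact_2x2(8, 5, 2, 9)
        assert res.p_value == pytest.approx(0.04718, abs=5e-5)
        assert round(res.p_value, 3) == 0.047

    def test_week14_donor_response_table(self):
        res = cst.fisher_exact_2x2(2, 10, 8, 4)
        assert res.p_value == pytest.approx(0.03607, abs=5e-5)
        assert res.p_value <= 0.04

    def test_balanced_table_p_one(self):
        assert cst.fisher_exact_2x2(5, 5, 5, 5).p_value == 1.0

    def test_degenerate_margin_warns_p_one(self):
        with pytest.warns(UserWarning, match="degenerate"):
            res = cst.fisher_exact_2x2(0, 0, 3, 4)
        assert res.p_value == 1.0

    def test_matches_scipy_oracle_on_random_tables(self, rng):
        for _ in range(300):
            a, b, c, d = rng.integers(0, 15, size=4)
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            ours = cst.fisher_exact_2x2(int(a), int(b), int(c), int(d)).p_value
            ref = ss.fisher_exact([[a, b], [c, d]]).pvalue
            assert ours == pytest.approx(ref, abs=1e-9)

    def test_matches_enumeration_oracle_small_tables(self):
        for a, b, c, d in itertools.product(range(5), repeat=4):
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            ours = cst.fisher_exact_2x2(a, b, c, d).p_value
            assert ours == pytest.approx(_enumeration_fisher(a, b, c, d), abs=1e-9)

    def test_doubling_convention_at_least_point_probability(self):
        point = cst.fisher_exact_2x2(8, 5, 2, 9).p_value
        doubled = cst.fisher_exact_2x2(8, 5, 2, 9, convention="doubling").p_value
        assert doubled >= point


class TestChiSquare:
    def test_independence_gives_zero_statistic(self):
        res = cst.chi_square_2x2(10, 10, 10, 10)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_perfect_association_statistic(self):
        # n*(ad-bc)^2 / (r1*r2*c1*c2) = 40*400^2/20^4 = 40
        assert cst.chi_square_2x2(20, 0, 0, 20).statistic == pytest.approx(40.0)

    def test_transposition_invariance(self, rng):
        a, b, c, d = (int(v) for v in rng.integers(1, 30, size=4))
        assert cst.chi_square_2x2(a, b, c, d).statistic == pytest.approx(cst.chi_square_2x2(a, c, b, d).statistic)

    def test_zero_margin_errors(self):
        with pytest.raises(ValueError, match="zero margin"):
            cst.chi_square_2x2(0, 0, 5, 5)


def _enumerate_rank_sum(x, y):
    """Brute-force two-sided p over all C(n+m, n) group assignments."""
    pooled = np.concatenate([x, y])
    n = len(x)
    ranks = ss.rankdata(pooled)
    obs = ranks[:n].sum()
    mu = n * (len(pooled) + 1) / 2
    stats = [
        abs(sum(ranks[list(idx)]) - mu)
        for idx in itertools.combinations(range(len(pooled)), n)
    ]
    return sum(s >= abs(obs - mu) - 1e-12 for s in stats) / len(stats)


class TestWilcoxonRankSum:
    def test_minimal_example_one_third(self):
        res = cst.wilcoxon_rank_sum_exact([1, 2], [3, 4])
        assert res.p_value == pytest.approx(1 / 3)
        assert res.method == "wilcoxon-exact"

    def test_degenerate_singletons_tie(self):
        res = cst.wilcoxon_rank_sum_exact([1.0], [1.0])
        assert res.p_value == pytest.approx(1.0)
        assert res.method == "wilcoxon-normal-approx"

    def test_symmetric_in_group_exchange(self, rng):
        x, y = rng.normal(size=6), rng.normal(size=4)
        assert cst.wilcoxon_rank_sum_exact(x, y).p_value == pytest.approx(
            cst.wilcoxon_rank_sum_exact(y, x).p_value
        )

    def test_matches_enumeration_oracle_small_groups(self, rng):
        for _ in range(30):
            n, m = rng.integers(2, 8, size=2)
            x = rng.normal(size=int(n))
            y = rng.normal(size=int(m))
            res = cst.wilcoxon_rank_sum_exact(x, y)
            assert res.method == "wilcoxon-exact"
            assert res.p_value == pytest.approx(_enumerate_rank_sum(x, y), abs=1e-12)

    def test_large_groups_fall_back_to_normal_approximation(self, rng):
        res = cst.wilcoxon_rank_sum_exact(rng.normal(size=20), rng.normal(size=20))
        assert res.method == "wilcoxon-normal-approx"


class TestTwoWayAnova:
    def test_constant_response_degenerates_to_null(self):
        res = cst.two_way_anova([1.0] * 8, list("aabbaabb"), list("ccddccdd"))
        assert res["factor_a"].statistic == 0.0
        assert res["factor_a"].p_value == 1.0

    def test_recovers_large_additive_effects(self, rng):
        a = np.repeat(["lo", "hi"], 12)
        b = np.tile(np.repeat(["x", "y"], 6), 2)
        score = 2.0 * (a == "hi") + 1.5 * (b == "y") + rng.normal(0, 0.3, size=24)
        res = cst.two_way_anova(score, a, b)
        assert res["factor_a"].p_value < 0.01
        assert res["factor_b"].p_value < 0.01

    def test_single_level_factor_errors(self):
        with pytest.raises(ValueError, match="single observed level"):
            cst.two_way_anova([1, 2, 3, 4], ["a"] * 4, ["x", "x", "y", "y"])

    def test_null_type_i_error_calibrated(self):
        rng = np.random.default_rng(7)
        rejections = 0
        n_sims = 300
        a = np.repeat(["p", "q"], 8)
        b = np.tile(["u", "v"], 8)
        for _ in range(n_sims):
            score = rng.normal(size=16)
            rejections += cst.two_way_anova(score, a, b)["factor_a"].p_value <= 0.05
        assert 0.02 <= rejections / n_sims <= 0.08


class TestDiversity:
    def test_uniform_maximizes_shannon(self):
        res = cst.diversity(pd.Series([0.25] * 4, index=list("abcd")))
        assert res.observed_species == 4
        assert res.shannon == pytest.approx(np.log(4), abs=1e-9)

    def test_single_species_zero_entropy(self):
        assert cst.diversity(pd.Series({"a": 1.0})).shannon == 0.0

    def test_hand_computed_composition(self):
        res = cst.diversity(pd.Series({"a": 0.5, "b": 0.25, "c": 0.25}))
        assert res.shannon == pytest.approx(1.0397, abs=1e-4)

    def test_detection_limit_applied(self):
        res = cst.diversity(pd.Series({"a": 0.9995, "b": 0.0005}), tau=0.001)
        assert res.observed_species == 1

    def test_uniform_dominates_any_same_richness_composition(self, rng):
        for _ in range(20):
            p = rng.dirichlet(np.ones(8))
            res = cst.diversity(pd.Series(p, index=[f"s{i}" for i in range(8)]), tau=0.0)
            assert res.shannon <= np.log(8) + 1e-12

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError, match="no species"):
            cst.diversity(pd.Series({"a": 0.0}))


def _two_cluster_table(rng, n_per=8, shift=4.0):
    base1 = rng.dirichlet(np.full(20, 0.8))
    base2 = rng.dirichlet(np.full(20, 0.8))
    rows = [rng.dirichlet(500 * base1) for _ in range(n_per)] + [rng.dirichlet(500 * base2) for _ in range(n_per)]
    return pd.DataFrame(rows, index=[f"s{i}" for i in range(2 * n_per)])


class TestPermanova:
    def test_separated_clusters_hit_permutation_floor(self, rng):
        table = _two_cluster_table(rng)
        dm = aitchison_distance_matrix(table)
        labels = ["g1"] * 8 + ["g2"] * 8
        res = cst.permanova(dm, labels, n_permutations=999, seed=1)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_seeded_reproducibility(self, rng):
        table = _two_cluster_table(rng)
        dm = aitchison_distance_matrix(table)
        labels = ["g1"] * 8 + ["g2"] * 8
        p1 = cst.permanova(dm, labels, n_permutations=99, seed=5).p_value
        p2 = cst.permanova(dm, labels, n_permutations=99, seed=5).p_value
        assert p1 == p2

    def test_relabel_invariance_of_statistic(self, rng):
        table = _two_cluster_table(rng)
        dm = aitchison_distance_matrix(table).to_numpy()
        labels = np.array(["g1"] * 8 + ["g2"] * 8)
        perm = rng.permutation(16)
        f1 = cst.permanova(dm, labels, n_permutations=9, seed=0).statistic
        f2 = cst.permanova(dm[np.ix_(perm, perm)], labels[perm], n_permutations=9, seed=0).statistic
        assert f1 == pytest.approx(f2)

    def test_single_group_errors(self):
        with pytest.raises(ValueError, match="2 groups"):
            cst.permanova(np.zeros((4, 4)), ["g"] * 4)

    def test_p_respects_permutation_floor(self, rng):
        table = _two_cluster_table(rng)
        dm = aitchison_distance_matrix(table)
        res = cst.permanova(dm, ["g1"] * 8 + ["g2"] * 8, n_permutations=99, seed=2)
        assert res.p_value >= 1 / 100


def _brute_force_complete_linkage(points):
    """Naive agglomeration tracking max inter-cluster distance at each merge."""
    clusters = [[i] for i in range(len(points))]
    heights = []
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=2)
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                h = max(d[a, b] for a in clusters[i] for b in clusters[j])
                if best is None or h < best[0]:
                    best = (h, i, j)
        h, i, j = best
        heights.append(h)
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return heights


class TestDonorClustering:
    def test_identical_donors_merge_at_zero(self):
        m = pd.DataFrame([[0.5, 0.5], [0.5, 0.5]], index=["D07", "D08"])
        tree = cst.donor_family_clustering(m)
        assert tree.heights.tolist() == [0.0]

    def test_three_point_hand_example(self):
        # mutual distances 1, 1, ~10: first merge at 1, second at max distance
        m = pd.DataFrame([[0.0, 0.0], [1.0, 0.0], [10.0, 0.0]], index=list("abc"))
        tree = cst.donor_family_clustering(m)
        assert tree.heights[0] == pytest.approx(1.0)
        assert tree.heights[1] == pytest.approx(10.0)

    def test_heights_nondecreasing(self, rng):
        m = pd.DataFrame(rng.dirichlet(np.ones(6), size=8))
        tree = cst.donor_family_clustering(m)
        assert (np.diff(tree.heights) >= -1e-12).all()

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(5):
            points = rng.normal(size=(7, 4))
            tree = cst.donor_family_clustering(pd.DataFrame(points))
            expected = _brute_force_complete_linkage(points)
            assert np.allclose(np.sort(tree.heights), np.sort(expected), atol=1e-9)

    def test_mean_family_aggregation(self):
        profiles = pd.DataFrame(
            [[0.2, 0.3, 0.5], [0.4, 0.1, 0.5]],
            index=["d1", "d2"],
            columns=["spA", "spB", "spC"],
        )
        fam = pd.Series({"spA": "F1", "spB": "F1", "spC": "F2"})
        by = pd.Series({"d1": "D07", "d2": "D07"})
        out = cst.mean_family_abundances(profiles, fam, by)
        assert out.loc["D07", "F1"] == pytest.approx(0.5)
        assert out.loc["D07", "F2"] == pytest.approx(0.5)
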