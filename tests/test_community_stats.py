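"""Diversity, ordination and permutation-test statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from tephraseq import community_stats as cs
from conftest import make_table


class TestRarefaction:
    def test_full_draw_is_identity_multiset(self):
        t = make_table([[5], [3], [2]])
        r = cs.rarefy_even_depth(t, depth=10, seed=0)
        assert r.sample("S0").tolist() == [5, 3, 2]

    def test_column_sums_equal_depth(self):
        rng = np.random.default_rng(1)
        t = make_table(rng.poisson(30, size=(20, 5)))
        r = cs.rarefy_even_depth(t, depth=100, seed=3)
        assert (r.column_sums() == 100).all()

    def test_shallow_samples_dropped_with_warning(self, caplog):
        t = make_table([[50, 2], [50, 1]])
        with caplog.at_level("WARNING"):
            r = cs.rarefy_even_depth(t, depth=20, seed=0)
        assert r.sample_ids == ["S0"]
        assert "S1" in caplog.text

    def test_deterministic_under_seed(self):
        t = make_table([[10, 8], [5, 9], [7, 3]])
        a = cs.rarefy_even_depth(t, depth=10, seed=9)
        b = cs.rarefy_even_depth(t, depth=10, seed=9)
        assert a == b

    def test_expected_richness_matches_hypergeometric_formula(self):
        """Mean rarefied richness over 1,000 seeds agrees with the closed-form
        hypergeometric expectation."""
        counts = np.array([12, 7, 5, 3, 2, 1, 1, 1])
        t = make_table(counts[:, None])
        depth = 15
        expected = cs.expected_rarefied_richness(counts, depth)
        obs = []
        for seed in range(1000):
            r = cs.rarefy_even_depth(t, depth=depth, seed=seed)
            obs.append(int((r.sample("S0") > 0).sum()))
        # 3 sigma Monte-Carlo band around the expectation
        se = np.std(obs, ddof=1) / math.sqrt(len(obs))
        assert np.mean(obs) == pytest.approx(expected, abs=3 * se + 1e-9)


class TestAlphaDiversity:
    def test_uniform_closed_form(self):
        assert cs.observed_richness([10, 10, 10, 10]) == 4
        assert cs.shannon([10, 10, 10, 10]) == pytest.approx(math.log(4))

    def test_single_taxon(self):
        assert cs.observed_richness([42, 0, 0]) == 1
        assert cs.shannon([42, 0, 0]) == 0.0

    def test_direct_formula(self):
        expected = -sum(p * math.log(p) for p in (1 / 6, 2 / 6, 3 / 6))
        assert cs.shannon([1, 2, 3]) == pytest.approx(expected)
        assert cs.shannon([1, 2, 3]) == pytest.approx(1.0114, abs=5e-5)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            cs.shannon([0, 0])

    def test_shannon_maximal_at_uniform(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            counts = rng.integers(1, 50, size=8)
            assert cs.shannon(counts) <= math.log(8) + 1e-12
        assert cs.shannon(np.ones(8)) == pytest.approx(math.log(8))


class TestAnovaTukey:
    def test_identical_groups_null(self):
        vals = np.array([1.0, 2.0, 1.0, 2.0, 1.0, 2.0])
        groups = np.array(["a", "a", "b", "b", "c", "c"])
        res = cs.anova_oneway(vals, groups)
        assert res.statistic == 0.0 and res.p == pytest.approx(1.0)
        for t in cs.tukey_hsd(vals, groups):
            assert t.p == pytest.approx(1.0, abs=1e-9)

    def test_f_equals_t_squared_two_groups(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(0, 1, 12), rng.normal(0.8, 1, 15)
        res = cs.anova_oneway(np.concatenate([x, y]),
                              np.array(["x"] * 12 + ["y"] * 15))
        t_stat, _ = stats.ttest_ind(x, y)
        assert res.statistic == pytest.approx(t_stat**2, rel=1e-10)

    def test_cross_check_with_scipy(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(size=18)
        groups = np.repeat(["a", "b", "c"], 6)
        res = cs.anova_oneway(vals, groups)
        f, p = stats.f_oneway(*(vals[groups == g] for g in "abc"))
        assert res.statistic == pytest.approx(f, rel=1e-12)
        assert res.p == pytest.approx(p, rel=1e-12)
        ours = {t.name: t for t in cs.tukey_hsd(vals, groups)}
        ref = stats.tukey_hsd(*(vals[groups == g] for g in "abc"))
        pairs = [("a", "b", 0, 1), ("a", "c", 0, 2), ("b", "c", 1, 2)]
        for g1, g2, i, j in pairs:
            assert ours[f"tukey:{g1}|{g2}"].p == pytest.approx(
                ref.pvalue[i, j], abs=1e-9)

    def test_displaced_group_dominates(self):
        vals = np.array([1, 2, 1, 2, 5, 6], dtype=float)
        groups = np.array(["g1", "g1", "g2", "g2", "g3", "g3"])
        res = {t.name: t for t in cs.tukey_hsd(vals, groups)}
        assert res["tukey:g1|g2"].p > 0.9
        q12 = res["tukey:g1|g2"].statistic
        assert res["tukey:g1|g3"].statistic > q12
        assert res["tukey:g2|g3"].statistic > q12

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="g2"):
            cs.tukey_hsd(np.array([1.0, 2.0, 3.0]), np.array(["g1", "g1", "g2"]))


class TestBrayCurtis:
    def test_closed_forms(self):
        assert cs.bray_curtis([1, 2, 3], [1, 2, 3]) == 0.0
        assert cs.bray_curtis([1, 0], [0, 4]) == 1.0
        assert cs.bray_curtis([1, 2, 3], [3, 2, 1]) == pytest.approx(1 / 3)

    def test_matrix_properties(self):
        rng = np.random.default_rng(2)
        t = make_table(rng.poisson(10, size=(30, 6)))
        d = cs.bray_curtis_matrix(t)
        assert np.allclose(d.values, d.values.T)
        assert np.allclose(np.diag(d.values), 0)
        assert d.values.max() <= 1.0 and d.values.min() >= 0.0

    def test_joint_scaling_invariance(self):
        x, y = np.array([3.0, 1.0, 4.0]), np.array([2.0, 2.0, 0.0])
        assert cs.bray_curtis(5 * x, 5 * y) == pytest.approx(cs.bray_curtis(x, y))

    def test_all_zero_sample_named(self):
        t = make_table([[1, 0], [2, 0]])
        with pytest.raises(ValueError, match="S1"):
            cs.bray_curtis_matrix(t)


def planar_distance_matrix(n=10, seed=0):
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(n, 2))
    return cs.DistanceMatrix([f"p{i}" for i in range(n)],
                             squareform(pdist(pts)))


class TestNMDS:
    def test_planar_configuration_recovered(self):
        o = cs.nmds(planar_distance_matrix(), seed=1)
        assert o.stress < 0.01

    def test_three_points_exact(self):
        d = cs.DistanceMatrix(["a", "b", "c"],
                              np.array([[0, 1.0, 1.5], [1.0, 0, 2.0], [1.5, 2.0, 0]]))
        o = cs.nmds(d, seed=2)
        assert o.stress < 1e-6

    def test_stress_trace_non_increasing(self):
        rng = np.random.default_rng(3)
        t = make_table(rng.poisson(15, size=(25, 9)))
        o = cs.nmds(cs.bray_curtis_matrix(t), seed=4)
        assert all(a >= b for a, b in zip(o.stress_trace, o.stress_trace[1:]))

    def test_rank_invariance_under_doubling(self):
        d = cs.bray_curtis_matrix(
            make_table(np.random.default_rng(6).poisson(12, size=(20, 8))))
        d2 = cs.DistanceMatrix(d.sample_ids, 2 * d.values)
        o1 = cs.nmds(d, seed=7)
        o2 = cs.nmds(d2, seed=7)
        assert o1.stress == pytest.approx(o2.stress, abs=1e-9)

    def test_stored_stress_matches_recomputation(self):
        o = cs.nmds(planar_distance_matrix(seed=11), seed=8)
        assert cs.ordination_stress(o.coordinates, planar_distance_matrix(seed=11)) \
            == pytest.approx(o.stress, abs=1e-10)

    def test_stress_invariant_to_rigid_motion(self):
        dm = planar_distance_matrix(seed=12)
        o = cs.nmds(dm, seed=9)
        theta = 0.7
        rot = np.array([[math.cos(theta), -math.sin(theta)],
                        [math.sin(theta), math.cos(theta)]])
        moved = 3.0 * (o.coordinates @ rot) + np.array([5.0, -2.0])
        assert cs.ordination_stress(moved, dm) == pytest.approx(o.stress, abs=1e-10)


def two_cluster_distance(n_per=3, gap=4.0, seed=0):
    rng = np.random.default_rng(seed)
    pts = np.vstack([rng.normal(0, 1, size=(n_per, 2)),
                     rng.normal(gap, 1, size=(n_per, 2))])
    ids = [f"s{i}" for i in range(2 * n_per)]
    return cs.DistanceMatrix(ids, squareform(pdist(pts)))


class TestPermanova:
    def test_degenerate_all_zero(self):
        d = cs.DistanceMatrix(["a", "b", "c", "d"], np.zeros((4, 4)))
        res = cs.permanova(d, np.array(["x", "x", "y", "y"]), seed=0)
        assert res.statistic == 0.0 and res.p == 1.0

    def test_exhaustive_matches_brute_force(self):
        """Exhaustive mode reproduces a from-scratch enumeration over all 20
        distinct assignments of 6 samples into two groups of 3."""
        d = two_cluster_distance()
        labels = np.array(["g1"] * 3 + ["g2"] * 3)
        res = cs.permanova(d, labels, exhaustive=True)

        # independent brute force from the SS definitions
        d2 = d.values**2
        def pseudo_f(lab):
            n = len(lab)
            ss_tot = d2[np.triu_indices(n, 1)].sum() / n
            ss_w = 0.0
            for g in ("g1", "g2"):
                idx = np.flatnonzero(lab == g)
                ss_w += d2[np.ix_(idx, idx)][np.triu_indices(len(idx), 1)].sum() / len(idx)
            return ((ss_tot - ss_w) / 1) / (ss_w / (n - 2))

        f_obs = pseudo_f(labels)
        seen = set()
        ge = total = 0
        for combo in itertools.combinations(range(6), 3):
            lab = np.array(["g2"] * 6)
            lab[list(combo)] = "g1"
            key = tuple(lab)
            if key in seen or tuple(np.where(lab == "g1", "g2", "g1")) in seen:
                pass
            seen.add(key)
            total += 1
            if pseudo_f(lab) >= f_obs - 1e-12:
                ge += 1
        assert res.statistic == pytest.approx(f_obs, rel=1e-12)
        assert res.p == pytest.approx(ge / total, abs=1e-12)

    def test_cross_check_with_scikit_bio(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import permanova as skbio_permanova

        d = two_cluster_distance(n_per=5, gap=2.0, seed=3)
        labels = ["g1"] * 5 + ["g2"] * 5
        ours = cs.permanova(d, np.array(labels), n_permutations=99, seed=0)
        theirs = skbio_permanova(skbio.DistanceMatrix(d.values, d.sample_ids),
                                 labels, permutations=99)
        assert ours.statistic == pytest.approx(theirs["test statistic"], rel=1e-9)

    def test_p_floor(self):
        d = two_cluster_distance(gap=50.0)
        res = cs.permanova(d, np.array(["a"] * 3 + ["b"] * 3),
                           n_permutations=99, seed=1)
        assert res.p >= 1 / 100

    def test_null_type_one_error_calibrated(self):
        """Empirical size at alpha=0.05 within 3 binomial SEs over 500 null
        simulations (n=20, two groups, 199 permutations)."""
        rng = np.random.default_rng(2024)
        labels = np.array(["a"] * 10 + ["b"] * 10)
        rejections = 0
        n_sim = 500
        for i in range(n_sim):
            pts = rng.normal(size=(20, 3))
            d = cs.DistanceMatrix([f"s{j}" for j in range(20)],
                                  squareform(pdist(pts)))
            res = cs.permanova(d, labels, n_permutations=199,
                               seed=int(rng.integers(2**31 - 1)))
            if res.p <= 0.05:
                rejections += 1
        rate = rejections / n_sim
        se = math.sqrt(0.05 * 0.95 / n_sim)
        assert abs(rate - 0.05) <= 3 * se + 1 / 200


class TestPairwisePermanova:
    def test_adjusted_at_least_raw(self):
        d = two_cluster_distance(n_per=4, gap=1.0, seed=9)
        labels = np.array(["a", "a", "a", "b", "b", "b", "c", "c"])
        results = cs.pairwise_permanova(d, labels, n_permutations=99, seed=0)
        assert len(results) == 3
        for r in results:
            assert r.p_adjusted >= r.p - 1e-12

    def test_displaced_group_found(self):
        rng = np.random.default_rng(4)
        pts = np.vstack([rng.normal(0, 0.1, size=(4, 2)),
                         rng.normal(0, 0.1, size=(4, 2)),
                         rng.normal(8, 0.1, size=(4, 2))])
        d = cs.DistanceMatrix([f"s{i}" for i in range(12)], squareform(pdist(pts)))
        labels = np.repeat(["a", "b", "c"], 4)
        results = {r.name: r for r in cs.pairwise_permanova(
            d, labels, n_permutations=199, seed=5)}
        assert results["permanova:a|c"].p_adjusted < results["permanova:a|b"].p_adjusted
        assert results["permanova:b|c"].p_adjusted < results["permanova:a|b"].p_adjusted


class TestEnvfit:
    def ordination(self, n=12, seed=0):
        rng = np.random.default_rng(seed)
        coords = rng.normal(size=(n, 2))
        return cs.Ordination([f"s{i}" for i in range(n)], coords, 0.1, 1, True)

    def test_perfect_fit_on_axis(self):
        o = self.ordination()
        var = pd.DataFrame({"v": o.coordinates[:, 0]}, index=o.sample_ids)
        res = cs.envfit(o, var, n_permutations=99, seed=1)["v"]
        assert res.statistic == pytest.approx(1.0, abs=1e-10)
        direction = np.abs(res.payload["direction"])
        assert direction[0] == pytest.approx(1.0, abs=1e-8)
        assert direction[1] == pytest.approx(0.0, abs=1e-8)

    def test_exhaustive_p_at_n5(self):
        """Sampled permutation p is within Monte-Carlo error of the exhaustive
        p over all 120 permutations of the variable."""
        o = self.ordination(n=5, seed=3)
        rng = np.random.default_rng(7)
        v = rng.normal(size=5)
        coords = o.coordinates - o.coordinates.mean(axis=0)
        y0 = v - v.mean()

        def r2(y):
            beta, *_ = np.linalg.lstsq(coords, y, rcond=None)
            return 1 - ((y - coords @ beta) ** 2).sum() / (y**2).sum()

        r2_obs = r2(y0)
        ge = sum(r2(np.array(p)) >= r2_obs - 1e-12
                 for p in itertools.permutations(y0))
        exact = ge / math.factorial(5)
        res = cs.envfit(o, pd.DataFrame({"v": v}, index=o.sample_ids),
                        n_permutations=4999, seed=11)["v"]
        assert res.p == pytest.approx(exact, abs=0.05)

    def test_constant_variable_rejected(self):
        o = self.ordination()
        with pytest.raises(ValueError, match="zero variance"):
            cs.envfit(o, pd.DataFrame({"v": np.ones(12)}, index=o.sample_ids))

    def test_missing_values_dropped_with_warning(self, caplog):
        o = self.ordination()
        v = o.coordinates[:, 0].copy()
        v[0] = np.nan
        with caplog.at_level("WARNING"):
            res = cs.envfit(o, pd.DataFrame({"depth": v}, index=o.sample_ids),
                            n_permutations=49, seed=2)["depth"]
        assert "missing" in caplog.text
        assert res.statistic == pytest.approx(1.0, abs=1e-10)
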