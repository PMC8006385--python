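import itertools

import numpy as np
import pandas as pd
import pytest

import otukit as ok
from otukit.diversity import _permanova_f
from otukit.errors import AnalysisError, ValidationError


def _exp_from_columns(cols):
    cols = np.asarray(cols, dtype=int)
    counts = pd.DataFrame(
        cols.T, index=[f"f{i}" for i in range(cols.shape[1])],
        columns=[f"S{j}" for j in range(cols.shape[0])],
    )
    return ok.create_experiment(counts, metadata=pd.DataFrame(index=counts.columns))


class TestAlphaDiversity:
    def test_uniform_closed_forms(self):
        exp = _exp_from_columns([[5, 5, 5, 5]])
        assert ok.alpha_diversity(exp, "shannon")["S0"] == pytest.approx(np.log(4), abs=1e-12)
        assert ok.alpha_diversity(exp, "gini_simpson")["S0"] == pytest.approx(0.75, abs=1e-12)
        assert ok.alpha_diversity(exp, "inverse_simpson")["S0"] == pytest.approx(4.0, abs=1e-12)
        assert ok.alpha_diversity(exp, "richness")["S0"] == 4

    def test_single_taxon_degenerate(self):
        exp = _exp_from_columns([[9, 0, 0]])
        assert ok.alpha_diversity(exp, "shannon")["S0"] == 0.0
        assert ok.alpha_diversity(exp, "gini_simpson")["S0"] == 0.0
        assert ok.alpha_diversity(exp, "inverse_simpson")["S0"] == 1.0
        assert ok.alpha_diversity(exp, "richness")["S0"] == 1

    def test_direct_formula(self):
        # brute-force evaluation of -sum p ln p with p = (1/6, 1/3, 1/2)
        exp = _exp_from_columns([[1, 2, 3]])
        p = np.array([1, 2, 3]) / 6
        expected = -(p * np.log(p)).sum()
        assert ok.alpha_diversity(exp, "shannon")["S0"] == pytest.approx(expected, rel=1e-12)

    def test_shannon_bounded_by_log_richness(self, effect_sim):
        exp, _ = effect_sim
        sh = ok.alpha_diversity(exp, "shannon")
        rich = ok.alpha_diversity(exp, "richness")
        inv = ok.alpha_diversity(exp, "inverse_simpson")
        assert (sh <= np.log(rich) + 1e-9).all()
        assert (inv <= rich + 1e-9).all()

    def test_all_zero_sample_errors(self):
        with pytest.raises(AnalysisError):
            ok.alpha_diversity(_exp_from_columns([[0, 0], [1, 2]]))


def _wilcoxon_exact_oracle(a, b):
    """Two-sided rank-sum p by full enumeration of rank assignments."""
    pooled = np.concatenate([a, b])
    ranks = pd.Series(pooled).rank().to_numpy()
    n = len(pooled)
    na = len(a)
    obs = ranks[:na].sum()
    mean = na * (n + 1) / 2
    stats = [sum(combo) for combo in itertools.combinations(ranks, na)]
    extreme = sum(abs(s - mean) >= abs(obs - mean) - 1e-9 for s in stats)
    return extreme / len(stats)


class TestAlphaTests:
    def test_wilcoxon_exact_matches_enumeration(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        oracle_p = _wilcoxon_exact_oracle(a, b)
        assert oracle_p == pytest.approx(0.1)
        values = pd.Series(a + b)
        groups = ["x"] * 3 + ["y"] * 3
        res = ok.alpha_div_test(values, groups, method="wilcoxon")
        assert res.method == "wilcoxon_exact"
        assert res.p_value == pytest.approx(oracle_p, abs=1e-12)

    def test_identical_groups_no_separation(self):
        values = pd.Series([2.0, 2.0, 2.0, 2.0, 2.0, 2.0])
        groups = ["x"] * 3 + ["y"] * 3
        kw = ok.alpha_div_test(values, groups, method="kruskal_wallis")
        assert kw.statistic == 0.0 and kw.p_value == 1.0
        wil = ok.alpha_div_test(values, groups, method="wilcoxon")
        assert wil.p_value == pytest.approx(1.0)

    def test_welch_t_against_scipy(self):
        from scipy import stats as sps
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 10), rng.normal(1, 2, 12)
        values = pd.Series(np.concatenate([a, b]))
        groups = ["a"] * 10 + ["b"] * 12
        res = ok.alpha_div_test(values, groups, method="t_test")
        ref = sps.ttest_ind(a, b, equal_var=False)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_kruskal_equals_squared_z_on_two_groups(self):
        # algebraic identity H = z^2 (no continuity correction) on tie-free data
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 15), rng.normal(0.5, 1, 17)
        values = pd.Series(np.concatenate([a, b]))
        groups = ["a"] * 15 + ["b"] * 17
        kw = ok.alpha_div_test(values, groups, method="kruskal_wallis")
        from scipy import stats as sps
        u = sps.mannwhitneyu(a, b, alternative="two-sided",
                             method="asymptotic", use_continuity=False)
        n1, n2 = 15, 17
        z = (u.statistic - n1 * n2 / 2) / np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12)
        assert kw.statistic == pytest.approx(z**2, rel=1e-9)

    def test_method_group_count_mismatch(self):
        values = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        with pytest.raises(ValidationError):
            ok.alpha_div_test(values, ["a", "a", "b", "b", "c", "c"],
                              method="wilcoxon")


class TestBetaDistance:
    def test_worked_case(self):
        exp = _exp_from_columns([[6, 4, 0], [2, 4, 8]])
        D = ok.beta_distance(exp, "bray_curtis", assay="counts")
        assert D.values[0, 1] == pytest.approx(0.5)
        J = ok.beta_distance(exp, "jaccard")
        assert J.values[0, 1] == pytest.approx(1 - 2 / 3)

    def test_identical_columns_zero(self):
        exp = _exp_from_columns([[3, 1, 4], [3, 1, 4]])
        for metric in ("bray_curtis", "jaccard"):
            assert ok.beta_distance(exp, metric).values[0, 1] == 0.0

    def test_disjoint_support_one(self):
        exp = _exp_from_columns([[5, 0, 3, 0], [0, 2, 0, 7]])
        for metric in ("bray_curtis", "jaccard"):
            assert ok.beta_distance(exp, metric).values[0, 1] == 1.0

    def test_matches_scipy_reference(self, cluster_sim):
        from scipy.spatial.distance import braycurtis, jaccard

        exp, _ = cluster_sim
        rel = ok.counts_to_relabu(exp.counts).to_numpy().T
        D = ok.beta_distance(exp, "bray_curtis")
        for i, j in [(0, 1), (2, 17), (5, 19)]:
            assert D.values[i, j] == pytest.approx(braycurtis(rel[i], rel[j]))
        pres = (exp.counts.to_numpy() > 0).T
        J = ok.beta_distance(exp, "jaccard")
        for i, j in [(0, 1), (3, 12)]:
            assert J.values[i, j] == pytest.approx(jaccard(pres[i], pres[j]))

    def test_range_and_symmetry(self, cluster_sim):
        exp, _ = cluster_sim
        for metric in ("bray_curtis", "jaccard"):
            D = ok.beta_distance(exp, metric)
            assert ((D.values >= -1e-12) & (D.values <= 1 + 1e-12)).all()
            np.testing.assert_allclose(D.values, D.values.T)


class TestBetaGroupDistances:
    def test_pair_counting(self):
        exp = _exp_from_columns([[1, 2], [2, 1], [5, 1], [1, 5]])
        D = ok.beta_distance(exp, "bray_curtis")
        parts = ok.beta_group_distances(D, ["a", "a", "b", "b"])
        assert len(parts["within_g1"]) == 1
        assert len(parts["within_g2"]) == 1
        assert len(parts["between"]) == 4

    def test_constant_distances(self):
        vals = np.full((4, 4), 0.3)
        np.fill_diagonal(vals, 0.0)
        D = ok.DistanceMatrix(vals, ("a", "b", "c", "d"), "bray_curtis")
        parts = ok.beta_group_distances(D, ["x", "x", "y", "y"])
        for key in ("within_g1", "within_g2", "between"):
            assert (parts[key] == 0.3).all()

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        M = rng.random((6, 6))
        vals = (M + M.T) / 2
        np.fill_diagonal(vals, 0.0)
        ids = tuple("abcdef")
        D = ok.DistanceMatrix(vals, ids, "bray_curtis")
        groups = ["x", "x", "x", "y", "y", "y"]
        parts = ok.beta_group_distances(D, groups)
        perm = [2, 0, 1, 5, 3, 4]
        D2 = ok.DistanceMatrix(vals[np.ix_(perm, perm)],
                               tuple(ids[i] for i in perm), "bray_curtis")
        parts2 = ok.beta_group_distances(D2, [groups[i] for i in perm])
        for key in ("within_g1", "within_g2", "between"):
            assert sorted(parts[key]) == pytest.approx(sorted(parts2[key]))


@pytest.fixture(scope="module")
def fixed_d():
    rng = np.random.default_rng(11)
    X = rng.random((6, 4))
    from scipy.spatial.distance import pdist, squareform
    vals = squareform(pdist(X, "braycurtis"))
    return ok.DistanceMatrix(vals, tuple(f"S{i}" for i in range(6)),
                             "bray_curtis")


class TestPermanova:

    def test_exhaustive_enumeration_matches_monte_carlo(self, fixed_d):
        groups = np.array(["a", "a", "a", "b", "b", "b"])
        D2 = fixed_d.values**2
        _, codes = np.unique(groups, return_inverse=True)
        f_obs = _permanova_f(D2, codes, 2)
        # oracle: all 20 balanced labelings
        fs = []
        for combo in itertools.combinations(range(6), 3):
            lab = np.zeros(6, dtype=int)
            lab[list(combo)] = 1
            fs.append(_permanova_f(D2, lab, 2))
        p_exact = np.mean([f >= f_obs - 1e-12 for f in fs])
        res = ok.permanova(fixed_d, groups, n_perm=999, seed=5)
        se = np.sqrt(p_exact * (1 - p_exact) / 999)
        assert abs(res.p_value - p_exact) <= 2 * se + 2 / 999

    def test_seed_reproducibility(self, fixed_d):
        groups = ["a", "a", "a", "b", "b", "b"]
        r1 = ok.permanova(fixed_d, groups, n_perm=199, seed=9)
        r2 = ok.permanova(fixed_d, groups, n_perm=199, seed=9)
        assert r1.p_value == r2.p_value and r1.statistic == r2.statistic

    def test_relabeling_invariance(self, fixed_d):
        groups = ["a", "a", "a", "b", "b", "b"]
        flipped = ["b", "b", "b", "a", "a", "a"]
        r1 = ok.permanova(fixed_d, groups, n_perm=199, seed=9)
        r2 = ok.permanova(fixed_d, flipped, n_perm=199, seed=9)
        assert r1.statistic == pytest.approx(r2.statistic)

    def test_duplicated_profiles_no_separation(self):
        base = np.array([[5, 1, 0], [1, 5, 2], [0, 2, 7]])
        cols = np.vstack([base, base])  # each profile present in both groups
        exp = _exp_from_columns(cols)
        D = ok.beta_distance(exp, "bray_curtis")
        groups = ["a", "a", "a", "b", "b", "b"]
        res = ok.permanova(D, groups, n_perm=499, seed=1)
        assert np.isfinite(res.statistic)
        assert res.p_value > 0.2

    def test_matches_scikit_bio(self, cluster_sim):
        """Cross-check the pseudo-F against the independent scikit-bio path."""
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        exp, truth = cluster_sim
        D = ok.beta_distance(exp, "bray_curtis")
        groups = truth.group_labels
        res = ok.permanova(D, groups, n_perm=99, seed=0)
        dm = skbio_stats.DistanceMatrix(D.values, ids=list(D.sample_ids))
        ref = skbio_stats.permanova(dm, grouping=list(groups), permutations=99)
        assert res.statistic == pytest.approx(float(ref["test statistic"]),
                                              rel=1e-9)

    def test_strong_structure_significant(self, cluster_sim):
        exp, truth = cluster_sim
        D = ok.beta_distance(exp, "bray_curtis")
        res = ok.permanova(D, truth.group_labels, n_perm=999, seed=3)
        assert res.p_value <= 0.01

    def test_requires_seed(self, fixed_d):
        with pytest.raises(ValidationError, match="seed"):
            ok.permanova(fixed_d, ["a", "a", "a", "b", "b", "b"], n_perm=99)

    def test_singleton_group_warns(self, fixed_d):
        with pytest.warns(UserWarning, match="singleton"):
            ok.permanova(fixed_d, ["a", "b", "b", "b", "b", "b"],
                         n_perm=99, seed=0)


class TestBetaDivTest:
    def test_block_structure_detected(self):
        n = 5
        vals = np.full((2 * n, 2 * n), 0.9)
        vals[:n, :n] = 0.1
        vals[n:, n:] = 0.1
        np.fill_diagonal(vals, 0.0)
        D = ok.DistanceMatrix(vals, tuple(f"S{i}" for i in range(2 * n)),
                              "bray_curtis")
        groups = ["a"] * n + ["b"] * n
        res = ok.beta_div_test(D, groups, method="wilcoxon")
        assert res.p_value <= 0.05

    def test_permanova_delegation_exact(self, cluster_sim):
        exp, truth = cluster_sim
        D = ok.beta_distance(exp, "bray_curtis")
        direct = ok.permanova(D, truth.group_labels, n_perm=99, seed=4)
        via = ok.beta_div_test(D, truth.group_labels, method="permanova",
                               n_perm=99, seed=4)
        assert direct == via

    def test_all_equal_distances_tie_region(self):
        vals = np.full((8, 8), 0.5)
        np.fill_diagonal(vals, 0.0)
        D = ok.DistanceMatrix(vals, tuple(f"S{i}" for i in range(8)),
                              "bray_curtis")
        res = ok.beta_div_test(D, ["a"] * 4 + ["b"] * 4, method="wilcoxon")
        assert res.p_value > 0.9
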