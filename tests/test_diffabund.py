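import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import otukit as ok
from otukit.diffabund import estimate_variance_prior, moderated_t_fit
from otukit.errors import ValidationError


def _exp(counts_rows, groups, features=None):
    counts_rows = np.asarray(counts_rows)
    features = features or [f"f{i}" for i in range(counts_rows.shape[0])]
    samples = [f"S{j}" for j in range(counts_rows.shape[1])]
    counts = pd.DataFrame(counts_rows, index=features, columns=samples)
    meta = pd.DataFrame({"group": groups}, index=samples)
    return ok.create_experiment(counts, metadata=meta)


class TestSizeFactors:
    def test_identical_samples_unit_factors(self):
        sf = ok.size_factors(pd.DataFrame([[4, 4], [9, 9]],
                                          index=["a", "b"],
                                          columns=["S1", "S2"]))
        np.testing.assert_allclose(sf, [1.0, 1.0])

    def test_doubled_sample_hand_case(self):
        counts = pd.DataFrame([[4, 8], [10, 20], [6, 12]],
                              index=["a", "b", "c"], columns=["S1", "S2"])
        sf = ok.size_factors(counts)
        np.testing.assert_allclose(sf, [1 / np.sqrt(2), np.sqrt(2)], rtol=1e-12)

    def test_single_feature_ratio(self):
        counts = pd.DataFrame([[3, 12]], index=["a"], columns=["S1", "S2"])
        sf = ok.size_factors(counts)
        assert sf["S2"] / sf["S1"] == pytest.approx(4.0)

    def test_geometric_mean_one(self, effect_sim):
        exp, _ = effect_sim
        sf = ok.size_factors(exp.counts)
        assert np.exp(np.mean(np.log(sf))) == pytest.approx(1.0)


class TestExtendedColumns:
    def test_hand_case(self):
        # group1 relabu (0.2, 0.4), group2 (0.1, 0.1) for the first feature
        counts = np.array([[2, 4, 1, 1],
                           [8, 6, 9, 9]])
        exp = _exp(counts, ["g1", "g1", "g2", "g2"])
        cols = ok.da_extended_columns(exp, "group")
        assert cols.loc["f0", "pct_group1"] == pytest.approx(0.3)
        assert cols.loc["f0", "pct_group2"] == pytest.approx(0.1)
        assert cols.loc["f0", "adj_fc"] == pytest.approx(3.0, rel=1e-4)

    def test_absent_in_group2(self):
        counts = np.array([[5, 7, 0, 0], [5, 3, 10, 10]])
        exp = _exp(counts, ["g1", "g1", "g2", "g2"])
        cols = ok.da_extended_columns(exp, "group")
        assert cols.loc["f0", "prev_group2"] == 0.0
        assert cols.loc["f0", "adj_fc"] > 1e4  # large but finite
        assert np.isfinite(cols.loc["f0", "adj_fc"])

    def test_identical_groups_unit_fc(self):
        counts = np.array([[3, 3, 3, 3], [7, 7, 7, 7]])
        exp = _exp(counts, ["g1", "g1", "g2", "g2"])
        cols = ok.da_extended_columns(exp, "group")
        np.testing.assert_allclose(cols["adj_fc"], 1.0)


class TestModeratedT:
    @pytest.fixture()
    def gaussian_null(self):
        rng = np.random.default_rng(8)
        n, p = 16, 300
        Y = rng.normal(0.0, 1.0, size=(p, n))
        X = np.column_stack([np.ones(n),
                             np.repeat([0.0, 1.0], n // 2)])
        return Y, X

    def test_d0_zero_reduces_to_ordinary_t(self, gaussian_null):
        Y, X = gaussian_null
        fit = moderated_t_fit(Y, X, d0_override=0.0)
        a, b = Y[:, X[:, 1] == 0], Y[:, X[:, 1] == 1]
        ref = sps.ttest_ind(a, b, axis=1, equal_var=True)
        np.testing.assert_allclose(np.abs(fit["t"]), np.abs(ref.statistic),
                                   rtol=1e-9)
        np.testing.assert_allclose(fit["p"], ref.pvalue, rtol=1e-9)

    def test_d0_infinite_pools_variance(self, gaussian_null):
        Y, X = gaussian_null
        fit = moderated_t_fit(Y, X, d0_override=np.inf)
        assert fit["s2_post"].nunique() == 1

    def test_null_pvalues_uniform(self, gaussian_null):
        Y, X = gaussian_null
        fit = moderated_t_fit(Y, X)
        ks = sps.kstest(fit["p"], "uniform").statistic
        assert ks < 0.08

    def test_moderation_shrinks_toward_prior(self, gaussian_null):
        Y, X = gaussian_null
        fit = moderated_t_fit(Y, X)
        d0, s0 = fit["d0"].iloc[0], fit["s0_sq"].iloc[0]
        if np.isfinite(d0):
            # posterior variances lie between the observed and the prior
            lo = np.minimum(fit["s2"], s0) - 1e-12
            hi = np.maximum(fit["s2"], s0) + 1e-12
            assert ((fit["s2_post"] >= lo) & (fit["s2_post"] <= hi)).all()

    def test_prior_recovery_on_simulated_variances(self):
        # variances drawn from the scaled-inverse-chi-square model itself
        rng = np.random.default_rng(9)
        d0_true, s0_true, df = 6.0, 2.5, 10
        p = 4000
        true_var = d0_true * s0_true / rng.chisquare(d0_true, size=p)
        s2 = true_var * rng.chisquare(df, size=p) / df
        d0_hat, s0_hat = estimate_variance_prior(s2, df)
        assert d0_hat == pytest.approx(d0_true, rel=0.25)
        assert s0_hat == pytest.approx(s0_true, rel=0.15)


class TestDAPipelines:
    def test_bh_monotone_and_order_invariant(self, effect_sim):
        exp, _ = effect_sim
        config = ok.DAConfig(target="group", method="moderated_t")
        table = ok.da_moderated_t(exp, config)
        assert ((table["p_adj"] >= table["p"] - 1e-12) | table["p"].isna()).all()
        # permuting feature order permutes results identically
        perm_ids = list(exp.feature_ids[::-1])
        exp_perm = exp.pick_features(perm_ids, "keep")
        table_perm = ok.da_moderated_t(exp_perm, config)
        joined = table.join(table_perm, rsuffix="_perm", how="inner")
        np.testing.assert_allclose(joined["p"], joined["p_perm"], rtol=1e-9)

    def test_both_paths_same_feature_set(self, effect_sim):
        exp, _ = effect_sim
        t1 = ok.da_nb_wald(exp, ok.DAConfig(target="group", min_count=2))
        t2 = ok.da_moderated_t(exp, ok.DAConfig(target="group",
                                                method="moderated_t",
                                                min_count=2))
        assert set(t1.index) == set(t2.index)

    def test_paths_agree_in_ranking(self, effect_sim):
        exp, _ = effect_sim
        t1 = ok.da_nb_wald(exp, ok.DAConfig(target="group"))
        t2 = ok.da_moderated_t(exp, ok.DAConfig(target="group",
                                                method="moderated_t"))
        joined = pd.DataFrame({"p1": t1["p"], "p2": t2["p"]}).dropna()
        rho = sps.spearmanr(-np.log10(joined["p1"] + 1e-300),
                            -np.log10(joined["p2"] + 1e-300)).statistic
        assert rho >= 0.8

    def test_nb_wald_sign_matches_group_means(self, effect_sim):
        exp, _ = effect_sim
        table = ok.da_nb_wald(exp, ok.DAConfig(target="group"))
        sf = ok.size_factors(exp.counts)
        norm = exp.counts / sf
        groups = exp.sample_metadata["group"]
        m1 = norm.loc[:, (groups == "group1").to_numpy()].mean(axis=1)
        m2 = norm.loc[:, (groups == "group2").to_numpy()].mean(axis=1)
        conv = table[table["converged"]]
        big = conv[np.abs(conv["log2fc"]) > 0.2]
        diff_sign = np.sign(m2 - m1).loc[big.index]
        assert (np.sign(big["log2fc"]) == diff_sign).mean() > 0.95

    def test_nb_wald_recovers_effect_size(self, effect_sim):
        exp, truth = effect_sim
        table = ok.da_nb_wald(exp, ok.DAConfig(target="group"))
        da = [f for f in truth.da_taxa if f in table.index]
        est = table.loc[da, "log2fc"].mean()
        assert est == pytest.approx(2.0, abs=0.5)

    def test_all_zero_feature_excluded_by_min_count(self):
        counts = np.array([[0, 0, 0, 0], [5, 6, 7, 8], [3, 3, 3, 3]])
        exp = _exp(counts, ["g1", "g1", "g2", "g2"])
        table = ok.da_nb_wald(exp, ok.DAConfig(target="group", min_count=0.5))
        assert "f0" not in table.index

    def test_multilevel_target_rejected(self):
        counts = np.array([[1, 2, 3], [4, 5, 6]])
        exp = _exp(counts, ["a", "b", "c"])
        with pytest.raises(ValidationError, match="2 levels"):
            ok.da_nb_wald(exp, ok.DAConfig(target="group"))

    def test_nb_wald_agrees_with_deseq2_reference(self, effect_sim):
        """Independent NB-GLM oracle: the native Wald path should rank and
        size effects like pyDESeq2 on the same data (equality is a non-goal:
        dispersion shrinkage differs)."""
        pytest.importorskip("pydeseq2")
        import warnings as w
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        exp, _ = effect_sim
        ours = ok.da_nb_wald(exp, ok.DAConfig(target="group", min_count=1))
        with w.catch_warnings():
            w.simplefilter("ignore")
            dds = DeseqDataSet(counts=exp.counts.T,
                               metadata=exp.sample_metadata[["group"]],
                               design="~group", quiet=True)
            dds.deseq2()
            stats = DeseqStats(dds, contrast=["group", "group2", "group1"],
                               quiet=True)
            stats.summary()
        ref = stats.results_df
        joined = pd.DataFrame({
            "p_ours": ours["p"], "p_ref": ref["pvalue"],
            "lfc_ours": ours["log2fc"], "lfc_ref": ref["log2FoldChange"],
        }).dropna()
        rho = sps.spearmanr(joined["p_ours"], joined["p_ref"]).statistic
        assert rho >= 0.9
        r = np.corrcoef(joined["lfc_ours"], joined["lfc_ref"])[0, 1]
        assert r >= 0.95

    def test_covariate_adjustment_accepted(self, effect_sim):
        exp, _ = effect_sim
        table = ok.da_nb_wald(exp, ok.DAConfig(target="group",
                                               covariates=("age",)))
        assert table["converged"].mean() > 0.9
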