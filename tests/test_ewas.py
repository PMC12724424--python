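import numpy as np
import pandas as pd
import pytest
from scipy import stats

from frailmeth.ewas import (
    DesignSpec,
    build_design,
    call_dmps,
    context_enrichment,
    estimate_consensus_correlation,
    fit_probe_models,
    moderate_variances,
    pca_variance_partition,
    run_ewas,
    trigamma_inverse,
)


def _design(n, rng, two_cols=True):
    lfi = rng.normal(-1.5, 0.4, n)
    X = pd.DataFrame({"intercept": 1.0, "logFI": lfi},
                     index=[f"s{i}" for i in range(n)])
    return X


class TestDesign:
    def test_sex_inclusive_group_means_coding(self, discovery):
        X = build_design(discovery.samples, DesignSpec("sex_inclusive"))
        assert list(X.columns) == ["sexF", "sexM", "sexF_logFI", "sexM_logFI"]
        assert ((X["sexF"] + X["sexM"]) == 1.0).all()

    def test_male_t5_excluded_by_default(self, discovery):
        X = build_design(discovery.samples, DesignSpec("sex_inclusive"))
        sheet = discovery.samples.loc[X.index]
        last = discovery.samples["timepoint"].max()
        assert not ((sheet["sex"] == "M") & (sheet["timepoint"] == last)).any()
        X2 = build_design(discovery.samples,
                          DesignSpec("sex_inclusive", drop_male_t5=False))
        assert len(X2) > len(X)

    def test_stratified_single_sex(self, discovery):
        X = build_design(discovery.samples, DesignSpec("female_only"))
        assert (discovery.samples.loc[X.index, "sex"] == "F").all()
        assert list(X.columns) == ["intercept", "logFI"]


class TestGls:
    def test_rho_zero_equals_ols(self, rng):
        n, P = 60, 30
        X = _design(n, rng)
        blocks = np.repeat(np.arange(n // 3), 3)
        M = pd.DataFrame(rng.normal(0, 1, (P, n)), columns=X.index)
        fits = fit_probe_models(M, X, blocks, rho=0.0)
        pinv = np.linalg.pinv(X.to_numpy())
        for i in range(P):
            beta = pinv @ M.iloc[i].to_numpy()
            assert np.allclose(
                fits.iloc[i][["coef_intercept", "coef_logFI"]].to_numpy(),
                beta, atol=1e-10)

    def test_exact_linear_fit_recovered(self, rng):
        n = 40
        X = _design(n, rng)
        blocks = np.arange(n)
        y = 1.0 + 0.3 * X["logFI"].to_numpy()
        M = pd.DataFrame([y], columns=X.index)
        fits = fit_probe_models(M, X, blocks, rho=0.0)
        assert fits["coef_logFI"].iloc[0] == pytest.approx(0.3, abs=1e-10)
        assert fits["s2"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_rank_deficient_design_names_columns(self, rng):
        n = 30
        X = _design(n, rng)
        X["dup"] = X["logFI"]
        M = pd.DataFrame(rng.normal(0, 1, (3, n)), columns=X.index)
        with pytest.raises(ValueError, match="dup"):
            fit_probe_models(M, X, np.arange(n), rho=0.0)

    def test_slope_coverage_with_repeated_measures(self, rng):
        n_mice, k, P = 40, 4, 60
        n = n_mice * k
        blocks = np.repeat(np.arange(n_mice), k)
        lfi = rng.normal(-1.5, 0.4, n)
        X = pd.DataFrame({"intercept": 1.0, "logFI": lfi},
                         index=[f"s{i}" for i in range(n)])
        mouse_eff = rng.normal(0, 0.4, n_mice)[blocks]
        M = pd.DataFrame(
            0.3 * lfi + mouse_eff + rng.normal(0, 0.3, (P, n)),
            columns=X.index,
        )
        rho, n_used = estimate_consensus_correlation(M, X, blocks)
        fits = fit_probe_models(M, X, blocks, rho=rho)
        se = np.sqrt(fits["s2"] * fits["uvar_logFI"])
        covered = np.abs(fits["coef_logFI"] - 0.3) < 2 * se
        assert covered.mean() >= 0.9


class TestConsensusCorrelation:
    def test_recovers_planted_block_correlation(self, rng):
        n_mice, k, P = 40, 4, 400
        blocks = np.repeat(np.arange(n_mice), k)
        n = n_mice * k
        X = pd.DataFrame({"intercept": np.ones(n)},
                         index=[f"s{i}" for i in range(n)])
        # block correlation 0.5: equal variance split
        mouse = rng.normal(0, 1, (P, n_mice))[:, blocks]
        noise = rng.normal(0, 1, (P, n))
        M = pd.DataFrame(mouse + noise, columns=X.index)
        rho, _ = estimate_consensus_correlation(M, X, blocks)
        assert 0.4 <= rho <= 0.6

    def test_independent_noise_gives_near_zero(self, rng):
        n_mice, k, P = 40, 4, 400
        blocks = np.repeat(np.arange(n_mice), k)
        n = n_mice * k
        X = pd.DataFrame({"intercept": np.ones(n)},
                         index=[f"s{i}" for i in range(n)])
        M = pd.DataFrame(rng.normal(0, 1, (P, n)), columns=X.index)
        rho, _ = estimate_consensus_correlation(M, X, blocks)
        assert abs(rho) < 0.05

    def test_singleton_blocks_return_zero(self, rng):
        n = 30
        X = pd.DataFrame({"intercept": np.ones(n)},
                         index=[f"s{i}" for i in range(n)])
        M = pd.DataFrame(rng.normal(0, 1, (20, n)), columns=X.index)
        with pytest.warns(UserWarning, match="singleton"):
            rho, n_used = estimate_consensus_correlation(M, X, np.arange(n))
        assert rho == 0.0


class TestModeration:
    def test_identical_variances_degenerate(self):
        s2 = np.full(50, 0.7)
        d0, s02, post = moderate_variances(s2, 10.0)
        assert d0 >= 1e6
        assert s02 == pytest.approx(0.7, rel=0.05)
        assert np.allclose(post, s02, rtol=0.05)

    def test_prior_df_recovered(self, rng):
        # s^2 ~ s0^2 * chi2_d / d marginally with prior d0=4, s0^2=1
        d, d0, s02, P = 10, 4.0, 1.0, 5000
        true_var = s02 * d0 / rng.chisquare(d0, P) * rng.chisquare(d, P) / d
        d0_hat, s02_hat, _ = moderate_variances(true_var, float(d))
        assert 3.0 <= d0_hat <= 5.0
        assert 0.8 <= s02_hat <= 1.2

    def test_few_probes_rejected(self):
        with pytest.raises(ValueError):
            moderate_variances(np.ones(5), 10.0)

    def test_trigamma_inverse_inverts(self):
        from scipy.special import polygamma

        for x in (0.05, 0.5, 2.0, 20.0):
            y = trigamma_inverse(x)
            assert polygamma(1, y) == pytest.approx(x, rel=1e-8)

    def test_moderation_off_equals_ordinary_t(self, discovery):
        res_mod = run_ewas(discovery, DesignSpec("female_only"), moderate=False)
        tab = res_mod.table
        # with d0 = 0, posterior variance equals the per-probe s2
        valid = tab["s2"] > 0
        assert np.allclose(tab.loc[valid, "post_var"],
                           tab.loc[valid, "s2"], rtol=1e-12)


class TestDmpsAndContext:
    def test_planted_effects_recovered(self, discovery, cohort):
        res = run_ewas(discovery, DesignSpec("sex_inclusive"))
        dmps = call_dmps(res)
        lab = cohort.truth.probe_labels
        reg = cohort.truth.regions.set_index("region_id")
        dual = reg.index[reg["cls"] == "dual"]
        dual_probes = [p for p in lab.index[lab["region_id"].isin(dual)]
                       if p in res.table.index]
        recall = np.mean([p in set(dmps) for p in dual_probes])
        assert recall >= 0.8

    def test_empty_dmp_set_allowed(self, rng):
        tab = pd.DataFrame({"adj_p": [0.5, 0.9]},
                           index=pd.Index(["a", "b"]))
        assert len(call_dmps(tab)) == 0

    def test_chi2_hand_value(self):
        # table [[10,90],[50,50]]: E = [[30,70],[30,70]], so
        # chi2 = 400/30 + 400/70 + 400/30 + 400/70 = 38.095 (3 dp)
        ann = pd.DataFrame({
            "island_relation": ["island"] * 60 + ["open_sea"] * 140,
            "tss_relation": "body",
            "chrom": "chr1",
        }, index=[f"p{i}" for i in range(200)])
        # DMPs: 10 in islands, 90 outside; non-DMPs: 50 in, 50 out
        dmp_ids = [f"p{i}" for i in range(10)] + [f"p{i}" for i in range(110, 200)]
        ann2 = ann.copy()
        out = context_enrichment(pd.Index(dmp_ids), ann2, "island")
        assert out["chi2"] == pytest.approx(800 / 30 + 800 / 70, rel=1e-12)

    def test_equal_proportions_zero(self):
        ann = pd.DataFrame({
            "island_relation": ["island", "open_sea"] * 50,
            "tss_relation": "body", "chrom": "chr1",
        }, index=[f"p{i}" for i in range(100)])
        # 25 islands + 25 open-sea: DMP island proportion matches the universe
        dmps = pd.Index([f"p{i}" for i in range(50)])
        out = context_enrichment(dmps, ann, "island")
        assert out["chi2"] == pytest.approx(0.0, abs=1e-9)

    def test_doubling_cells_doubles_chi2(self):
        def build(factor):
            n_is, n_os = 30 * factor, 70 * factor
            ann = pd.DataFrame({
                "island_relation": ["island"] * n_is + ["open_sea"] * n_os,
                "tss_relation": "body", "chrom": "chr1",
            }, index=[f"p{i}" for i in range(n_is + n_os)])
            dmps = pd.Index([f"p{i}" for i in range(5 * factor)]
                            + [f"p{i}" for i in range(n_is, n_is + 50 * factor)])
            return context_enrichment(dmps, ann, "island")["chi2"]

        assert build(2) == pytest.approx(2 * build(1), rel=1e-9)


class TestPcaPartition:
    def test_pure_sex_effect_dominates(self, rng):
        n, P = 80, 300
        sex = np.array(["F", "M"])[rng.integers(0, 2, n)]
        M = rng.normal(0, 0.05, (P, n))
        M[: P // 2] += 2.0 * (sex == "M")
        Mdf = pd.DataFrame(M, columns=[f"s{i}" for i in range(n)])
        samples = pd.DataFrame({
            "mouse_id": [f"m{i}" for i in range(n)],
            "sex": sex, "timepoint": 1, "age_months": rng.uniform(20, 34, n),
            "fi": rng.uniform(0.1, 0.4, n),
        }, index=Mdf.columns)
        out = pca_variance_partition(Mdf, samples,
                                     factors=("sex", "age", "fi_residual"))
        assert out["shares"]["sex"] >= 0.9
        assert out["shares"]["age"] <= 0.05

    def test_independent_factor_share_near_zero(self, rng):
        n, P = 150, 200
        Mdf = pd.DataFrame(rng.normal(0, 1, (P, n)),
                           columns=[f"s{i}" for i in range(n)])
        samples = pd.DataFrame({
            "mouse_id": [f"m{i}" for i in range(n)],
            "sex": np.array(["F", "M"])[rng.integers(0, 2, n)],
            "timepoint": 1,
            "age_months": rng.uniform(20, 34, n),
            "fi": rng.uniform(0.1, 0.4, n),
        }, index=Mdf.columns)
        out = pca_variance_partition(Mdf, samples, factors=("sex", "age"))
        assert out["shares"]["age"] < 0.02

    def test_retained_weights_reach_threshold(self, discovery):
        M = discovery.m_values().iloc[:400]
        out = pca_variance_partition(M, discovery.samples,
                                     var_threshold=0.95)
        assert out["pc_weights"].sum() >= 0.95

    def test_constant_factor_warns_share_zero(self, rng):
        n, P = 40, 50
        Mdf = pd.DataFrame(rng.normal(0, 1, (P, n)),
                           columns=[f"s{i}" for i in range(n)])
        samples = pd.DataFrame({
            "mouse_id": [f"m{i}" for i in range(n)], "sex": "F",
            "timepoint": 1, "age_months": rng.uniform(20, 30, n),
            "fi": rng.uniform(0.1, 0.4, n),
        }, index=Mdf.columns)
        with pytest.warns(UserWarning, match="constant"):
            out = pca_variance_partition(Mdf, samples, factors=("sex", "age"))
        assert out["shares"]["sex"] == 0.0
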