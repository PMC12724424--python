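import numpy as np
import pandas as pd
import pytest

from frailmeth.classify import (
    assemble_joint_set,
    classify_dmrs,
    classify_labels,
    fit_dmr_lmm,
    make_long,
    merge_intervals,
    sex_interaction_scan,
    sex_residualize,
)
from frailmeth.lmm import fit_reml


def _long(rng, n_mice=45, n_t=4, n_cpg=6, slope=0.0, mouse_sd=0.2,
          sample_sd=0.0, noise_sd=0.25, sex_slopes=None):
    rows = []
    ages = np.linspace(21, 30, n_t)
    for i in range(n_mice):
        sex = "F" if i % 2 else "M"
        u = rng.normal(0, mouse_sd)
        for t in range(n_t):
            lfi = rng.normal(-1.5, 0.4)
            s_eff = rng.normal(0, sample_sd)
            b = slope if sex_slopes is None else sex_slopes[sex]
            base = b * lfi + u + s_eff
            for c in range(n_cpg):
                rows.append({
                    "cpg_id": f"c{c}", "sample_id": f"m{i}_T{t}",
                    "mouse_id": f"m{i}", "sex": sex, "age": ages[t],
                    "age_months": ages[t], "fi": np.exp(lfi),
                    "logFI": lfi,
                    "M": base + rng.normal(0, noise_sd),
                })
    return pd.DataFrame(rows)


class TestSexResidualize:
    def test_recenters_group_means(self):
        M = pd.DataFrame([[1.0, 1.0, 3.0, 3.0]], columns=list("abcd"))
        samples = pd.DataFrame({"sex": ["F", "F", "M", "M"]},
                               index=list("abcd"))
        out = sex_residualize(M, samples)
        assert np.allclose(out.to_numpy(), 2.0)

    def test_no_sex_effect_is_identity(self, rng):
        M = pd.DataFrame(rng.normal(0, 1, (10, 30)),
                         columns=[f"s{i}" for i in range(30)])
        samples = pd.DataFrame({"sex": ["F", "M"] * 15}, index=M.columns)
        base = M.copy()
        for s, cols in samples.groupby("sex").groups.items():
            pass
        out = sex_residualize(M, samples)
        # re-residualizing is a projection: applying twice changes nothing
        out2 = sex_residualize(out, samples)
        assert np.allclose(out.to_numpy(), out2.to_numpy(), atol=1e-12)

    def test_planted_shift_removed(self, rng):
        n = 60
        sex = np.array(["F"] * 30 + ["M"] * 30)
        M = pd.DataFrame(rng.normal(0, 1, (20, n))
                         + 0.8 * (sex == "M")[None, :],
                         columns=[f"s{i}" for i in range(n)])
        samples = pd.DataFrame({"sex": sex}, index=M.columns)
        out = sex_residualize(M, samples).to_numpy()
        male = out[:, sex == "M"].mean(axis=1)
        female = out[:, sex == "F"].mean(axis=1)
        assert np.allclose(male, female, atol=1e-10)

    def test_single_sex_errors(self, rng):
        M = pd.DataFrame(rng.normal(0, 1, (3, 4)),
                         columns=[f"s{i}" for i in range(4)])
        samples = pd.DataFrame({"sex": ["F"] * 4}, index=M.columns)
        with pytest.raises(ValueError):
            sex_residualize(M, samples)


class TestRegionLmm:
    def test_matches_statsmodels_on_mouse_intercept_reduction(self, rng):
        import statsmodels.api as sm

        long = _long(rng, n_cpg=1)
        fit = fit_dmr_lmm(long, ["intercept", "logFI"], "logFI")
        X = np.column_stack([np.ones(len(long)), long["logFI"]])
        md = sm.regression.mixed_linear_model.MixedLM(
            long["M"].to_numpy(), X, groups=long["mouse_id"].to_numpy())
        ref = md.fit(reml=True)
        assert fit.params["logFI"] == pytest.approx(ref.params[1], abs=1e-4)
        assert fit.bse["logFI"] == pytest.approx(ref.bse[1], rel=1e-2)

    def test_zero_random_variance_reduces_to_ols(self, rng):
        long = _long(rng, mouse_sd=0.0, n_cpg=3, slope=0.4)
        fit = fit_dmr_lmm(long, ["intercept", "logFI"], "logFI",
                          sample_effect=False)
        X = np.column_stack([np.ones(len(long)), long["logFI"]])
        beta = np.linalg.lstsq(X, long["M"].to_numpy(), rcond=None)[0]
        assert fit.params["logFI"] == pytest.approx(beta[1], abs=5e-3)

    def test_type_i_error_calibrated(self, rng):
        rejections = 0
        reps = 120
        for r in range(reps):
            long = _long(np.random.default_rng(1000 + r), n_mice=30, n_cpg=4,
                         slope=0.0, sample_sd=0.15)
            fit = fit_dmr_lmm(long, ["intercept", "logFI"], "logFI")
            rejections += fit.pvalues["logFI"] < 0.05
        rate = rejections / reps
        assert 0.01 <= rate <= 0.10

    def test_planted_slope_coverage(self, rng):
        covered = 0
        reps = 40
        for r in range(reps):
            g = np.random.default_rng(2000 + r)
            long = _long(g, slope=0.4, n_cpg=5)
            fit = fit_dmr_lmm(long, ["intercept", "logFI"], "logFI")
            lo, hi = fit.conf_int("logFI")
            covered += lo <= 0.4 <= hi
        assert covered / reps >= 0.9

    def test_too_few_mice_rejected(self, rng):
        long = _long(rng, n_mice=2)
        with pytest.raises(ValueError, match="3 mice"):
            fit_dmr_lmm(long, ["intercept", "logFI"], "logFI")


class TestClassification:
    @pytest.mark.parametrize(
        "aifi,adfi,expected",
        [(0.01, 0.40, "aiDMR"), (0.01, 0.01, "dualDMR"),
         (0.40, 0.01, "adDMR"), (0.40, 0.40, "none")],
    )
    def test_label_rules(self, aifi, adfi, expected):
        assert classify_labels([aifi], [adfi], alpha=0.05)[0] == expected

    def test_classify_dmrs_table(self):
        aifi = pd.DataFrame({"coef": [0.5, 0.1], "adj_p": [0.01, 0.4]},
                            index=["d1", "d2"])
        adfi = pd.DataFrame({"coef": [0.2, 0.3], "adj_p": [0.4, 0.01]},
                            index=["d1", "d2"])
        out = classify_dmrs(aifi, adfi)
        assert out.loc["d1", "class"] == "aiDMR"
        assert out.loc["d2", "class"] == "adDMR"

    def test_mismatched_sets_error(self):
        aifi = pd.DataFrame({"coef": [0.5], "adj_p": [0.01]}, index=["d1"])
        adfi = pd.DataFrame({"coef": [0.5], "adj_p": [0.01]}, index=["d2"])
        with pytest.raises(ValueError):
            classify_dmrs(aifi, adfi)

    def test_count_arithmetic(self, rng):
        labels = classify_labels(rng.uniform(0, 0.2, 100),
                                 rng.uniform(0, 0.2, 100))
        ai_assoc = np.sum(labels == "aiDMR") + np.sum(labels == "dualDMR")
        ad_assoc = np.sum(labels == "adDMR") + np.sum(labels == "dualDMR")
        total_fi = np.sum(labels != "none")
        assert ai_assoc + ad_assoc - np.sum(labels == "dualDMR") == total_fi


class TestSexInteraction:
    def _scan(self, rng, sex_slopes, n_mice=45):
        long = _long(rng, n_mice=n_mice, n_cpg=4, sex_slopes=sex_slopes)
        M_wide = long.pivot_table(index="cpg_id", columns="sample_id",
                                  values="M")
        samples = long.drop_duplicates("sample_id").set_index("sample_id")[
            ["mouse_id", "sex", "age_months", "fi"]]
        return sex_interaction_scan(M_wide, {"d1": list(M_wide.index)},
                                    samples.loc[M_wide.columns])

    def test_equal_slopes_interaction_null(self, rng):
        rej = 0
        for r in range(25):
            out = self._scan(np.random.default_rng(300 + r),
                             {"F": 0.4, "M": 0.4})
            rej += out["interaction_p"].iloc[0] < 0.05
        assert rej / 25 <= 0.2

    def test_opposite_slopes_detected(self):
        hits, conc = 0, []
        for r in range(10):
            out = self._scan(np.random.default_rng(400 + r),
                             {"F": 0.5, "M": -0.5})
            hits += out["interaction_p"].iloc[0] < 0.05
            conc.append(out["concordance"].iloc[0])
        assert hits / 10 >= 0.9
        assert conc.count("opposite") >= 9

    def test_null_slopes_near_zero(self):
        out = self._scan(np.random.default_rng(7), {"F": 0.0, "M": 0.0})
        assert abs(out["female_effect"].iloc[0]) < 0.15
        assert abs(out["male_effect"].iloc[0]) < 0.15


class TestJointSet:
    def _cls(self, ids, classes):
        return pd.DataFrame({"class": classes}, index=pd.Index(ids, name="dmr_id"))

    def test_provenance_categories(self):
        tables = {
            "sex_inclusive": self._cls(["chr1:100-200", "chr2:10-90"],
                                       ["aiDMR", "adDMR"]),
            "female": self._cls(["chr1:100-200", "chr3:5-50"],
                                ["adDMR", "dualDMR"]),
            "male": self._cls(["chr1:100-200"], ["aiDMR"]),
        }
        joint, merged = assemble_joint_set(tables)
        prov = joint.set_index("dmr_id")["provenance"]
        assert prov["chr1:100-200"] == "both_sexes"
        assert prov["chr3:5-50"] == "female_only"
        assert prov["chr2:10-90"] == "inclusive_only"

    def test_interval_merge(self):
        tables = {
            "female": self._cls(["chr1:100-200", "chr1:150-300",
                                 "chr1:500-600"], ["adDMR"] * 3),
        }
        joint, merged = assemble_joint_set(tables)
        assert len(merged) == 2
        first = merged.iloc[0]
        assert (first["start"], first["end"]) == (100, 300)

    def test_none_class_excluded(self):
        tables = {"female": self._cls(["chr1:1-2"], ["none"])}
        joint, merged = assemble_joint_set(tables)
        assert len(joint) == 0
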