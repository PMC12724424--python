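import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from frailmeth.core_data import validate_sample_sheet
from frailmeth.simulate import (
    CohortPlan,
    SimConfig,
    SyntheticTruth,
    apply_mortality,
    expected_item_score,
    simulate_cohort,
    simulate_frailty,
    simulate_methylation,
    simulate_planted_outcome,
)
from tests.conftest import small_config


class TestFrailtyTrajectories:
    def test_fi_on_grid(self, cohort):
        fi = cohort.matrix.samples["fi"].to_numpy()
        assert np.allclose((fi * 62) % 1, 0, atol=1e-9)

    def test_sheet_invariants_hold(self, cohort):
        validate_sample_sheet(cohort.matrix.samples)

    def test_mean_fi_increases_without_noise(self):
        cfg = small_config(mouse_frailty_sd=0.0, q_step_sd=0.0,
                           hazard_intercept=-50.0)
        sheet, _ = simulate_frailty(cfg, seed=0)
        means = sheet.groupby("timepoint")["fi"].mean()
        assert (np.diff(means.to_numpy()) > 0).all()

    def test_mean_fi_matches_analytic_scoring_rule(self):
        # calibrate the latent trajectory to hit a target mean item score at
        # the last age, then check the simulated mean FI against it
        cfg = small_config(mouse_frailty_sd=0.0, q_step_sd=0.0,
                           hazard_intercept=-50.0,
                           fi_intercept=-2.6, fi_age_slope=0.08)
        eta_last = cfg.fi_intercept + cfg.fi_age_slope * cfg.timepoint_ages[-1]
        target = float(expected_item_score(eta_last, cfg))
        fis = []
        for rep in range(20):
            sheet, _ = simulate_frailty(cfg, seed=rep)
            last = sheet[sheet["timepoint"] == 5]
            fis.append(last["fi"].mean())
        assert np.mean(fis) == pytest.approx(target, abs=0.01)

    def test_fixed_seed_reproducible(self):
        a, _ = simulate_frailty(small_config(), seed=4)
        b, _ = simulate_frailty(small_config(), seed=4)
        pd.testing.assert_frame_equal(a, b)


class TestMortality:
    def test_no_deaths_with_tiny_hazard(self):
        sheet, _ = simulate_frailty(small_config(), seed=1)
        out = apply_mortality(sheet, 0, hazard_intercept=-100.0)
        assert not out["dead"].any()
        assert len(out) == len(sheet)

    def test_all_die_with_huge_hazard(self):
        sheet, _ = simulate_frailty(small_config(), seed=1)
        out = apply_mortality(sheet, 0, hazard_intercept=100.0)
        assert (out.groupby("mouse_id").size() == 1).all()
        assert out["dead"].all()

    def test_dead_mice_have_no_later_records(self, cohort):
        sheet = cohort.matrix.samples
        for _, grp in sheet[sheet["dead"]].groupby("mouse_id"):
            assert (grp["age_months"] <= grp["age_at_death"] + 1e-9).all()

    def test_frail_mice_die_more(self):
        # Kendall correlation between FI and subsequent death over replicates
        taus = []
        for rep in range(20):
            sheet, _ = simulate_frailty(small_config(), seed=rep)
            out = apply_mortality(sheet, rep, hazard_intercept=-2.5,
                                  hazard_fi_slope=6.0)
            first = out[out["timepoint"] == 1]
            died = first["dead"].astype(float)
            if died.nunique() < 2:
                continue
            taus.append(stats.kendalltau(first["fi"], died).statistic)
        assert np.mean(taus) > 0


class TestMethylation:
    def test_betas_in_unit_interval(self, cohort):
        vals = cohort.matrix.betas.to_numpy()
        ok = np.isnan(vals) | ((vals >= 0) & (vals <= 1))
        assert ok.all()

    def test_regions_span_within_limit(self, cohort):
        reg = cohort.truth.regions
        assert ((reg["end"] - reg["start"]) <= small_config().regions.max_span).all()

    def test_region_comethylation_exceeds_background(self, cohort):
        mat, truth = cohort.matrix, cohort.truth
        lab = truth.probe_labels
        M = mat.m_values()

        def mean_pairwise_corr(probe_ids):
            sub = M.loc[probe_ids].T
            c = sub.corr().to_numpy()
            iu = np.triu_indices_from(c, k=1)
            return np.nanmean(c[iu])

        region_corrs = []
        for rid, grp in lab[lab["region_id"] != ""].groupby("region_id"):
            region_corrs.append(mean_pairwise_corr(list(grp.index)[:6]))
        bg = list(lab.index[lab["kind"] == "background"])[:40]
        bg_corr = mean_pairwise_corr(bg)
        assert np.mean(region_corrs) > bg_corr + 0.2

    def test_planted_age_slope_recovered_by_ols(self):
        cfg = small_config(missing_rate=0.0)
        res = simulate_cohort(cfg, seed=3)
        truth, mat = res.truth, res.matrix
        reg = truth.regions.set_index("region_id")
        lab = truth.probe_labels
        M = mat.m_values()
        age = mat.samples["age_months"].to_numpy() - cfg.age_center
        hits, total = 0, 0
        for rid in reg.index[reg["cls"] == "ad"]:
            alpha = reg.loc[rid, "alpha"]
            for probe in lab.index[lab["region_id"] == rid][:2]:
                y = M.loc[probe].to_numpy()
                res_ = stats.linregress(age, y)
                total += 1
                hits += abs(res_.slope - alpha) < 2.5 * res_.stderr
        assert hits / total >= 0.8

    def test_chrx_dosage_patterns(self, cohort):
        mat, truth = cohort.matrix, cohort.truth
        lab = truth.probe_labels
        sex = mat.samples["sex"]
        f_cols = sex.index[sex == "F"]
        m_cols = sex.index[sex == "M"]
        subj = lab.index[lab["xci_class"] == "subject"]
        esc = lab.index[lab["xci_class"] == "escape"]
        bet = cohort.matrix.betas
        assert bet.loc[subj, f_cols].mean(axis=1).between(0.3, 0.6).all()
        assert (bet.loc[subj, m_cols].mean(axis=1) < 0.15).all()
        assert (bet.loc[esc, f_cols].mean(axis=1) < 0.15).all()
        assert (bet.loc[esc, m_cols].mean(axis=1) < 0.15).all()

    def test_fixed_seed_identical_matrices(self):
        cfg = small_config()
        a = simulate_cohort(cfg, seed=8)
        b = simulate_cohort(cfg, seed=8)
        pd.testing.assert_frame_equal(a.matrix.betas, b.matrix.betas)

    def test_null_effects_give_uniform_pvalues(self):
        # with all effect sizes zero, per-probe regression of M on logFI is null
        cfg = small_config(q_effect=0.0, age_effect=0.0, n_background=800,
                           cohorts=(CohortPlan("discovery", 20, 25, "control"),))
        res = simulate_cohort(cfg, seed=5)
        mat = res.matrix
        lab = res.truth.probe_labels
        bg = [p for p in lab.index[(lab["kind"] == "background") & ~lab["is_vmp"]]
              if p in mat.betas.index]
        M = mat.m_values()
        lfi = np.log(np.maximum(mat.samples["fi"].to_numpy(), 0.5 / 62))
        # one mouse-level observation per probe avoids repeated-measure
        # correlation: use first timepoint only
        first = mat.samples.index[mat.samples["timepoint"] == 1]
        lfi1 = np.log(np.maximum(mat.samples.loc[first, "fi"].to_numpy(), 0.5 / 62))
        pvals = []
        for probe in bg:
            y = M.loc[probe, first].to_numpy()
            mask = ~np.isnan(y)
            res_ = stats.linregress(lfi1[mask], y[mask])
            pvals.append(res_.pvalue)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestTruth:
    def test_labels_partition_regions(self, cohort):
        lab = cohort.truth.probe_labels
        planted = lab[lab["region_id"] != ""]
        counts = planted.groupby("region_id").size()
        reg = cohort.truth.regions.set_index("region_id")
        assert (counts == reg["n_probes"]).all()

    def test_truth_round_trips_through_json(self, tmp_path, cohort):
        path = tmp_path / "truth.json"
        cohort.truth.to_json(path)
        back = SyntheticTruth.from_json(path)
        pd.testing.assert_frame_equal(
            back.regions, cohort.truth.regions, check_dtype=False
        )
        assert list(back.probe_labels.index) == list(cohort.truth.probe_labels.index)
        assert np.allclose(back.latent["q"], cohort.truth.latent["q"])


class TestPlantedOutcome:
    def test_lagged_coefficient_construction(self):
        sheet, summ = simulate_planted_outcome(coef=0.5, noise_sd=0.0,
                                               n_dmrs=1, seed=0)
        # for every mouse with >= 3 assessments, dlogFI(c->f) = 0.5 * dM(p->c)
        lfi = np.log(sheet["fi"])
        for mouse, grp in sheet.groupby("mouse_id"):
            grp = grp.sort_values("timepoint")
            if len(grp) < 3:
                continue
            m = summ.loc["d0", grp.index].to_numpy()
            l = np.log(grp["fi"].to_numpy())
            for t in range(1, len(grp) - 1):
                planted = 0.5 * (m[t] - m[t - 1])
                observed = l[t + 1] - l[t]
                # probe noise on the summary is 0.02
                assert observed == pytest.approx(planted, abs=0.05)
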