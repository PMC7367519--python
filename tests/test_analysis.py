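"""Effect estimators: design derivation, ANCOVA, delay-control LMM, power."""

import dataclasses
import warnings

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from actitrial.analysis import (
    AnalysisError,
    ancova_adjusted_difference,
    build_analysis_dataset,
    estimate_all,
    fit_delay_control_lmm,
    power_two_sample,
)
from actitrial.synth import TrialConfig, generate_trial

warnings.filterwarnings("ignore", message=".*convergence.*")


def _trial_dataset(cfg):
    trial = generate_trial(cfg, write_epochs=False)
    return build_analysis_dataset(trial.summaries, trial.roster,
                                  trial.questionnaires), trial


class TestBuildAnalysisDataset:
    def make_inputs(self):
        roster = pd.DataFrame(
            {"participant_id": ["P1", "P2"], "arm": ["IG", "DG"], "block_id": [1, 1]}
        )
        summaries = pd.DataFrame(
            {
                "participant_id": ["P1"] * 4 + ["P2"] * 4,
                "week": [0, 13, 26, 39] * 2,
                "outcome": "mvpa_bout_minutes",
                "value": 1.0,
            }
        )
        return summaries, roster

    def test_exposure_derivation(self):
        summaries, roster = self.make_inputs()
        ds = build_analysis_dataset(summaries, roster)
        exp = ds.set_index(["participant_id", "week"])["exposure"]
        assert exp.loc[("P1", 13)] == 12          # immediate arm at endpoint
        assert exp.loc[("P2", 13)] == 0           # delay arm not yet exposed
        assert exp.loc[("P1", 39)] == 38
        assert exp.loc[("P2", 39)] == 25
        assert (ds.loc[ds["week"] == 0, "exposure"] == 0).all()

    def test_unrostered_participant_rejected(self):
        summaries, roster = self.make_inputs()
        summaries.loc[0, "participant_id"] = "P9"
        with pytest.raises(AnalysisError, match="no roster entry"):
            build_analysis_dataset(summaries, roster)

    def test_duplicate_rows_rejected(self):
        summaries, roster = self.make_inputs()
        dup = pd.concat([summaries, summaries.iloc[[0]]], ignore_index=True)
        with pytest.raises(AnalysisError, match="duplicated"):
            build_analysis_dataset(dup, roster)


class TestAncova:
    def test_matches_normal_equations_oracle(self, paper_scale_config):
        ds, trial = _trial_dataset(paper_scale_config)
        est = ancova_adjusted_difference(ds, "mvpa_bout_minutes")
        # independent least-squares solve of the same design
        rows = ds[ds["outcome"] == "mvpa_bout_minutes"]
        wide = rows.pivot_table(index="participant_id", columns="week",
                                values="value").dropna(subset=[0, 13])
        arm = trial.roster.set_index("participant_id").loc[wide.index, "arm"]
        X = np.column_stack([
            np.ones(len(wide)), (arm == "IG").to_numpy(float), wide[0].to_numpy()
        ])
        beta = np.linalg.solve(X.T @ X, X.T @ wide[13].to_numpy())
        assert est.estimate == pytest.approx(beta[1], abs=1e-8)

    def test_symmetric_arms_zero_effect(self, noiseless_config):
        cfg = dataclasses.replace(
            noiseless_config, participant_sd=12.0,
            baseline_mean_by_arm={"IG": 50.0, "DG": 50.0},
            true_exposure_effects={0: 0.0, 12: 0.0, 25: 0.0, 38: 0.0},
            n_per_arm=8,
        )
        ds, _ = _trial_dataset(cfg)
        est = ancova_adjusted_difference(ds, "mvpa_bout_minutes")
        assert est.estimate == pytest.approx(0.0, abs=1e-8)

    def test_noiseless_recovery_of_effect(self, noiseless_config):
        # latent values stay >=10 so the day-target snap cannot distort them
        cfg = dataclasses.replace(
            noiseless_config, participant_sd=10.0,
            baseline_mean_by_arm={"IG": 60.0, "DG": 60.0}, n_per_arm=10,
        )
        ds, _ = _trial_dataset(cfg)
        est = ancova_adjusted_difference(ds, "mvpa_bout_minutes")
        assert est.estimate == pytest.approx(13.0, abs=1e-6)

    def test_constant_shift_invariance(self, paper_scale_config):
        ds, _ = _trial_dataset(paper_scale_config)
        est1 = ancova_adjusted_difference(ds, "mvpa_bout_minutes")
        shifted = ds.copy()
        shifted["value"] = shifted["value"] + 1000.0
        est2 = ancova_adjusted_difference(shifted, "mvpa_bout_minutes")
        assert est2.estimate == pytest.approx(est1.estimate, abs=1e-8)

    def test_degenerate_baseline_named(self, noiseless_config):
        ds, _ = _trial_dataset(dataclasses.replace(noiseless_config, n_per_arm=5))
        # participant_sd = 0 makes each arm's baseline constant, but the two
        # arms differ (40 vs 60), so variance is nonzero; force degeneracy:
        flat = ds.copy()
        flat.loc[flat["week"] == 0, "value"] = 50.0
        with pytest.raises(AnalysisError, match="zero variance"):
            ancova_adjusted_difference(flat, "mvpa_bout_minutes")

    def test_too_few_cases_rejected(self):
        cfg = TrialConfig(n_per_arm=2, dropout_rate=0.0, seed=3)
        ds, _ = _trial_dataset(cfg)
        with pytest.raises(AnalysisError, match=">=3"):
            ancova_adjusted_difference(ds, "mvpa_bout_minutes")

    def test_block_adjustment_runs(self, paper_scale_config):
        ds, _ = _trial_dataset(paper_scale_config)
        est = ancova_adjusted_difference(ds, "mvpa_bout_minutes", adjust_block=True)
        assert np.isfinite(est.estimate)


class TestDelayControlLMM:
    def test_noiseless_saturated_recovery(self, noiseless_config):
        ds, _ = _trial_dataset(noiseless_config)
        terms = {e.term: e.estimate
                 for e in fit_delay_control_lmm(ds, "mvpa_bout_minutes")}
        assert terms["intercept"] == pytest.approx(60.0, abs=1e-6)
        assert terms["group_IG"] == pytest.approx(-20.0, abs=1e-6)
        assert terms["T_week13"] == pytest.approx(5.0, abs=1e-6)
        assert terms["T_week26"] == pytest.approx(8.0, abs=1e-6)
        assert terms["T_week39"] == pytest.approx(3.0, abs=1e-6)
        assert terms["E_12wk"] == pytest.approx(13.0, abs=1e-6)
        assert terms["E_25wk"] == pytest.approx(6.0, abs=1e-6)
        assert terms["E_38wk"] == pytest.approx(4.0, abs=1e-6)
        assert terms["T_week26_vs_week13"] == pytest.approx(3.0, abs=1e-6)

    def test_zero_random_intercept_variance_equals_ols(self, paper_scale_config):
        ds, _ = _trial_dataset(paper_scale_config)
        rows = ds[ds["outcome"] == "mvpa_bout_minutes"].dropna(subset=["value"])
        ests = fit_delay_control_lmm(ds, "mvpa_bout_minutes", random_intercept=False,
                                     emit_trend_contrasts=False)
        import statsmodels.api as sm

        y = rows["value"].to_numpy(float)
        X = np.column_stack(
            [np.ones(len(rows)), (rows["arm"] == "IG").to_numpy(float)]
            + [(rows["week"] == w).to_numpy(float) for w in (13, 26, 39)]
            + [(rows["exposure"] == e).to_numpy(float) for e in (12, 25, 38)]
        )
        beta = sm.OLS(y, X).fit().params
        for i, e in enumerate(ests):
            assert e.estimate == pytest.approx(beta[i], abs=1e-6)

    def test_sandwich_invariant_to_participant_relabeling(self, paper_scale_config):
        ds, _ = _trial_dataset(paper_scale_config)
        base = {e.term: e.se for e in fit_delay_control_lmm(ds, "mvpa_bout_minutes")}
        relabeled = ds.copy()
        mapping = {p: f"Z{i:03d}" for i, p in
                   enumerate(sorted(ds["participant_id"].unique(), reverse=True))}
        relabeled["participant_id"] = relabeled["participant_id"].map(mapping)
        new = {e.term: e.se
               for e in fit_delay_control_lmm(relabeled, "mvpa_bout_minutes")}
        for term in base:
            assert new[term] == pytest.approx(base[term], rel=1e-6)

    def test_rank_deficiency_names_aliased_columns(self, paper_scale_config):
        ds, _ = _trial_dataset(paper_scale_config)
        # removing the delay arm makes occasion and exposure collinear
        ig_only = ds[ds["arm"] == "IG"]
        with pytest.raises(AnalysisError, match="rank deficient"):
            fit_delay_control_lmm(ig_only, "mvpa_bout_minutes")

    def test_model_and_sandwich_ses_same_scale(self, paper_scale_config):
        """Under a correctly specified model both SEs estimate the same target."""
        ds, _ = _trial_dataset(paper_scale_config)
        for e in fit_delay_control_lmm(ds, "mvpa_bout_minutes",
                                       emit_trend_contrasts=False):
            assert 0.3 < e.se / e.se_model < 3.0


class TestEstimateAll:
    def test_row_enumeration_single_outcome(self, paper_scale_config):
        ds, _ = _trial_dataset(paper_scale_config)
        mvpa_only = ds[ds["outcome"] == "mvpa_bout_minutes"]
        table = estimate_all(mvpa_only)
        assert set(table["outcome"]) == {"mvpa_bout_minutes"}
        assert (table["estimator"] == "ancova").sum() == 1
        assert (table["estimator"] == "lmm_sandwich").sum() == 8

    def test_full_trial_row_count_and_determinism(self, paper_scale_config):
        ds, _ = _trial_dataset(paper_scale_config)
        t1 = estimate_all(ds)
        t2 = estimate_all(ds)
        n_outcomes = ds["outcome"].nunique()
        assert len(t1) == n_outcomes * 9
        pd.testing.assert_frame_equal(t1, t2)

    def test_one_failure_does_not_abort_others(self, paper_scale_config):
        ds, _ = _trial_dataset(paper_scale_config)
        broken = ds.copy()
        # degenerate outcome: constant everywhere -> ANCOVA must fail
        extra = ds[ds["outcome"] == "mvpa_bout_minutes"].copy()
        extra["outcome"] = "constant"
        extra["value"] = 5.0
        table = estimate_all(pd.concat([broken, extra], ignore_index=True))
        ok = table[table["outcome"] == "mvpa_bout_minutes"]
        assert np.isfinite(ok[ok["estimator"] == "ancova"]["estimate"]).all()
        flagged = table[(table["outcome"] == "constant")
                        & table["estimator"].str.startswith("error")]
        assert len(flagged) >= 1


class TestPower:
    def test_null_alternative_equals_alpha(self):
        for alpha, one_sided in [(0.05, True), (0.1, True), (0.05, False)]:
            p = power_two_sample(50.0, 10.0, 50.0, 10.0, 50, alpha, one_sided)
            assert p == pytest.approx(alpha, abs=1e-9)

    def test_monotone_in_alpha_and_n(self):
        args = (75.5, 54.3, 50.0, 46.8)
        powers_alpha = [power_two_sample(*args, 50, a, True) for a in (0.01, 0.05, 0.1)]
        assert powers_alpha == sorted(powers_alpha)
        powers_n = [power_two_sample(*args, n, 0.1, True) for n in (20, 50, 100, 400)]
        assert powers_n == sorted(powers_n)

    def test_matches_monte_carlo(self, rng):
        """Analytic noncentral-t power vs simulated pooled t-tests."""
        for mean_a, sd_a, mean_b, sd_b, n, alpha, one_sided in [
            (75.5, 54.3, 50.0, 46.8, 50, 0.1, True),
            (60.0, 20.0, 50.0, 20.0, 40, 0.05, False),
        ]:
            n_a = (n + 1) // 2
            n_b = n - n_a
            reps = 40_000
            xa = rng.normal(mean_a, sd_a, (reps, n_a))
            xb = rng.normal(mean_b, sd_b, (reps, n_b))
            va = xa.var(axis=1, ddof=1)
            vb = xb.var(axis=1, ddof=1)
            sp2 = ((n_a - 1) * va + (n_b - 1) * vb) / (n - 2)
            t = (xa.mean(axis=1) - xb.mean(axis=1)) / np.sqrt(sp2 * (1 / n_a + 1 / n_b))
            if one_sided:
                crit = st.t.ppf(1 - alpha, n - 2)
                mc = float(np.mean(t > crit))
            else:
                crit = st.t.ppf(1 - alpha / 2, n - 2)
                mc = float(np.mean(np.abs(t) > crit))
            ana = power_two_sample(mean_a, sd_a, mean_b, sd_b, n, alpha, one_sided)
            assert ana == pytest.approx(mc, abs=0.012)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            power_two_sample(1, 0.0, 0, 1.0, 50)
        with pytest.raises(ValueError):
            power_two_sample(1, 1.0, 0, 1.0, 3)
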