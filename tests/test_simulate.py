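import numpy as np
import pandas as pd
import pytest

from rivalbias import psychometric as psy
from rivalbias import simulate as sim
from rivalbias.errors import ConfigurationError, DomainError, InvalidDesignError


GRID = sim.default_contrast_grid(99)


class TestGenerateDesign:
    def test_default_design_counts(self):
        d = sim.generate_design(2, 10, 22, 0.1, GRID, seed=0)
        per = d.groupby("subject_id")
        assert (per.size() == 220).all()
        assert (per["is_catch"].sum() == 22).all()

    def test_each_contrast_once_per_condition(self):
        d = sim.generate_design(1, 10, 22, 0.1, GRID, seed=3)
        rivalry = d[~d["is_catch"]]
        for cond in psy.CONDITIONS:
            xs = np.sort(rivalry.loc[rivalry["condition"] == cond,
                                     "manipulated_contrast"].to_numpy())
            assert np.allclose(xs, GRID)

    def test_cues_counterbalanced_within_blocks(self):
        d = sim.generate_design(3, 10, 22, 0.1, GRID, seed=1)
        counts = d.groupby(["subject_id", "block"])["cue"].apply(
            lambda s: abs((s == "manipulated").sum() - (s == "fixed").sum()))
        assert (counts == 0).all()

    def test_catch_trials_have_no_contrast(self):
        d = sim.generate_design(1, 10, 22, 0.1, GRID, seed=0)
        assert d.loc[d["is_catch"], "manipulated_contrast"].isna().all()
        assert d.loc[~d["is_catch"], "manipulated_contrast"].notna().all()

    def test_zero_catch_fraction(self):
        d = sim.generate_design(1, 10, 22, 0.0, GRID[:110], seed=0)
        assert not d["is_catch"].any()

    def test_determinism(self):
        a = sim.generate_design(2, 10, 22, 0.1, GRID, seed=42)
        b = sim.generate_design(2, 10, 22, 0.1, GRID, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_grid_truncated_with_warning(self):
        with pytest.warns(UserWarning, match="truncating"):
            d = sim.generate_design(1, 2, 10, 0.0, GRID, seed=0)
        assert len(d) == 20

    @pytest.mark.parametrize("kwargs", [
        dict(n_blocks=0), dict(trials_per_block=-3), dict(catch_fraction=1.0),
    ])
    def test_invalid_counts(self, kwargs):
        args = dict(n_subjects=1, n_blocks=10, trials_per_block=22,
                    catch_fraction=0.1)
        args.update(kwargs)
        with pytest.raises(InvalidDesignError):
            sim.generate_design(**args, contrast_grid=GRID, seed=0)

    def test_grid_outside_unit_interval(self):
        with pytest.raises(DomainError):
            sim.generate_design(1, 10, 22, 0.1, np.linspace(-0.1, 1, 99), seed=0)


class TestDrawSubjectTruth:
    def test_profiles_force_signs(self):
        gt = sim.GroupTruth()
        for k in range(10):
            assert sim.draw_subject_truth(gt, "primer", seed=k).delta_u_i > 0
            assert sim.draw_subject_truth(gt, "adapter", seed=k).delta_u_i < 0

    def test_null_profile_zero_variance(self):
        gt = sim.GroupTruth(sigma_delta_u=0.0)
        assert sim.draw_subject_truth(gt, "null", seed=0).delta_u_i == 0.0

    def test_unknown_profile(self):
        with pytest.raises(ConfigurationError):
            sim.draw_subject_truth(sim.GroupTruth(), "telepath", seed=0)

    def test_random_profile_proportions(self):
        gt = sim.GroupTruth()
        rng = np.random.default_rng(123)
        labels = [sim.draw_subject_truth(gt, "random", rng).bias_profile
                  for _ in range(1000)]
        for name, p in gt.profile_mix.items():
            n_obs = labels.count(name)
            sd = np.sqrt(1000 * p * (1 - p))
            assert abs(n_obs - 1000 * p) <= 3 * sd

    def test_invariants_hold(self):
        gt = sim.GroupTruth()
        for k in range(25):
            t = sim.draw_subject_truth(gt, "random", seed=k)
            assert t.v_i > 0 and t.sigma_i > 0
            assert t.g_i + t.lambda_i < 1
            assert 0 <= t.pi_mixed_i < 1


def _flat_truth(**kw):
    base = dict(subject_id="S01", u_i=0.4, v_i=0.3, delta_u_i=0.0,
                delta_v_i=0.0, g_i=0.05, lambda_i=0.05, sigma_i=0.05,
                pi_mixed_i=0.1, bias_i=0.0, vividness_mean_i=30.0,
                vividness_sd_i=25.0, vviq_i=60.0)
    base.update(kw)
    return sim.SubjectTruth(**base)


def _one_contrast_design(n, contrast, is_catch=False):
    return pd.DataFrame({
        "subject_id": "S01", "block": 1, "trial": np.arange(n) + 1,
        "trial_in_block": np.arange(n) + 1, "cue": "manipulated",
        "condition": "congruent", "is_catch": is_catch,
        "manipulated_contrast": np.nan if is_catch else contrast,
        "fixed_contrast": 0.4,
    })


class TestSimulateResponses:
    def test_midpoint_gives_even_odds(self):
        t = _flat_truth(pi_mixed_i=0.0, g_i=1e-6, lambda_i=1e-6)
        trials = sim.simulate_responses(_one_contrast_design(20000, 0.4), t,
                                        seed=0, p_none=0.0)
        p = (trials["response"] == "manipulated").mean()
        assert p == pytest.approx(0.5, abs=3 * 0.5 / np.sqrt(20000))

    def test_all_mixed_when_pi_one(self):
        t = _flat_truth(pi_mixed_i=0.999999)
        trials = sim.simulate_responses(_one_contrast_design(500, 0.6), t,
                                        seed=1, p_none=0.0)
        assert (trials["response"] == "mixed").all()

    def test_dominance_score_matches_curve(self):
        # Monte-Carlo check of E[dominant + 0.5 mixed] against closed-form psi
        t = _flat_truth(pi_mixed_i=0.2, delta_u_i=0.1)
        x = 0.55
        trials = sim.simulate_responses(_one_contrast_design(10000, x), t,
                                        seed=2, p_none=0.0)
        score = np.select([trials["response"] == "manipulated",
                           trials["response"] == "mixed"], [1.0, 0.5], 0.0)
        p = psy.condition_params(t.params, t.deltas, "congruent")
        psi = psy.evaluate(x, p)
        assert score.mean() == pytest.approx(psi, abs=3 * 0.5 / np.sqrt(10000))

    def test_catch_trial_bias_model(self):
        # score = bias + 0.5 (1 - bias): bias 0.2 -> 0.6
        from rivalbias.preprocess import mock_priming
        t = _flat_truth(bias_i=0.2)
        trials = sim.simulate_responses(_one_contrast_design(10000, 0.4, is_catch=True),
                                        t, seed=3, p_none=0.0)
        assert mock_priming(trials) == pytest.approx(0.6, abs=3 * 0.5 / np.sqrt(10000))

    def test_vividness_within_range(self):
        t = _flat_truth(vividness_mean_i=140.0, vividness_sd_i=60.0)
        trials = sim.simulate_responses(_one_contrast_design(2000, 0.4), t, seed=4)
        assert trials["vividness"].between(-150, 150).all()


class TestSimulateCohort:
    def test_trial_count(self, small_cohort):
        assert len(small_cohort.trials) == 6 * 220
        assert small_cohort.truth.shape[0] == 6

    def test_determinism(self):
        cfg = sim.CohortConfig(n_subjects=2)
        a = sim.simulate_cohort(cfg, 9)
        b = sim.simulate_cohort(cfg, 9)
        pd.testing.assert_frame_equal(a.trials, b.trials)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_no_injection_by_default(self, small_cohort):
        assert (small_cohort.trials.groupby("subject_id")["response"]
                .apply(lambda s: (s != "none").sum()) > 0).all()
        assert (small_cohort.truth["bias_i"] < 0.5).all()

    def test_injected_outliers(self):
        cfg = sim.CohortConfig(n_subjects=4, inject_high_bias_subject=True,
                               inject_no_response_subject=True)
        coh = sim.simulate_cohort(cfg, 2)
        by_subj = coh.trials.groupby("subject_id")["response"]
        assert (by_subj.apply(lambda s: (s == "none").all())).sum() == 1
        assert coh.truth["bias_i"].max() == pytest.approx(0.8)
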