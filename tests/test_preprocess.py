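import numpy as np
import pandas as pd
import pytest

from conftest import window_trials
from rivalbias import preprocess as pp
from rivalbias import simulate as sim
from rivalbias.errors import (EmptyInputError, InsufficientDataError,
                              PreconditionError, UndefinedStatisticError)


class TestDeriveDominance:
    def test_printed_window_examples(self):
        # 0.20-0.31, 2 dominant + 1 mixed -> (0.255, 2.5/11)
        c1 = pp.derive_dominance(window_trials(0.20, 0.31, 2, 1, 8))
        assert c1.midpoints[0] == pytest.approx(0.255)
        assert c1.dominance[0] == pytest.approx(2.5 / 11)
        # 0.21-0.32, 3 dominant -> (0.265, 3/11)
        c2 = pp.derive_dominance(window_trials(0.21, 0.32, 3, 0, 8))
        assert c2.midpoints[0] == pytest.approx(0.265)
        assert c2.dominance[0] == pytest.approx(3 / 11)

    def test_all_mixed_gives_half(self):
        c = pp.derive_dominance(window_trials(0.2, 0.3, 0, 11, 0))
        assert len(c.dominance) == 1
        assert c.dominance[0] == pytest.approx(0.5)

    def test_output_length_and_quantization(self):
        rng = np.random.default_rng(0)
        n, w = 60, 11
        trials = pd.DataFrame({
            "subject_id": "S01", "condition": "congruent", "is_catch": False,
            "manipulated_contrast": rng.uniform(size=n),
            "response": rng.choice(["manipulated", "fixed", "mixed"], size=n),
        })
        c = pp.derive_dominance(trials, w)
        assert len(c.midpoints) == len(c.dominance) == n - w + 1
        assert np.all((c.dominance >= 0) & (c.dominance <= 1))
        # every value is an integer multiple of 0.5 / w
        assert np.allclose(np.round(c.dominance * 2 * w) / (2 * w), c.dominance)
        assert np.all(np.diff(c.midpoints) > 0)

    def test_step_response_gives_monotone_curve(self):
        # all "fixed" below a threshold, all "manipulated" above it
        x = np.linspace(0, 1, 50)
        trials = pd.DataFrame({
            "subject_id": "S01", "condition": "congruent", "is_catch": False,
            "manipulated_contrast": x,
            "response": np.where(x < 0.45, "fixed", "manipulated"),
        })
        c = pp.derive_dominance(trials)
        assert np.all(np.diff(c.dominance) >= 0)

    def test_insufficient_trials(self):
        with pytest.raises(InsufficientDataError):
            pp.derive_dominance(window_trials(0.2, 0.3, 2, 1, 2))

    def test_none_responses_rejected(self):
        t = window_trials(0.2, 0.31, 2, 1, 8)
        t.loc[0, "response"] = "none"
        with pytest.raises(PreconditionError):
            pp.derive_dominance(t)


class TestPrimingProportion:
    def test_all_match(self):
        t = window_trials(0.2, 0.31, 11, 0, 0)  # cue=manipulated, all manipulated
        assert pp.priming_proportion(t) == 1.0

    def test_mixed_excluded(self):
        t = window_trials(0.2, 0.31, 4, 2, 4)
        assert pp.priming_proportion(t) == 0.5

    def test_order_invariant(self):
        t = window_trials(0.2, 0.31, 3, 2, 6)
        shuffled = t.sample(frac=1, random_state=1)
        assert pp.priming_proportion(t) == pp.priming_proportion(shuffled)

    def test_random_responses_near_chance(self):
        rng = np.random.default_rng(7)
        n = 10_000
        t = pd.DataFrame({
            "subject_id": "S01", "cue": "manipulated", "is_catch": False,
            "response": rng.choice(["manipulated", "fixed"], size=n),
        })
        assert pp.priming_proportion(t) == pytest.approx(
            0.5, abs=3 * 0.5 / np.sqrt(n))

    def test_all_mixed_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            pp.priming_proportion(window_trials(0.2, 0.31, 0, 11, 0))


class TestMockPriming:
    def _catch(self, responses):
        return pd.DataFrame({"subject_id": "S01", "cue": "manipulated",
                             "is_catch": True, "response": responses})

    def test_all_mixed_unbiased(self):
        assert pp.mock_priming(self._catch(["mixed"] * 10)) == 0.5

    def test_all_cue_matching(self):
        assert pp.mock_priming(self._catch(["manipulated"] * 10)) == 1.0

    def test_no_responses(self):
        with pytest.raises(UndefinedStatisticError):
            pp.mock_priming(self._catch(["none"] * 5))

    def test_rejects_rivalry_trials(self):
        t = window_trials(0.2, 0.31, 2, 1, 8)
        with pytest.raises(PreconditionError):
            pp.mock_priming(t)


class TestApplyExclusions:
    def test_no_outliers_no_exclusions(self, small_cohort):
        kept, report = pp.apply_exclusions(small_cohort.trials)
        assert report.excluded == {}
        assert kept["subject_id"].nunique() == 6

    def test_identical_subjects_none_excluded(self):
        # zero between-subject variance: nobody exceeds mean + 2 SD
        rows = []
        for sid in ("A", "B", "C"):
            rows.append(pd.DataFrame({
                "subject_id": sid, "cue": "manipulated", "is_catch": True,
                "response": ["mixed"] * 10}))
            rows.append(pd.DataFrame({
                "subject_id": sid, "cue": "manipulated", "is_catch": False,
                "response": ["manipulated"] * 10}))
        kept, report = pp.apply_exclusions(pd.concat(rows, ignore_index=True))
        assert report.excluded == {}

    def test_injected_outliers_removed(self):
        cfg = sim.CohortConfig(n_subjects=10, inject_high_bias_subject=True,
                               inject_no_response_subject=True)
        coh = sim.simulate_cohort(cfg, 21)
        kept, report = pp.apply_exclusions(coh.trials)
        reasons = sorted(r for r, _ in report.excluded.values())
        assert reasons == ["no_responses", "response_bias"]
        assert kept["subject_id"].nunique() == 8

    def test_empty_dataset(self):
        with pytest.raises(EmptyInputError):
            pp.apply_exclusions(pd.DataFrame(columns=["subject_id", "response"]))
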