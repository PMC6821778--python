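import math

import numpy as np
import pandas as pd
import pytest

from rivalbias import classical as cl
from rivalbias import simulate as sim
from rivalbias.errors import DomainError, UndefinedStatisticError


class TestOneSampleT:
    def test_symmetric_sample_t_zero(self):
        res = cl.one_sample_t([0.6, 0.6, 0.6, 0.4, 0.4, 0.4], 0.5)
        assert res.t == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)
        assert res.df == 5

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0.55, 0.1, size=23)
        res = cl.one_sample_t(x, 0.5)
        m, s = x.mean(), x.std(ddof=1)
        t_manual = (m - 0.5) / (s / math.sqrt(len(x)))
        assert res.t == pytest.approx(t_manual, abs=1e-10)
        assert res.cohen_d == pytest.approx((m - 0.5) / s, abs=1e-10)

    def test_zero_variance(self):
        with pytest.raises(UndefinedStatisticError):
            cl.one_sample_t([0.5] * 10, 0.5)


class TestPearsonBF:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        res = cl.pearson_bf(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)

    def test_null_simulation_small_r(self):
        rng = np.random.default_rng(11)
        x, y = rng.normal(size=10_000), rng.normal(size=10_000)
        res = cl.pearson_bf(x, y)
        assert abs(res.r) < 0.05
        assert res.bf10 < 1  # large-n null: evidence for no correlation

    @pytest.mark.parametrize("r_target,n", [(0.03, 59), (0.3, 40), (-0.5, 25)])
    def test_bf_matches_closed_form_oracle(self, r_target, n):
        # independent closed-form implementation of the same default test
        import pingouin as pg
        rng = np.random.default_rng(int(n))
        x = rng.normal(size=n)
        y = r_target * x + math.sqrt(1 - r_target ** 2) * rng.normal(size=n)
        res = cl.pearson_bf(x, y)
        oracle = float(pg.bayesfactor_pearson(res.r, n))
        assert res.bf10 == pytest.approx(oracle, rel=0.02)

    def test_constant_input(self):
        with pytest.raises(UndefinedStatisticError):
            cl.pearson_bf(np.ones(10), np.arange(10.0))


def _trials_with_vividness(priming_by_bin, trials_per_bin=10, sid="S01"):
    """Trials whose priming probability is constant within vividness bins."""
    rows = []
    rng = np.random.default_rng(1)
    for b, p in enumerate(priming_by_bin):
        n_match = int(round(p * trials_per_bin))
        resp = ["manipulated"] * n_match + ["fixed"] * (trials_per_bin - n_match)
        for k, r in enumerate(resp):
            rows.append({"subject_id": sid, "is_catch": False,
                         "cue": "manipulated", "response": r,
                         "vividness": 10.0 * b + rng.uniform()})
    return pd.DataFrame(rows)


class TestVividnessBins:
    def test_equal_bin_sizes(self):
        t = _trials_with_vividness([0.5, 0.5, 0.5, 0.5])
        table, flagged = cl.vividness_bins(t, 4)
        assert flagged == []
        assert table.shape == (1, 4)

    def test_bin_priming_values(self):
        t = _trials_with_vividness([0.2, 0.4, 0.6, 0.8])
        table, _ = cl.vividness_bins(t, 4)
        assert table.iloc[0].tolist() == pytest.approx([0.2, 0.4, 0.6, 0.8])

    def test_constant_vividness_flagged(self):
        t = _trials_with_vividness([0.5, 0.5, 0.5, 0.5])
        t["vividness"] = 3.0
        table, flagged = cl.vividness_bins(t, 4)
        assert flagged == ["S01"]
        assert len(table) == 0

    def test_bin_sizes_differ_by_at_most_one(self):
        t = _trials_with_vividness([0.5, 0.5, 0.5], trials_per_bin=9)  # 27 trials
        rivalry = t
        order = np.argsort(rivalry["vividness"].to_numpy(), kind="stable")
        rank = np.empty(len(rivalry), int)
        rank[order] = np.arange(len(rivalry))
        sizes = np.bincount((rank * 4) // len(rivalry))
        assert sizes.max() - sizes.min() <= 1

    def test_vividness_coupled_generator_shows_gradient(self):
        # stronger imagery effect on more vivid trials -> priming rises by bin
        cfg = sim.CohortConfig(
            n_subjects=8, vividness_coupling=1.0, profile=("primer", "neutral"),
            group_truth=sim.GroupTruth(delta_u=0.25, sigma_delta_u=0.08))
        coh = sim.simulate_cohort(cfg, 17)
        table, _ = cl.vividness_bins(coh.trials, 4)
        means = table.mean(axis=0).to_numpy()
        assert means[-1] > means[0]


class TestRmAnovaHF:
    def test_equal_condition_means_f_zero(self):
        rng = np.random.default_rng(0)
        subj = rng.normal(size=(8, 1))
        noise = rng.normal(size=(8, 4))
        noise -= noise.mean(axis=0, keepdims=True)  # force equal column means
        res = cl.rm_anova_hf(subj + noise)
        assert res.F == pytest.approx(0.0, abs=1e-9)

    def test_sums_of_squares_match_brute_force(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=(6, 4))
        res = cl.rm_anova_hf(y)
        n, k = y.shape
        grand = y.mean()
        ss_cond = sum(n * (y[:, j].mean() - grand) ** 2 for j in range(k))
        ss_subj = sum(k * (y[i].mean() - grand) ** 2 for i in range(n))
        ss_err = sum((y[i, j] - y[i].mean() - y[:, j].mean() + grand) ** 2
                     for i in range(n) for j in range(k))
        assert res.ss_condition == pytest.approx(ss_cond, abs=1e-8)
        assert res.ss_subject == pytest.approx(ss_subj, abs=1e-8)
        assert res.ss_error == pytest.approx(ss_err, abs=1e-8)

    def test_matches_pingouin(self):
        import pingouin as pg
        rng = np.random.default_rng(8)
        y = rng.normal(size=(12, 4)) + rng.normal(size=(12, 1))
        res = cl.rm_anova_hf(y)
        df = pd.DataFrame(y, columns=list("abcd"))
        df["s"] = range(12)
        long = df.melt(id_vars="s", var_name="c", value_name="y")
        pgres = pg.rm_anova(long, dv="y", within="c", subject="s", detailed=True)
        assert res.F == pytest.approx(float(pgres["F"][0]), rel=1e-9)
        assert res.ss_condition == pytest.approx(float(pgres["SS"][0]), rel=1e-9)

    def test_compound_symmetry_epsilon_near_one(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=(40, 4)) + 2 * rng.normal(size=(40, 1))
        res = cl.rm_anova_hf(y)
        assert res.epsilon_hf > 0.85

    def test_epsilon_bounds_and_correction_direction(self):
        rng = np.random.default_rng(9)
        # strongly non-spherical: one condition much noisier, correlated scales
        base = rng.normal(size=(15, 1))
        effect = np.array([0.0, 0.2, 0.4, 0.9])
        y = effect + np.hstack([base + 0.1 * rng.normal(size=(15, 1)),
                                base + 0.5 * rng.normal(size=(15, 1)),
                                base + 2.0 * rng.normal(size=(15, 1)),
                                8.0 * rng.normal(size=(15, 1))])
        res = cl.rm_anova_hf(y)
        k = 4
        assert 1.0 / (k - 1) <= res.epsilon_hf <= 1.0
        # shrinking both dfs weakens the evidence whenever F exceeds 1
        if res.epsilon_hf < 1.0 and res.F > 1.0:
            assert res.p >= res.p_uncorrected

    def test_linear_contrast_detects_trend(self):
        rng = np.random.default_rng(4)
        y = np.arange(4)[None, :] * 0.5 + rng.normal(scale=0.5, size=(20, 4))
        res = cl.rm_anova_hf(y)
        assert res.p_linear < 0.01
        assert res.df_linear == (1, 19)

    def test_missing_cells_rejected(self):
        y = np.ones((6, 4))
        y[0, 0] = np.nan
        with pytest.raises(Exception):
            cl.rm_anova_hf(y)
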