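import numpy as np
import pandas as pd
import pytest

from rivalbias import simulate as sim


def window_trials(contrast_lo, contrast_hi, n_manip, n_mixed, n_fixed,
                  subject="S01", condition="congruent"):
    """Eleven-trial window with the given response composition."""
    n = n_manip + n_mixed + n_fixed
    return pd.DataFrame({
        "subject_id": subject,
        "condition": condition,
        "is_catch": False,
        "cue": "manipulated" if condition == "congruent" else "fixed",
        "manipulated_contrast": np.linspace(contrast_lo, contrast_hi, n),
        "response": (["manipulated"] * n_manip + ["mixed"] * n_mixed
                     + ["fixed"] * n_fixed),
    })


def strong_effect_truths(n_subjects=10, seed=5, sigma_obs=0.08):
    """Fixed subject truths with large opposite-signed bias effects."""
    rng = np.random.default_rng(seed)
    deltas = [0.25, -0.25, 0.3, -0.3, 0.25, -0.25, 0.2, -0.2, 0.3, 0.0]
    truths = []
    for i in range(n_subjects):
        truths.append(sim.SubjectTruth(
            subject_id=f"S{i + 1:02d}",
            u_i=0.4 + 0.05 * rng.normal(),
            v_i=float(np.exp(np.log(0.3) + 0.2 * rng.normal())),
            delta_u_i=deltas[i % len(deltas)],
            delta_v_i=0.03 * rng.normal(),
            g_i=0.05, lambda_i=0.05, sigma_i=sigma_obs,
            pi_mixed_i=0.1, bias_i=0.0,
            vividness_mean_i=30.0, vividness_sd_i=25.0, vviq_i=60.0))
    return truths


@pytest.fixture(scope="session")
def small_cohort():
    """Six-subject cohort at the default design (fast, reused across tests)."""
    cfg = sim.CohortConfig(n_subjects=6)
    return sim.simulate_cohort(cfg, seed=11)
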