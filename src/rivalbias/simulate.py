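"""Synthetic cohorts for the imagery / binocular-rivalry paradigm.

Generates trial tables with the structure of the behavioral experiment: each
subject runs ``n_blocks`` blocks of ``trials_per_block`` trials (default
10 x 22 = 220).  On every trial the subject imagines one of the two rival
gratings (the cue), rates imagery vividness, and then reports which grating
dominated a brief rivalry display ("manipulated", "fixed", "mixed", or "none"
when no key was pressed in time).  The contrast of the manipulated grating
sweeps a grid in [0, 1] — each contrast appearing once per imagery condition —
while the other grating stays at a fixed contrast (default 0.4).  Ten percent
of trials are catch trials showing a mock half/half rivalry stimulus; they
probe response bias rather than perception and carry no manipulated contrast.

Responses are drawn from a psychometric model with known per-subject ground
truth, so recovery of biases, sensitivities and condition differences can be
tested.  Subjects are heterogeneous: the population mixes priming
(``delta_u > 0``), adaptation (``delta_u < 0``) and null-effect profiles, and
independently sensitization / desensitization / neutral profiles for the
discrimination-sensitivity difference ``delta_v``.

Default design counts follow the experimental protocol (10 blocks x 22
trials, 10% catch).  220 total minus 22 catch leaves 198 rivalry trials, i.e.
99 contrast levels per condition on an even grid over [0, 1]; the grid length
is configurable.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from . import psychometric as psy
from .errors import (ConfigurationError, DomainError, InvalidDesignError,
                     PreconditionError)

__all__ = [
    "GroupTruth",
    "SubjectTruth",
    "CohortConfig",
    "CohortData",
    "generate_design",
    "draw_subject_truth",
    "simulate_responses",
    "simulate_cohort",
    "simulate_curves_from_truth",
    "default_contrast_grid",
]

CUE_MANIPULATED = "manipulated"
CUE_FIXED = "fixed"
RESPONSES = ("manipulated", "fixed", "mixed", "none")

BIAS_PROFILES = ("primer", "adapter", "null")
SLOPE_PROFILES = ("sensitizer", "desensitizer", "neutral")


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def subject_rng(master_seed: int, subject_id: str, salt: str = "") -> np.random.Generator:
    """Deterministic per-subject substream: master seed + CRC32 of the id."""
    key = zlib.crc32(f"{subject_id}|{salt}".encode())
    return np.random.default_rng([int(master_seed), key])


# ---------------------------------------------------------------------------
# ground-truth population model
# ---------------------------------------------------------------------------

@dataclass
class GroupTruth:
    """Population (group-level) parameters of the generative model.

    ``mu_u``/``sigma_u`` govern the baseline bias ``u_i ~ N(mu_u, sigma_u)``;
    ``mu_v``/``sigma_v`` the baseline discrimination sensitivity on the log
    scale, ``log v_i ~ N(mu_v, sigma_v)`` (positivity by construction).
    ``delta_u``/``sigma_delta_u`` and ``delta_v``/``sigma_delta_v`` are the
    population mean and spread of the per-subject condition differences; the
    defaults put the population mean at zero with substantial between-subject
    spread, the regime in which group-level evidence can favor the null while
    individual subjects show strong opposite-signed effects.
    """

    mu_u: float = 0.4            # centered at the fixed-grating contrast
    sigma_u: float = 0.12
    mu_v: float = float(np.log(0.3))   # median v ~ 0.3 contrast units
    sigma_v: float = 0.35
    delta_u: float = 0.0
    sigma_delta_u: float = 0.12
    delta_v: float = 0.0
    sigma_delta_v: float = 0.06
    # guess/lapse rates ~ 0.5 * Beta(a, b): support (0, 0.5), mass near 0
    g_beta: tuple = (1.2, 10.0)
    lam_beta: tuple = (1.2, 10.0)
    sigma_obs_scale: float = 0.06      # half-normal scale of sigma_i
    pi_mixed_beta: tuple = (2.0, 10.0)  # mixed-report probability per subject
    bias_halfnormal_scale: float = 0.04  # catch-trial response-bias spread
    vividness_mean_loc: float = 40.0
    vividness_mean_scale: float = 35.0
    vividness_sd_loc: float = 30.0
    vividness_sd_scale: float = 8.0
    vviq_loc: float = 60.0            # VVIQ2 total, 16 items x 1..5
    vviq_scale: float = 8.0
    profile_mix: dict = field(default_factory=lambda: {
        "primer": 0.40, "adapter": 0.35, "null": 0.25,
    })
    slope_profile_mix: dict = field(default_factory=lambda: {
        "sensitizer": 0.30, "desensitizer": 0.30, "neutral": 0.40,
    })

    def __post_init__(self):
        for name in ("sigma_u", "sigma_v", "sigma_delta_u", "sigma_delta_v"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for mix, allowed in ((self.profile_mix, BIAS_PROFILES),
                             (self.slope_profile_mix, SLOPE_PROFILES)):
            if set(mix) != set(allowed):
                raise ConfigurationError(f"profile mix keys must be {allowed}")
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ConfigurationError("profile mix proportions must sum to 1")


@dataclass
class SubjectTruth:
    """Ground-truth parameters of one simulated subject."""

    subject_id: str
    u_i: float
    v_i: float
    delta_u_i: float
    delta_v_i: float
    g_i: float
    lambda_i: float
    sigma_i: float
    pi_mixed_i: float
    bias_i: float
    vividness_mean_i: float
    vividness_sd_i: float
    vviq_i: float
    bias_profile: str = "null"
    slope_profile: str = "neutral"

    def __post_init__(self):
        if self.v_i <= 0 or self.sigma_i <= 0:
            raise DomainError("v_i and sigma_i must be positive")
        if self.g_i + self.lambda_i >= 1:
            raise DomainError("g_i + lambda_i must be < 1")
        if not (0 <= self.pi_mixed_i < 1):
            raise DomainError("pi_mixed_i must lie in [0, 1)")

    @property
    def params(self) -> psy.PsychometricParams:
        return psy.PsychometricParams(self.u_i, self.v_i, self.g_i, self.lambda_i)

    @property
    def deltas(self) -> psy.ConditionDeltas:
        return psy.ConditionDeltas(self.delta_u_i, self.delta_v_i)


def _truncated_normal(rng, loc, scale, lower=-np.inf, upper=np.inf):
    """Inverse-CDF truncated normal draw (deterministic under ``rng``)."""
    from scipy.stats import truncnorm

    if scale == 0:
        if not (lower <= loc <= upper):
            raise DomainError("degenerate truncated normal outside its bounds")
        return float(loc)
    a, b = (lower - loc) / scale, (upper - loc) / scale
    return float(truncnorm.ppf(rng.uniform(), a, b, loc=loc, scale=scale))


def draw_subject_truth(group_truth: GroupTruth, profile="random", seed=None) -> SubjectTruth:
    """Draw one subject's ground truth from the population model.

    ``profile`` selects the sign of the condition effects: a bias profile in
    {"primer", "adapter", "null"}, a (bias, slope) tuple, or "random" to draw
    both from the population profile mixture.  Primers get a strictly positive
    ``delta_u_i`` (truncated draw), adapters a strictly negative one; the null
    profile draws from a tight zero-centered distribution (exactly zero when
    ``sigma_delta_u`` is zero).  Slope profiles act the same way on
    ``delta_v_i``.
    """
    gt = group_truth
    rng = _rng(seed)

    if profile == "random":
        bias_profile = rng.choice(list(gt.profile_mix), p=list(gt.profile_mix.values()))
        slope_profile = rng.choice(
            list(gt.slope_profile_mix), p=list(gt.slope_profile_mix.values()))
    elif isinstance(profile, (tuple, list)):
        bias_profile, slope_profile = profile
    else:
        bias_profile = profile
        slope_profile = rng.choice(
            list(gt.slope_profile_mix), p=list(gt.slope_profile_mix.values()))
    if bias_profile not in BIAS_PROFILES:
        raise ConfigurationError(f"unknown bias profile {bias_profile!r}")
    if slope_profile not in SLOPE_PROFILES:
        raise ConfigurationError(f"unknown slope profile {slope_profile!r}")

    u_i = float(rng.normal(gt.mu_u, gt.sigma_u))
    v_i = float(np.exp(rng.normal(gt.mu_v, gt.sigma_v)))

    if bias_profile == "primer":
        delta_u_i = _truncated_normal(rng, max(gt.delta_u, 0.0) + 1e-12,
                                      gt.sigma_delta_u, lower=0.0)
    elif bias_profile == "adapter":
        delta_u_i = _truncated_normal(rng, min(gt.delta_u, 0.0) - 1e-12,
                                      gt.sigma_delta_u, upper=0.0)
    else:
        delta_u_i = float(rng.normal(0.0, 0.1 * gt.sigma_delta_u))

    if slope_profile == "sensitizer":
        delta_v_i = _truncated_normal(rng, max(gt.delta_v, 0.0) + 1e-12,
                                      gt.sigma_delta_v, lower=0.0)
    elif slope_profile == "desensitizer":
        delta_v_i = _truncated_normal(rng, min(gt.delta_v, 0.0) - 1e-12,
                                      gt.sigma_delta_v, upper=0.0)
    else:
        delta_v_i = float(rng.normal(0.0, 0.1 * gt.sigma_delta_v))
    # truncate so both condition-specific sensitivities stay positive
    delta_v_i = float(np.clip(delta_v_i, -1.8 * v_i, 1.8 * v_i))

    g_i = float(0.5 * rng.beta(*gt.g_beta))
    lam_i = float(0.5 * rng.beta(*gt.lam_beta))
    sigma_i = float(abs(rng.normal(0.0, gt.sigma_obs_scale))) + 1e-4
    pi_mixed_i = float(rng.beta(*gt.pi_mixed_beta))
    bias_i = float(min(abs(rng.normal(0.0, gt.bias_halfnormal_scale)), 1.0))
    viv_mean = float(rng.normal(gt.vividness_mean_loc, gt.vividness_mean_scale))
    viv_sd = float(max(abs(rng.normal(gt.vividness_sd_loc, gt.vividness_sd_scale)), 1.0))
    vviq = float(np.clip(rng.normal(gt.vviq_loc, gt.vviq_scale), 16, 80))

    return SubjectTruth(
        subject_id="", u_i=u_i, v_i=v_i, delta_u_i=delta_u_i, delta_v_i=delta_v_i,
        g_i=g_i, lambda_i=lam_i, sigma_i=sigma_i, pi_mixed_i=pi_mixed_i,
        bias_i=bias_i, vividness_mean_i=viv_mean, vividness_sd_i=viv_sd,
        vviq_i=vviq, bias_profile=bias_profile, slope_profile=slope_profile,
    )


# ---------------------------------------------------------------------------
# experimental design
# ---------------------------------------------------------------------------

def default_contrast_grid(n_levels: int = 99) -> np.ndarray:
    """Evenly spaced contrast grid over [0, 1] inclusive."""
    return np.linspace(0.0, 1.0, n_levels)


def generate_design(n_subjects, n_blocks, trials_per_block, catch_fraction,
                    contrast_grid, seed, fixed_contrast: float = 0.4) -> pd.DataFrame:
    """Build the per-subject trial design table.

    Each subject gets ``n_blocks * trials_per_block`` rows.  Catch trials
    (``round(catch_fraction * total)`` of them) are spread across blocks; the
    remaining rivalry trials present every grid contrast once per imagery
    condition, in an order randomized per subject.  Imagery cues are
    counterbalanced within blocks.
    """
    for name, val in (("n_subjects", n_subjects), ("n_blocks", n_blocks),
                      ("trials_per_block", trials_per_block)):
        if not (isinstance(val, (int, np.integer)) and val > 0):
            raise InvalidDesignError(f"{name} must be a positive integer, got {val!r}")
    if not (0 <= catch_fraction < 1):
        raise InvalidDesignError("catch_fraction must lie in [0, 1)")
    grid = np.asarray(contrast_grid, dtype=float)
    if grid.ndim != 1 or len(grid) == 0:
        raise DomainError("contrast_grid must be a non-empty 1-d sequence")
    if np.any(grid < 0) or np.any(grid > 1):
        raise DomainError("contrast grid values must lie in [0, 1]")
    if np.any(np.diff(grid) <= 0):
        raise DomainError("contrast grid must be strictly increasing")

    total = n_blocks * trials_per_block
    n_catch = int(round(catch_fraction * total))
    n_rivalry = total - n_catch
    if n_rivalry % 2:
        raise InvalidDesignError(
            f"{n_rivalry} rivalry trials cannot be split evenly over two conditions; "
            "adjust the design counts or catch fraction")
    budget = n_rivalry // 2
    if budget < len(grid):
        warnings.warn(
            f"per-condition budget {budget} < grid length {len(grid)}; truncating grid",
            stacklevel=2)
        grid = grid[:budget]
    reps, rem = divmod(budget, len(grid))
    per_condition = np.concatenate([np.tile(grid, reps), grid[:rem]])

    frames = []
    for s in range(n_subjects):
        sid = f"S{s + 1:02d}"
        rng = subject_rng(seed, sid, "design")
        frames.append(_subject_design(
            sid, n_blocks, trials_per_block, n_catch, per_condition,
            fixed_contrast, rng))
    return pd.concat(frames, ignore_index=True)


def _subject_design(sid, n_blocks, tpb, n_catch, per_condition, fixed_contrast, rng):
    # catch trials: counts per block as even as possible, cues balanced
    base, extra = divmod(n_catch, n_blocks)
    catch_per_block = np.full(n_blocks, base, dtype=int)
    if extra:
        catch_per_block[rng.choice(n_blocks, size=extra, replace=False)] += 1
    n_cm = n_catch // 2 + (n_catch % 2) * int(rng.integers(2))
    catch_cues = np.array([CUE_MANIPULATED] * n_cm + [CUE_FIXED] * (n_catch - n_cm))
    rng.shuffle(catch_cues)

    cong = list(rng.permutation(per_condition))    # cue = manipulated
    incong = list(rng.permutation(per_condition))  # cue = fixed
    catch_cues = list(catch_cues)

    rows = []
    trial_no = 0
    for b in range(n_blocks):
        block_rows = []
        c_b = catch_per_block[b]
        block_catch = [catch_cues.pop() for _ in range(c_b)]
        n_manip_catch = sum(c == CUE_MANIPULATED for c in block_catch)
        quota_manip = tpb // 2 + (tpb % 2) * (b % 2)
        want_cong = int(np.clip(quota_manip - n_manip_catch, 0, tpb - c_b))
        want_cong = min(want_cong, len(cong))
        want_incong = min(tpb - c_b - want_cong, len(incong))
        want_cong = tpb - c_b - want_incong  # absorb any pool shortfall
        for cue in block_catch:
            block_rows.append((cue, True, np.nan))
        for _ in range(want_cong):
            block_rows.append((CUE_MANIPULATED, False, cong.pop()))
        for _ in range(want_incong):
            block_rows.append((CUE_FIXED, False, incong.pop()))
        order = rng.permutation(len(block_rows))
        for k in order:
            cue, is_catch, contrast = block_rows[k]
            trial_no += 1
            rows.append({
                "subject_id": sid, "block": b + 1, "trial": trial_no,
                "cue": cue,
                "condition": psy.CONGRUENT if cue == CUE_MANIPULATED else psy.INCONGRUENT,
                "is_catch": is_catch,
                "manipulated_contrast": contrast,
                "fixed_contrast": fixed_contrast,
            })
    df = pd.DataFrame(rows)
    df["trial_in_block"] = df.groupby("block").cumcount() + 1
    return df[["subject_id", "block", "trial", "trial_in_block", "cue",
               "condition", "is_catch", "manipulated_contrast", "fixed_contrast"]]


# ---------------------------------------------------------------------------
# response generation
# ---------------------------------------------------------------------------

def simulate_responses(design: pd.DataFrame, subject_truth: SubjectTruth, seed,
                       p_none: float = 0.01,
                       vividness_coupling: float = 0.0) -> pd.DataFrame:
    """Generate rivalry responses and vividness ratings for one subject.

    Rivalry trials: with probability ``pi_mixed_i`` the report is "mixed";
    otherwise "manipulated" with probability
    ``psi' = clip((psi - 0.5 pi) / (1 - pi), 0, 1)`` so that the expectation of
    the dominance score (dominant + 0.5 * mixed) equals the psychometric curve
    psi (up to clipping).  Catch trials: "mixed" with probability
    ``1 - bias_i``, the cued percept otherwise.  Every response is replaced by
    "none" with probability ``p_none`` (no key pressed in time).  Vividness is
    a truncated normal on [-150, 150]; with ``vividness_coupling != 0`` the
    trial-level effective ``delta_u`` scales linearly with the standardized
    vividness of that trial, so more vivid imagery exerts a stronger pull.
    """
    if design["subject_id"].nunique() != 1:
        raise PreconditionError("design rows must belong to a single subject")
    t = subject_truth
    rng = _rng(seed)
    n = len(design)
    out = design.copy()

    from scipy.stats import truncnorm
    a = (-150.0 - t.vividness_mean_i) / t.vividness_sd_i
    b = (150.0 - t.vividness_mean_i) / t.vividness_sd_i
    vividness = truncnorm.ppf(rng.uniform(size=n), a, b,
                              loc=t.vividness_mean_i, scale=t.vividness_sd_i)
    out["vividness"] = np.round(vividness, 1)

    z = (vividness - t.vividness_mean_i) / t.vividness_sd_i
    delta_u_eff = t.delta_u_i * (1.0 + vividness_coupling * z)

    is_catch = out["is_catch"].to_numpy(bool)
    congruent = (out["condition"] == psy.CONGRUENT).to_numpy()
    x = out["manipulated_contrast"].to_numpy(float)

    sign = np.where(congruent, -1.0, 1.0)
    u_c = t.u_i + sign * delta_u_eff / 2.0
    v_c = np.maximum(t.v_i + sign * t.delta_v_i / 2.0, 1e-6)
    s_c = psy.scale_from_sensitivity(v_c)
    from scipy.special import expit
    psi = t.g_i + (1.0 - t.g_i - t.lambda_i) * expit((x - u_c) / s_c)

    pi = t.pi_mixed_i
    if pi < 1.0:
        psi_adj = (psi - 0.5 * pi) / (1.0 - pi)
    else:
        psi_adj = np.full_like(psi, 0.5)
    psi_prime = np.clip(psi_adj, 0.0, 1.0)

    response = np.empty(n, dtype=object)
    u1, u2 = rng.uniform(size=n), rng.uniform(size=n)
    mixed = u1 < pi
    manip = u2 < psi_prime
    response[~is_catch & mixed] = "mixed"
    response[~is_catch & ~mixed & manip] = "manipulated"
    response[~is_catch & ~mixed & ~manip] = "fixed"

    catch_mixed = rng.uniform(size=n) < (1.0 - t.bias_i)
    response[is_catch & catch_mixed] = "mixed"
    cue = out["cue"].to_numpy(object)
    hold = is_catch & ~catch_mixed
    response[hold] = cue[hold]

    none_mask = rng.uniform(size=n) < p_none
    response[none_mask] = "none"
    out["response"] = response
    return out


# ---------------------------------------------------------------------------
# whole cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Study conditions for a synthetic cohort (defaults = the experiment)."""

    n_subjects: int = 59
    n_blocks: int = 10
    trials_per_block: int = 22
    catch_fraction: float = 0.1
    n_contrast_levels: int = 99
    fixed_contrast: float = 0.4
    p_none: float = 0.01
    vividness_coupling: float = 0.0
    inject_high_bias_subject: bool = False   # forces one subject's bias_i high
    inject_no_response_subject: bool = False  # one subject logs no responses
    high_bias_value: float = 0.8
    profile: object = "random"               # passed to draw_subject_truth
    group_truth: GroupTruth = field(default_factory=GroupTruth)

    def to_dict(self) -> dict:
        d = asdict(self)
        if isinstance(d.get("profile"), tuple):
            d["profile"] = list(d["profile"])
        return d


@dataclass
class CohortData:
    """A simulated dataset plus its generating truth."""

    trials: pd.DataFrame
    subjects: pd.DataFrame   # subject_id, vviq
    truth: pd.DataFrame      # one row per SubjectTruth
    group_truth: GroupTruth


def simulate_cohort(config: CohortConfig, seed) -> CohortData:
    """Simulate a full cohort under ``config``; deterministic in ``seed``."""
    cfg = config
    grid = default_contrast_grid(cfg.n_contrast_levels)
    design = generate_design(cfg.n_subjects, cfg.n_blocks, cfg.trials_per_block,
                             cfg.catch_fraction, grid, seed,
                             fixed_contrast=cfg.fixed_contrast)
    subject_ids = sorted(design["subject_id"].unique())

    truths, frames = [], []
    for i, sid in enumerate(subject_ids):
        truth = draw_subject_truth(cfg.group_truth, cfg.profile,
                                   subject_rng(seed, sid, "truth"))
        truth = replace(truth, subject_id=sid)
        if cfg.inject_high_bias_subject and i == len(subject_ids) - 1:
            truth = replace(truth, bias_i=cfg.high_bias_value)
        sub_design = design[design["subject_id"] == sid]
        trials = simulate_responses(sub_design, truth,
                                    subject_rng(seed, sid, "responses"),
                                    p_none=cfg.p_none,
                                    vividness_coupling=cfg.vividness_coupling)
        if (cfg.inject_no_response_subject
                and i == len(subject_ids) - (2 if cfg.inject_high_bias_subject else 1)):
            trials = trials.copy()
            trials["response"] = "none"
        truths.append(truth)
        frames.append(trials)

    trials_df = pd.concat(frames, ignore_index=True)
    truth_df = pd.DataFrame([asdict(t) for t in truths])
    subjects_df = truth_df[["subject_id", "vviq_i"]].rename(columns={"vviq_i": "vviq"})
    return CohortData(trials_df, subjects_df, truth_df, cfg.group_truth)


def simulate_curves_from_truth(truths, midpoints, seed) -> pd.DataFrame:
    """Dominance observations drawn from the analysis model itself.

    For each subject and condition, emits ``y ~ Normal(psi(x), sigma_i)`` at
    the given midpoint contrasts — the generative process the hierarchical
    Gaussian-likelihood model assumes exactly.  Used for simulation-based
    calibration, where the fitted model and the data-generating process must
    coincide.
    """
    x = np.asarray(midpoints, float)
    rng = _rng(seed)
    rows = []
    for t in truths:
        for cond in psy.CONDITIONS:
            p = psy.condition_params(t.params, t.deltas, cond)
            mu = psy.evaluate(x, p)
            y = rng.normal(mu, t.sigma_i)
            rows.append(pd.DataFrame({
                "subject_id": t.subject_id, "condition": cond,
                "midpoint": x, "dominance": y,
            }))
    return pd.concat(rows, ignore_index=True)
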