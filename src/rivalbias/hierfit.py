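"""Hierarchical Bayesian psychometric-curve estimation by MCMC.

Model
-----
Each subject *i* contributes a dominance curve per imagery condition.  The
default likelihood treats every windowed dominance value as Gaussian around
the psychometric curve::

    y ~ Normal(psi(x; u_ic, v_ic, g_i, lam_i), sigma_i)

with condition-specific bias and sensitivity obtained from the subject's base
parameters and condition differences (congruent: ``u_i - delta_u_i/2``,
incongruent: ``u_i + delta_u_i/2``; likewise for ``v`` with ``delta_v_i``).
Subject parameters are exchangeable draws from group-level distributions::

    u_i        ~ Normal(mu_u, sigma_u)
    log v_i    ~ Normal(mu_v, sigma_v)        (positivity by construction)
    delta_u_i  ~ Normal(delta_u, sigma_delta_u)
    delta_v_i  ~ Normal(delta_v, sigma_delta_v)
    g_i, lam_i ~ 0.5 * Beta(a, b)             (support (0, 0.5))
    sigma_i    ~ HalfNormal(s_sigma)

The group means get normal priors (``delta_u``, ``delta_v`` zero-centered
with scale ``tau`` — the scale the Savage-Dickey prior density at zero is
computed from), the group spreads half-normal priors.  A trial-level
multinomial likelihood (mixed / manipulated / fixed reports with a per-subject
mixed-report probability) is available via ``likelihood="trials"``; the
Gaussian-on-dominance likelihood is the default but ignores the
autocorrelation induced by overlapping windows, which the trial-level variant
avoids.

Inference
---------
Posterior sampling uses a Gibbs scan: conjugate normal updates for the four
group means and univariate slice sampling (Neal 2003, stepping-out plus
shrinkage) for everything else.  Subject-level coordinates are conditionally
independent across subjects, so their slice updates are vectorized over the
cohort.  Group spreads are slice-sampled on the log scale.  Slice sampling
needs no step-size tuning and never rejects, which keeps small-cohort fits
robust; split-R-hat and effective sample sizes are computed with arviz.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import betaln, expit

from . import psychometric as psy
from .errors import ConvergenceError, EmptyInputError, InsufficientDataError
from .preprocess import DominanceCurve

__all__ = [
    "PriorSpec",
    "MCMCSettings",
    "HierarchicalModel",
    "PosteriorDraws",
    "FitDiagnostics",
    "build_model",
    "fit",
    "summarize",
    "fit_independent",
]

_LN3x2 = 2.0 * math.log(3.0)

GROUP_PARAMS = ("mu_u", "sigma_u", "mu_v", "sigma_v",
                "delta_u", "sigma_delta_u", "delta_v", "sigma_delta_v")
SUBJECT_PARAMS = ("u_i", "v_i", "delta_u_i", "delta_v_i", "g_i", "lam_i", "sigma_i")


@dataclass(frozen=True)
class PriorSpec:
    """Priors of the hierarchical model (contrast / dominance units).

    ``tau_u`` and ``tau_v`` are the zero-centered prior scales of the group
    condition differences — the quantities whose prior density at zero enters
    the Savage-Dickey ratio.  ``prior_scale`` multiplies the four
    condition-difference scales (``tau_u``, ``tau_v`` and the half-normal
    scales of their between-subject spreads) and is the knob the prior
    sensitivity analysis turns.
    """

    mu_u_loc: float = 0.4          # centered at the fixed-grating contrast
    mu_u_scale: float = 0.3
    sigma_u_scale: float = 0.3
    mu_v_loc: float = float(np.log(0.3))
    mu_v_scale: float = 1.0
    sigma_v_scale: float = 0.5
    tau_u: float = 0.1
    sigma_delta_u_scale: float = 0.1
    tau_v: float = 0.1
    sigma_delta_v_scale: float = 0.1
    g_beta: tuple = (1.5, 8.0)
    lam_beta: tuple = (1.5, 8.0)
    sigma_obs_scale: float = 0.2
    pi_mixed_beta: tuple = (1.5, 6.0)   # trial-level likelihood only
    prior_scale: float = 1.0

    def __post_init__(self):
        for name in ("mu_u_scale", "sigma_u_scale", "mu_v_scale", "sigma_v_scale",
                     "tau_u", "sigma_delta_u_scale", "tau_v", "sigma_delta_v_scale",
                     "sigma_obs_scale", "prior_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"prior scale {name} must be > 0")

    def with_prior_scale(self, scale: float) -> "PriorSpec":
        """Rescale the condition-difference priors by ``scale``."""
        return replace(
            self,
            tau_u=self.tau_u * scale / self.prior_scale,
            tau_v=self.tau_v * scale / self.prior_scale,
            sigma_delta_u_scale=self.sigma_delta_u_scale * scale / self.prior_scale,
            sigma_delta_v_scale=self.sigma_delta_v_scale * scale / self.prior_scale,
            prior_scale=scale,
        )


@dataclass(frozen=True)
class MCMCSettings:
    chains: int = 4
    draws: int = 500
    warmup: int = 500
    seed: int = 0
    thin: int = 1
    hard_rhat: float | None = 1.1   # None disables the hard convergence check
    warn_rhat: float = 1.01

    def __post_init__(self):
        if self.chains < 2:
            raise ValueError("need at least 2 chains for split-R-hat")
        if self.draws < 1 or self.warmup < 0 or self.thin < 1:
            raise ValueError("invalid draw/warmup/thin counts")


# ---------------------------------------------------------------------------
# model container
# ---------------------------------------------------------------------------

@dataclass
class HierarchicalModel:
    """Data arrays and priors for one fit (see module docstring)."""

    subjects: list
    prior: PriorSpec
    likelihood: str
    # rectangular arrays (S, 2, P) with mask for ragged data
    x: np.ndarray
    y: np.ndarray        # gaussian: dominance values; trials: outcome codes
    mask: np.ndarray
    n_points: np.ndarray  # (S, 2)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_parameters(self) -> int:
        per_subject = 7 if self.likelihood == "gaussian" else 8
        return per_subject * self.n_subjects + 8

    def describe(self) -> str:
        return (f"hierarchical psychometric model: {self.n_subjects} subjects, "
                f"{self.likelihood} likelihood, {self.n_parameters} parameters, "
                f"prior_scale={self.prior.prior_scale}")


def _curves_to_frame(curves) -> pd.DataFrame:
    if isinstance(curves, pd.DataFrame):
        return curves
    frames = [c.to_frame() for c in curves]
    if not frames:
        return pd.DataFrame(columns=["subject_id", "condition", "midpoint", "dominance"])
    return pd.concat(frames, ignore_index=True)


def build_model(curves, prior_spec: PriorSpec | None = None,
                likelihood: str = "gaussian", trials: pd.DataFrame | None = None,
                subjects=None) -> HierarchicalModel:
    """Assemble the model from dominance curves (or raw trials).

    ``curves`` is a list of :class:`~rivalbias.preprocess.DominanceCurve` or a
    tidy frame with columns subject_id, condition, midpoint, dominance.  Every
    subject must appear in both conditions.  With ``likelihood="trials"``,
    pass the rivalry trials instead (columns subject_id, condition,
    manipulated_contrast, response); mixed reports are modeled through a
    per-subject mixed-report probability.
    """
    prior = prior_spec or PriorSpec()
    if likelihood not in ("gaussian", "trials"):
        raise ValueError(f"unknown likelihood {likelihood!r}")

    if likelihood == "gaussian":
        df = _curves_to_frame(curves)
        if len(df) == 0 and df.columns.size == 0:
            raise EmptyInputError("no curves supplied")
        xcol, ycol = "midpoint", "dominance"
    else:
        if trials is None:
            raise EmptyInputError("trial-level likelihood requires trials")
        df = trials[~trials["is_catch"] & (trials["response"] != "none")].copy()
        df["outcome"] = df["response"].map({"fixed": 0.0, "manipulated": 1.0, "mixed": 2.0})
        xcol, ycol = "manipulated_contrast", "outcome"
    if subjects is None:
        if df["subject_id"].nunique() == 0:
            raise EmptyInputError("no subjects in input")
        subjects = sorted(df["subject_id"].unique())
    else:
        subjects = list(subjects)  # may include data-free subjects (prior sampling)
    per = {}
    for sid in subjects:
        sub = df[df["subject_id"] == sid]
        conds = set(sub["condition"].unique())
        if conds != set(psy.CONDITIONS) and len(sub):
            missing = set(psy.CONDITIONS) - conds
            raise InsufficientDataError(f"subject {sid} missing condition(s) {missing}")
        for c, cond in enumerate(psy.CONDITIONS):
            g = sub[sub["condition"] == cond]
            per[(sid, c)] = (g[xcol].to_numpy(float), g[ycol].to_numpy(float))

    pmax = max((len(v[0]) for v in per.values()), default=0)
    S = len(subjects)
    x = np.full((S, 2, pmax), 0.5)
    y = np.zeros((S, 2, pmax))
    mask = np.zeros((S, 2, pmax))
    for i, sid in enumerate(subjects):
        for c in range(2):
            xv, yv = per[(sid, c)]
            x[i, c, :len(xv)] = xv
            y[i, c, :len(yv)] = yv
            mask[i, c, :len(xv)] = 1.0
    return HierarchicalModel(subjects=subjects, prior=prior, likelihood=likelihood,
                             x=x, y=y, mask=mask, n_points=mask.sum(axis=2))


# ---------------------------------------------------------------------------
# slice sampler
# ---------------------------------------------------------------------------

def _slice_sample(x0, logp, width, rng, max_steps=64, max_shrink=128):
    """One update of independent univariate slice samplers (vectorized).

    ``x0`` is a 1-d array of current values; ``logp`` maps such an array to
    the array of per-coordinate log densities (coordinate k of the output may
    depend only on coordinate k of the input).  Stepping-out with shrinkage
    (Neal 2003).
    """
    x0 = np.atleast_1d(np.asarray(x0, float))
    k = x0.shape[0]
    lp0 = logp(x0)
    level = lp0 + np.log(rng.uniform(size=k))

    u = rng.uniform(size=k)
    w = np.broadcast_to(np.asarray(width, float), (k,)).copy()
    left = x0 - u * w
    right = left + w
    for _ in range(max_steps):
        grow = logp(left) > level
        if not grow.any():
            break
        left = np.where(grow, left - w, left)
    for _ in range(max_steps):
        grow = logp(right) > level
        if not grow.any():
            break
        right = np.where(grow, right + w, right)

    x1 = x0.copy()
    todo = np.ones(k, bool)
    for _ in range(max_shrink):
        prop = np.where(todo, left + rng.uniform(size=k) * (right - left), x1)
        ok = logp(prop) >= level
        accept = todo & ok
        x1 = np.where(accept, prop, x1)
        # shrink the bracket toward x0 for still-pending coordinates
        pending = todo & ~ok
        below = pending & (prop < x0)
        above = pending & ~below
        left = np.where(below, prop, left)
        right = np.where(above, prop, right)
        todo = pending
        if not todo.any():
            break
    return x1


def _halfnormal_logpdf(x, scale):
    return np.where(x > 0, -0.5 * (x / scale) ** 2, -np.inf)


def _scaled_beta_logpdf(x, a, b, upper=0.5):
    z = np.asarray(x, float) / upper
    with np.errstate(divide="ignore", invalid="ignore"):
        lp = (a - 1) * np.log(z) + (b - 1) * np.log1p(-z) - betaln(a, b)
    return np.where((x > 0) & (x < upper), lp, -np.inf)


def _normal_logpdf(x, loc, scale):
    return -0.5 * ((x - loc) / scale) ** 2 - np.log(scale)


# ---------------------------------------------------------------------------
# posterior container
# ---------------------------------------------------------------------------

@dataclass
class FitDiagnostics:
    rhat: dict
    ess_bulk: dict
    divergences: int = 0

    @property
    def max_rhat(self) -> float:
        return float(max(np.nanmax(np.atleast_1d(v)) for v in self.rhat.values()))


@dataclass
class PosteriorDraws:
    """MCMC draws: group scalars (chains, draws), subject arrays (chains, draws, S)."""

    posterior: dict
    subjects: list
    prior: PriorSpec
    settings: MCMCSettings
    likelihood: str
    diagnostics: FitDiagnostics | None = None

    def group_samples(self, name: str) -> np.ndarray:
        return np.asarray(self.posterior[name]).reshape(-1)

    def subject_samples(self, name: str, subject_id) -> np.ndarray:
        i = self.subjects.index(subject_id)
        return np.asarray(self.posterior[name])[..., i].reshape(-1)

    def to_inference_data(self) -> az.InferenceData:
        return az.from_dict(posterior=self.posterior)


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------

class _Sampler:
    def __init__(self, model: HierarchicalModel):
        self.m = model
        self.S = model.n_subjects
        self.prior = model.prior
        self.trials = model.likelihood == "trials"

    # -- likelihood ---------------------------------------------------------

    def loglik_subjects(self, st) -> np.ndarray:
        m = self.m
        u, v = st["u_i"], st["v_i"]
        du, dv = st["delta_u_i"], st["delta_v_i"]
        g, lam = st["g_i"], st["lam_i"]
        ll = np.zeros(self.S)
        bad = (v <= 0) | (g <= 0) | (g >= 0.5) | (lam <= 0) | (lam >= 0.5)
        if not self.trials:
            sig = st["sigma_i"]
            bad |= sig <= 0
        for c, sign in enumerate((-1.0, 1.0)):
            u_c = u + sign * du / 2.0
            v_c = v + sign * dv / 2.0
            bad |= v_c <= 0
            s_c = np.maximum(v_c, 1e-9) / _LN3x2
            psi = (g[:, None]
                   + (1.0 - g - lam)[:, None]
                   * expit((m.x[:, c, :] - u_c[:, None]) / s_c[:, None]))
            if not self.trials:
                sig_safe = np.maximum(st["sigma_i"], 1e-12)
                r = (m.y[:, c, :] - psi) / sig_safe[:, None]
                ll += (m.mask[:, c, :] * (-0.5 * r * r)).sum(axis=1)
                ll -= m.n_points[:, c] * np.log(sig_safe)
            else:
                pi = np.clip(st["pi_i"], 1e-12, 1 - 1e-12)[:, None]
                p_raw = (psi - 0.5 * pi) / (1.0 - pi)
                p = np.clip(p_raw, 1e-9, 1 - 1e-9)
                o = m.y[:, c, :]
                logp_trial = np.where(
                    o == 2.0, np.log(pi),
                    np.log1p(-pi) + np.where(o == 1.0, np.log(p), np.log1p(-p)))
                ll += (m.mask[:, c, :] * logp_trial).sum(axis=1)
        return np.where(bad, -np.inf, ll)

    # -- priors -------------------------------------------------------------

    def subject_logprior(self, name, vals, st):
        p = self.prior
        if name == "u_i":
            return _normal_logpdf(vals, st["mu_u"], st["sigma_u"])
        if name == "v_i":
            # log v ~ N(mu_v, sigma_v); density of v includes 1/v Jacobian
            with np.errstate(divide="ignore", invalid="ignore"):
                lp = _normal_logpdf(np.log(np.maximum(vals, 1e-300)),
                                    st["mu_v"], st["sigma_v"]) - np.log(
                                        np.maximum(vals, 1e-300))
            return np.where(vals > 0, lp, -np.inf)
        if name == "delta_u_i":
            return _normal_logpdf(vals, st["delta_u"], st["sigma_delta_u"])
        if name == "delta_v_i":
            return _normal_logpdf(vals, st["delta_v"], st["sigma_delta_v"])
        if name == "g_i":
            return _scaled_beta_logpdf(vals, *p.g_beta)
        if name == "lam_i":
            return _scaled_beta_logpdf(vals, *p.lam_beta)
        if name == "sigma_i":
            return _halfnormal_logpdf(vals, p.sigma_obs_scale)
        if name == "pi_i":
            return _scaled_beta_logpdf(vals, *p.pi_mixed_beta, upper=1.0)
        raise KeyError(name)

    # -- updates ------------------------------------------------------------

    _WIDTHS = {"u_i": 0.05, "v_i": 0.1, "delta_u_i": 0.05, "delta_v_i": 0.05,
               "g_i": 0.05, "lam_i": 0.05, "sigma_i": 0.05, "pi_i": 0.1}

    def update_subject_param(self, name, st, rng):
        def logp(vals):
            st2 = dict(st)
            st2[name] = vals
            return self.loglik_subjects(st2) + self.subject_logprior(name, vals, st2)

        st[name] = _slice_sample(st[name], logp, self._WIDTHS[name], rng)

    def _conjugate_mean(self, values, spread, loc0, scale0, rng):
        n = len(values)
        prec = 1.0 / scale0 ** 2 + n / spread ** 2
        mean = (loc0 / scale0 ** 2 + values.sum() / spread ** 2) / prec
        return float(rng.normal(mean, prec ** -0.5))

    def _update_spread(self, values, mean, hn_scale, current, rng):
        """Slice-sample a group sd on the log scale (half-normal prior)."""
        x = np.asarray(values, float)

        def logp(log_s):
            s = np.exp(log_s)
            lp = _halfnormal_logpdf(s, hn_scale) + log_s  # Jacobian
            lp = lp + (-0.5 * ((x[None, :] - mean) / s[:, None]) ** 2).sum(axis=1) \
                - len(x) * log_s
            return lp

        new = _slice_sample(np.array([math.log(current)]), logp, 0.5, rng)
        return float(np.exp(new[0]))

    def _interweave_spread(self, st, rng, subj_key, mean_key, spread_key,
                           hn_scale, log_subject=False):
        """Non-centered re-update of a group spread (funnel breaker).

        Holding the standardized subject effects eps_i = (x_i - mean)/spread
        fixed, slice-sample the spread on the log scale under the data
        likelihood; subject values are then rescaled accordingly.  Interleaving
        this with the centered update (ancillarity-sufficiency interweaving)
        decorrelates spread and effects when the effects are weakly identified.
        """
        x = np.log(st[subj_key]) if log_subject else st[subj_key]
        mean, s = st[mean_key], st[spread_key]
        eps = (x - mean) / s

        def logp(log_s):
            out = np.empty(len(log_s))
            for j, ls in enumerate(log_s):
                s_new = math.exp(ls)
                x_new = mean + s_new * eps
                st2 = dict(st)
                st2[subj_key] = np.exp(x_new) if log_subject else x_new
                out[j] = (self.loglik_subjects(st2).sum()
                          + _halfnormal_logpdf(s_new, hn_scale) + ls)
            return out

        new = _slice_sample(np.array([math.log(s)]), logp, 0.5, rng)
        s_new = float(np.exp(new[0]))
        x_new = mean + s_new * eps
        st[spread_key] = s_new
        st[subj_key] = np.exp(x_new) if log_subject else x_new

    _GROUP_BLOCKS = (
        # subj_key, mean_key, spread_key, prior loc/scale attr, hn attr, log?
        ("u_i", "mu_u", "sigma_u", ("mu_u_loc", "mu_u_scale"), "sigma_u_scale", False),
        ("v_i", "mu_v", "sigma_v", ("mu_v_loc", "mu_v_scale"), "sigma_v_scale", True),
        ("delta_u_i", "delta_u", "sigma_delta_u", (None, "tau_u"),
         "sigma_delta_u_scale", False),
        ("delta_v_i", "delta_v", "sigma_delta_v", (None, "tau_v"),
         "sigma_delta_v_scale", False),
    )

    def update_group(self, st, rng):
        p = self.prior
        for subj_key, mean_key, spread_key, (loc_attr, scale_attr), hn_attr, \
                log_subject in self._GROUP_BLOCKS:
            loc0 = getattr(p, loc_attr) if loc_attr else 0.0
            scale0 = getattr(p, scale_attr)
            hn = getattr(p, hn_attr)
            x = np.log(st[subj_key]) if log_subject else st[subj_key]
            st[mean_key] = self._conjugate_mean(x, st[spread_key], loc0, scale0, rng)
            st[spread_key] = self._update_spread(x, st[mean_key], hn,
                                                 st[spread_key], rng)
            self._interweave_spread(st, rng, subj_key, mean_key, spread_key,
                                    hn, log_subject)

    # -- chain --------------------------------------------------------------

    def init_state(self, rng) -> dict:
        p = self.prior
        S = self.S
        st = {
            "mu_u": p.mu_u_loc + 0.05 * rng.normal(),
            "sigma_u": 0.1 * (1 + 0.2 * rng.uniform()),
            "mu_v": p.mu_v_loc + 0.1 * rng.normal(),
            "sigma_v": 0.3 * (1 + 0.2 * rng.uniform()),
            "delta_u": 0.02 * rng.normal(),
            "sigma_delta_u": 0.05 * (1 + 0.2 * rng.uniform()),
            "delta_v": 0.02 * rng.normal(),
            "sigma_delta_v": 0.05 * (1 + 0.2 * rng.uniform()),
        }
        st["u_i"] = st["mu_u"] + 0.05 * rng.normal(size=S)
        st["v_i"] = np.exp(st["mu_v"] + 0.1 * rng.normal(size=S))
        st["delta_u_i"] = 0.02 * rng.normal(size=S)
        st["delta_v_i"] = 0.02 * rng.normal(size=S)
        st["g_i"] = np.full(S, 0.05) * (1 + 0.2 * rng.uniform(size=S))
        st["lam_i"] = np.full(S, 0.05) * (1 + 0.2 * rng.uniform(size=S))
        st["sigma_i"] = np.full(S, 0.1) * (1 + 0.2 * rng.uniform(size=S))
        if self.trials:
            st["pi_i"] = np.full(S, 0.15) * (1 + 0.2 * rng.uniform(size=S))
        return st

    def subject_param_names(self):
        names = list(SUBJECT_PARAMS)
        if self.trials:
            names.append("pi_i")
        if self.trials:
            names.remove("sigma_i")
        return names

    def run_chain(self, settings: MCMCSettings, chain: int) -> dict:
        rng = np.random.default_rng([int(settings.seed), 7919, chain])
        st = self.init_state(rng)
        names = self.subject_param_names()
        store = {k: [] for k in GROUP_PARAMS + tuple(names)}
        total = settings.warmup + settings.draws * settings.thin
        for it in range(total):
            for name in names:
                self.update_subject_param(name, st, rng)
            self.update_group(st, rng)
            if it >= settings.warmup and (it - settings.warmup) % settings.thin == 0:
                for k in GROUP_PARAMS:
                    store[k].append(st[k])
                for k in names:
                    store[k].append(st[k].copy())
        return {k: np.asarray(v) for k, v in store.items()}


def fit(model: HierarchicalModel, mcmc_settings: MCMCSettings | None = None
        ) -> PosteriorDraws:
    """Draw from the joint posterior; attaches split-R-hat / ESS diagnostics.

    Chains run sequentially with independent seeded streams; identical
    settings and seed give identical draws.  Warns when any split-R-hat
    exceeds ``warn_rhat`` and raises :class:`ConvergenceError` above
    ``hard_rhat``.
    """
    settings = mcmc_settings or MCMCSettings()
    sampler = _Sampler(model)
    chains = [sampler.run_chain(settings, c) for c in range(settings.chains)]
    posterior = {k: np.stack([ch[k] for ch in chains]) for k in chains[0]}

    rhat_ds = az.rhat(az.from_dict(posterior=posterior))
    ess_ds = az.ess(az.from_dict(posterior=posterior))
    diagnostics = FitDiagnostics(
        rhat={k: np.asarray(rhat_ds[k]) for k in posterior},
        ess_bulk={k: np.asarray(ess_ds[k]) for k in posterior},
        divergences=0,
    )
    max_rhat = diagnostics.max_rhat
    if settings.hard_rhat is not None and max_rhat > settings.hard_rhat:
        raise ConvergenceError(
            f"max split-R-hat {max_rhat:.3f} exceeds hard threshold "
            f"{settings.hard_rhat}")
    if max_rhat > settings.warn_rhat:
        warnings.warn(f"max split-R-hat {max_rhat:.3f} > {settings.warn_rhat}; "
                      "consider more draws", stacklevel=2)
    return PosteriorDraws(posterior=posterior, subjects=list(model.subjects),
                          prior=model.prior, settings=settings,
                          likelihood=model.likelihood, diagnostics=diagnostics)


def summarize(draws: PosteriorDraws) -> pd.DataFrame:
    """Median, quartiles and central 95% interval per parameter.

    Subject-level parameters get one row per subject; these are the numbers a
    boxplot of the posterior samples would display.
    """
    rows = []
    for name, arr in draws.posterior.items():
        a = np.asarray(arr)
        if a.ndim == 2:  # (chains, draws)
            flat = a.reshape(-1)
            rows.append(_summary_row(name, None, flat))
        else:
            for i, sid in enumerate(draws.subjects):
                rows.append(_summary_row(name, sid, a[..., i].reshape(-1)))
    return pd.DataFrame(rows)


def _summary_row(name, sid, x):
    q = np.quantile(x, [0.025, 0.25, 0.5, 0.75, 0.975])
    return {"parameter": name, "subject_id": sid, "mean": float(np.mean(x)),
            "sd": float(np.std(x, ddof=1)), "lo95": q[0], "q25": q[1],
            "median": q[2], "q75": q[3], "hi95": q[4]}


# ---------------------------------------------------------------------------
# non-hierarchical reference fits (for shrinkage comparisons)
# ---------------------------------------------------------------------------

def fit_independent(curves) -> pd.DataFrame:
    """Per-subject least-squares psychometric fits, no pooling.

    Jointly fits both condition curves of each subject with the same
    parameterization as the hierarchical model (base u, v plus condition
    differences, shared g and lam), minimizing the squared error of the
    windowed dominance values.  Serves as the unpooled reference when
    quantifying shrinkage.
    """
    from scipy.optimize import least_squares

    df = _curves_to_frame(curves)
    rows = []
    for sid, sub in df.groupby("subject_id", sort=True):
        data = {}
        for c, cond in enumerate(psy.CONDITIONS):
            grp = sub[sub["condition"] == cond]
            data[c] = (grp["midpoint"].to_numpy(float),
                       grp["dominance"].to_numpy(float))

        def resid(theta):
            u, logv, du, dv, g, lam = theta
            v = math.exp(logv)
            out = []
            for c, sign in enumerate((-1.0, 1.0)):
                x, y = data[c]
                v_c = max(v + sign * dv / 2.0, 1e-4)
                u_c = u + sign * du / 2.0
                pred = g + (1 - g - lam) * expit((x - u_c) / (v_c / _LN3x2))
                out.append(y - pred)
            return np.concatenate(out)

        theta0 = np.array([0.4, math.log(0.3), 0.0, 0.0, 0.05, 0.05])
        lo = [-0.5, math.log(1e-3), -1.0, -1.0, 1e-4, 1e-4]
        hi = [1.5, math.log(3.0), 1.0, 1.0, 0.45, 0.45]
        sol = least_squares(resid, theta0, bounds=(lo, hi))
        u, logv, du, dv, g, lam = sol.x
        rows.append({"subject_id": sid, "u_i": u, "v_i": math.exp(logv),
                     "delta_u_i": du, "delta_v_i": dv, "g_i": g, "lam_i": lam,
                     "sse": float(2 * sol.cost)})
    return pd.DataFrame(rows)
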