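"""Non-hierarchical replication analyses.

These are the frequentist companions to the hierarchical model: a one-sample
t-test of the cohort priming proportion against chance, Pearson correlations
with default Bayes factors (e.g. mock priming vs. rivalry priming, VVIQ vs.
priming), trial binning by imagery vividness, and a one-way repeated-measures
ANOVA across vividness bins with Huynh-Feldt sphericity correction and a
linear polynomial contrast.

The correlation Bayes factor integrates the exact sampling density of the
Pearson r under a uniform stretched-beta prior on the population correlation
(the two-sided Jeffreys-type default); pingouin's closed-form implementation
of the same test is used as an independent cross-check in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, stats
from scipy.special import hyp2f1

from .errors import (DomainError, InsufficientDataError, PreconditionError,
                     UndefinedStatisticError)
from .preprocess import priming_proportion

__all__ = [
    "TTestResult",
    "CorrelationResult",
    "AnovaResult",
    "one_sample_t",
    "pearson_bf",
    "vividness_bins",
    "rm_anova_hf",
]


@dataclass(frozen=True)
class TTestResult:
    mean: float
    sd: float
    t: float
    df: int
    p: float
    cohen_d: float
    null_value: float


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    bf10: float
    n: int


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df1: float              # Huynh-Feldt corrected
    df2: float
    p: float
    epsilon_hf: float
    p_uncorrected: float
    ss_condition: float
    ss_subject: float
    ss_error: float
    F_linear: float
    df_linear: tuple
    p_linear: float


def one_sample_t(values, null_value: float = 0.5) -> TTestResult:
    """Two-sided one-sample t-test with Cohen's d."""
    x = np.asarray(values, float)
    if len(x) < 2 or not np.isfinite(x).all():
        raise DomainError("need >= 2 finite values")
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        raise UndefinedStatisticError("zero-variance sample: t undefined")
    res = stats.ttest_1samp(x, null_value)
    mean = float(np.mean(x))
    return TTestResult(mean=mean, sd=sd, t=float(res.statistic), df=len(x) - 1,
                       p=float(res.pvalue), cohen_d=(mean - null_value) / sd,
                       null_value=null_value)


def _log_density_ratio(rho, r, n):
    """log p(r | rho, n) - log p(r | 0, n) for the sample Pearson correlation.

    Based on the exact bivariate-normal sampling distribution of r; the
    rho-free factors cancel in the ratio.
    """
    h1 = hyp2f1(0.5, 0.5, n - 0.5, (rho * r + 1.0) / 2.0)
    h0 = hyp2f1(0.5, 0.5, n - 0.5, 0.5)
    return (0.5 * (n - 1) * np.log1p(-rho ** 2)
            - (n - 1.5) * np.log1p(-rho * r)
            + np.log(h1) - np.log(h0))


def pearson_bf(x, y) -> CorrelationResult:
    """Pearson correlation with two-sided p and a default Bayes factor.

    BF10 integrates the likelihood ratio of the observed r over a uniform
    prior on the population correlation (stretched beta with kappa = 1), the
    standard two-sided default test for the presence of a correlation.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 4:
        raise DomainError("need paired vectors of length >= 4")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise DomainError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedStatisticError("constant input: correlation undefined")
    r, p = stats.pearsonr(x, y)
    n = len(x)

    bf10, _ = integrate.quad(
        lambda rho: 0.5 * np.exp(_log_density_ratio(rho, r, n)),
        -1.0, 1.0, limit=200)
    return CorrelationResult(r=float(r), p=float(p), bf10=float(bf10), n=n)


def vividness_bins(trials: pd.DataFrame, n_bins: int = 4):
    """Per-subject priming effect across vividness bins.

    Each subject's rivalry trials are ranked by their vividness rating and cut
    into ``n_bins`` near-equal bins (sizes differ by at most one); the priming
    effect per bin is the proportion of decided (non-mixed) trials on which
    the imagined stimulus was perceived.  Subjects whose vividness is constant,
    who have fewer trials than bins, or who have a bin without decided trials
    are flagged and omitted from the returned table (and hence from the
    downstream ANOVA).

    Returns ``(table, flagged)``: a wide frame (subject x bin) and the list of
    flagged subject ids.
    """
    rivalry = trials[~trials["is_catch"] & trials["response"].notna()
                     & (trials["response"] != "none")
                     & trials["vividness"].notna()]
    rows, flagged = {}, []
    for sid, sub in rivalry.groupby("subject_id", sort=True):
        if len(sub) < n_bins or sub["vividness"].nunique() < 2:
            flagged.append(sid)
            continue
        order = np.argsort(sub["vividness"].to_numpy(), kind="stable")
        rank = np.empty(len(sub), dtype=int)
        rank[order] = np.arange(len(sub))
        bins = (rank * n_bins) // len(sub)
        vals = []
        try:
            for b in range(n_bins):
                vals.append(priming_proportion(sub.iloc[bins == b]))
        except UndefinedStatisticError:
            flagged.append(sid)
            continue
        rows[sid] = vals
    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"bin{b + 1}" for b in range(n_bins)])
    table.index.name = "subject_id"
    return table, flagged


def rm_anova_hf(matrix) -> AnovaResult:
    """One-way repeated-measures ANOVA with Huynh-Feldt correction.

    ``matrix`` is subjects x conditions (ordered levels).  The omnibus F is
    corrected for sphericity violation by multiplying both degrees of freedom
    with the Huynh-Feldt epsilon (clipped to [1/(k-1), 1]); the linear trend
    across the ordered levels is tested by a polynomial contrast with its own
    subject-level error term, F(1, n-1).
    """
    y = np.asarray(matrix, float)
    if y.ndim != 2:
        raise DomainError("matrix must be 2-d (subjects x conditions)")
    n, k = y.shape
    if k < 3:
        raise DomainError("need at least 3 within-subject conditions")
    if n < 3:
        raise InsufficientDataError("need at least 3 subjects")
    if not np.isfinite(y).all():
        raise PreconditionError("missing cells: complete the matrix upstream")

    grand = y.mean()
    ss_cond = n * ((y.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((y.mean(axis=1) - grand) ** 2).sum()
    ss_tot = ((y - grand) ** 2).sum()
    ss_err = ss_tot - ss_cond - ss_subj
    df1, df2 = k - 1, (n - 1) * (k - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    F = ms_cond / ms_err if ms_err > 0 else (0.0 if ms_cond == 0 else np.inf)
    p_unc = float(stats.f.sf(F, df1, df2))

    import pingouin as pg
    eps = float(pg.epsilon(pd.DataFrame(y), correction="hf"))
    eps = float(np.clip(eps, 1.0 / (k - 1), 1.0))
    df1c, df2c = eps * df1, eps * df2
    p = float(stats.f.sf(F, df1c, df2c))

    # linear polynomial contrast, tested against its own error term
    c = np.arange(k, dtype=float) - (k - 1) / 2.0
    L = y @ c
    mean_l, sd_l = L.mean(), L.std(ddof=1)
    if sd_l == 0:
        F_lin, p_lin = 0.0, 1.0
    else:
        t_lin = mean_l / (sd_l / math.sqrt(n))
        F_lin = float(t_lin ** 2)
        p_lin = float(stats.f.sf(F_lin, 1, n - 1))

    return AnovaResult(F=float(F), df1=float(df1c), df2=float(df2c), p=p,
                       epsilon_hf=eps, p_uncorrected=p_unc,
                       ss_condition=float(ss_cond), ss_subject=float(ss_subj),
                       ss_error=float(ss_err), F_linear=F_lin,
                       df_linear=(1, n - 1), p_linear=p_lin)
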