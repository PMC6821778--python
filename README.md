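# rivalbias

Analysis pipeline for studying how mental imagery biases conscious perception
in binocular rivalry.

## The problem

In binocular rivalry each eye sees a different grating and conscious
perception flips between them (or mixes). Sweep the contrast *x* of one
grating over [0, 1] while the other stays at 0.4, and the probability that
the manipulated grating dominates follows a psychometric curve

```
psi(x) = g + (1 - g - lam) / (1 + exp(-(x - u) / s)),    s = v / (2 ln 3)
```

with bias *u* (contrast at dominance 0.5), discrimination sensitivity *v*
(contrast span between dominance 0.25 and 0.75), guess rate *g* and lapse
rate *lam*. Imagining one of the gratings before each rivalry display shifts
this curve. The quantities of interest are the condition differences

* `delta_u = u_incongruent - u_congruent` — positive means imagery *primes*
  perception of the imagined grating, negative means *adaptation*;
* `delta_v` — positive means congruent imagery *sharpens* contrast
  sensitivity.

These are estimated for every subject and for the group in one hierarchical
Bayesian model, and each difference is tested against zero with a
Savage-Dickey Bayes factor `BF_+0 = p(delta=0) / p(delta=0 | data)`,
interpreted on the standard evidence ladder (band edges at ln 3, ln 10,
ln 30, ln 100). The scientifically interesting regime — and the default for
the synthetic cohorts — is a population whose mean effect is ~0 while
individual subjects carry strong effects of opposite sign: group evidence
then favors the null even though most subjects individually show decisive
effects.

The package is aimed at psychophysicists who want a tested reference
implementation of this analysis (dominance derivation, hierarchical fit,
Bayes factors, classical replication statistics) plus a ground-truth
simulator for power analysis and method validation. It ships with:

* `simulate` — synthetic cohorts with the experimental design (10 blocks x
  22 trials, 10% mock-rivalry catch trials, 99 contrasts per condition) and
  known per-subject ground truth;
* `preprocess` — response-bias exclusions (mock-priming > mean + 2 SD, or no
  responses), priming scores, and the sliding-window dominance derivation
  (11 consecutive contrasts, mixed reports = 0.5);
* `psychometric` — the four-parameter curve in the bias/sensitivity
  parameterization;
* `hierfit` — hierarchical MCMC (conjugate-Gibbs + slice sampling with
  non-centered interweaving) with arviz diagnostics, plus unpooled
  per-subject reference fits;
* `evidence` — Savage-Dickey Bayes factors (group and subject level),
  evidence categories, prior-sensitivity refits;
* `classical` — one-sample t-tests, correlations with default Bayes
  factors, vividness binning, repeated-measures ANOVA with Huynh-Feldt
  correction and linear contrast;
* `interface` — YAML-configured end-to-end runs and a thin `rivalbias` CLI.

See `docs/methods.md` for the model, priors, sampler and design choices.

## Worked example

```python
import numpy as np
from rivalbias import (CohortConfig, GroupTruth, simulate_cohort,
                       apply_exclusions, derive_all_curves, build_model, fit,
                       MCMCSettings, compute_bayes_factors, one_sample_t,
                       priming_proportion)

cfg = CohortConfig(n_subjects=12,
                   group_truth=GroupTruth(delta_u=0.0, sigma_delta_u=0.12))
cohort = simulate_cohort(cfg, seed=7)
trials, report = apply_exclusions(cohort.trials)
curves = derive_all_curves(trials)

priming = trials.groupby("subject_id").apply(priming_proportion,
                                             include_groups=False)
t = one_sample_t(priming, 0.5)
draws = fit(build_model(curves),
            MCMCSettings(chains=4, draws=500, warmup=500, seed=7))
bfs = compute_bayes_factors(draws, seed=7)
```

Output (about a minute on one core):

```
subjects kept: 11 | curves: 22
priming vs chance: M = 0.482, t(10) = -1.51, p = 0.161
group delta_u: log BF = -0.25 (anecdotal evidence for H0)
subject-level median log BF = 9.47
subjects with strong+ individual evidence (log BF > ln 10): 7/11
```

Reading the numbers: one of the 12 simulated subjects happened to exceed the
mock-priming exclusion threshold and was removed (`report.excluded` says
why). The cohort was generated with a zero *mean* imagery effect but large
between-subject spread, and the analysis recovers exactly that signature:
the group-level Bayes factor is inconclusive-to-null (log BF = -0.25), while
the median subject-level log BF of 9.47 — 7 of 11 subjects above ln 10 —
shows that most individuals have a decisive imagery effect; the effects
simply point in opposite directions and cancel at the group level.

The same pipeline runs from the shell:

```bash
rivalbias all --seed 7 --out runs/demo --subjects 12
```

writing trial data, ground truth, exclusion report, dominance curves,
posterior summaries, Bayes-factor tables and the classical-statistics report
into `runs/demo/`, together with the resolved YAML config that reproduces
the run bit-identically.

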