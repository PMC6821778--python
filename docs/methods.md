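# Methods

## The scientific question and the measurement

In binocular rivalry, each eye is shown a different grating and conscious
perception settles on one of them (or a mix). When the contrast of one
grating (the *manipulated* grating) is swept from 0 to 1 while the other is
held at 0.4, the probability that the manipulated grating dominates traces a
psychometric curve. Imagining one of the two gratings just before the rivalry
display shifts this curve: imagery of the manipulated grating (*congruent*
imagery) can make it need less contrast to dominate (priming) or more
(adaptation). `rivalbias` estimates these shifts per subject and for the
group, and quantifies the evidence for them with Bayes factors.

## Psychometric parameterization

The curve is

```
psi(x) = g + (1 - g - lam) * F(x; u, s),    F = logistic,    s = v / (2 ln 3)
```

* `u` — **bias**: contrast at which the inner sigmoid crosses dominance 0.5.
* `v` — **discrimination sensitivity**: contrast span between dominance 0.25
  and 0.75 of the inner sigmoid. The logistic scale follows from `v` as
  `s = v / (2 ln 3)`; a cumulative-Gaussian sigmoid
  (`s = v / (2 Phi^-1(0.75))`) is available as an option.
* `g`, `lam` — guess and lapse rates, the asymptote offsets at very low and
  very high contrast.

`u` and `v` are defined on the inner sigmoid, not the full curve, so they
remain interpretable regardless of `g` and `lam`; the informal reading of the
asymptotes ("dominance at contrast 0 / 1") is treated as asymptotic.

Condition differences use a symmetric half-difference split: congruent
imagery gets `u - delta_u/2`, incongruent `u + delta_u/2` (likewise `v` with
`delta_v`). Hence **`delta_u > 0` means priming** (less contrast needed under
congruent imagery) and **`delta_v > 0` means congruent sensitization**
(smaller 0.25–0.75 span). The base parameters are exactly the midpoint of
the two conditions, which makes the hierarchical shrinkage symmetric in the
conditions. `g` and `lam` are shared across conditions within a subject;
only the two deltas are tested.

## From categorical reports to dominance curves

Each rivalry trial yields a categorical report (manipulated / fixed / mixed /
none). Per subject and condition, trials are sorted by manipulated contrast
and a sliding window of 11 consecutive contrast values is moved along them;
each window contributes one dominance value,

```
dominance = (#manipulated + 0.5 * #mixed) / 11,
```

assigned to the midpoint `(min + max)/2` of the window's contrast range.
Values are therefore multiples of 0.5/11 and a sweep of `n` contrasts yields
`n - 10` points. Trials with no logged response are dropped *before*
windowing, so windows always span 11 consecutive remaining contrasts; the
no-response rate is a generator knob with no empirical target, and the
default rate (1%) is small enough that this choice is immaterial.

Subject exclusions use the catch trials (mock rivalry: a half/half composite
that should elicit "mixed"). The response-bias score is
`(#cue-matching + 0.5 * #mixed) / #responded` over catch trials — 0.5 is
unbiased. Subjects above the cohort mean + 2 SD are excluded, as are
subjects with no logged responses at all. Mixed reports count 0.5 here for
symmetry with the dominance rule.

## Hierarchical model

Likelihood (default): every windowed dominance value is
`y ~ Normal(psi(x), sigma_i)` with a per-subject noise level. Hierarchy:

```
u_i ~ N(mu_u, sigma_u)            log v_i ~ N(mu_v, sigma_v)
delta_u_i ~ N(delta_u, sigma_delta_u)
delta_v_i ~ N(delta_v, sigma_delta_v)
g_i, lam_i ~ 0.5 Beta(1.5, 8)     sigma_i ~ HalfNormal(0.2)
```

Group priors: `mu_u ~ N(0.4, 0.3)` (centered at the fixed-grating contrast),
`mu_v ~ N(log 0.3, 1)` on the log scale, `delta_u, delta_v ~ N(0, tau)` with
`tau = 0.1` contrast units, and half-normal priors on all group spreads
(scale 0.3/0.5 for the baselines, 0.1 for the delta spreads). The
`prior_scale` multiplier rescales the four delta-prior scales and is the knob
the prior-sensitivity analysis turns (default scales 0.5, 1, 2). All prior
settings are recorded in the resolved run config next to every output.

Two caveats are deliberate and documented rather than hidden:

* **Window autocorrelation.** Adjacent windows share 10 of 11 trials, so the
  Gaussian likelihood treats heavily overlapping values as independent and
  understates posterior widths on windowed data from binary trials. A
  trial-level multinomial likelihood (`likelihood="trials"`: mixed with
  per-subject probability `pi_i`, otherwise manipulated with probability
  `(psi - 0.5 pi_i)/(1 - pi_i)`) is provided as the correctly specified
  alternative. Calibration checks (interval coverage) are therefore run on
  data drawn from the Gaussian model's own generative process; passing them
  shows the inference machinery is correct, not that the default likelihood
  is well specified for raw windowed binary data.
* **Reconstructed priors.** The prior family and settings above are this
  package's own choices; they are not taken from any external model
  specification.

### Sampling

No gradient-based PPL is used; the posterior is sampled with a Gibbs scan:

* conjugate normal draws for the four group means;
* univariate slice sampling (stepping-out + shrinkage, Neal 2003) for all
  subject-level parameters — these are conditionally independent across
  subjects, so each scan updates the whole cohort vector at once;
* group spreads are slice-sampled on the log scale and then re-updated in
  the *non-centered* parameterization (ancillarity–sufficiency
  interweaving): holding the standardized subject effects fixed, the spread
  is slice-sampled under the data likelihood and the effects rescaled. This
  breaks the funnel coupling between a spread and its effects when the
  effects are weakly identified (e.g. `sigma_delta_v` when all
  `delta_v_i ~ 0`), which a purely centered sampler mixes through very
  slowly. The centered scan was kept (rather than a fully non-centered
  model) because it yields conjugate group-mean updates and, with ~90
  dominance values per subject and condition, the likelihood dominates and
  the residual funnel is mild.

Slice sampling needs no step-size tuning and never rejects; fixed bracket
widths (0.05–0.5 depending on the parameter) only affect efficiency, not
correctness. Chains run sequentially from independent seeded streams;
identical settings give bit-identical draws. Split-R-hat and bulk ESS are
computed with arviz for every parameter; fits warn above R-hat 1.01 and fail
above a configurable hard threshold (default 1.1). Divergences do not exist
for this sampler and are reported as zero.

Default settings (4 chains x 500 draws after 500 warmup) fit a 10-subject
cohort in under a minute on one core; 59 subjects take a few minutes. Test
and example fits use 2 chains and a few hundred draws — enough for the
qualitative properties they check while keeping the suite fast.

## Savage-Dickey Bayes factors

For the nested point null `delta = 0`,

```
BF_+0 = p(delta = 0) / p(delta = 0 | data).
```

The group-level prior density at zero is closed-form (`N(0; 0, tau)`). A
subject-level delta has marginal prior `N(delta_group, spread)` integrated
over the hyperpriors; the group mean integrates analytically and the spread
is averaged by Monte Carlo over its half-normal prior:
`E[ N(0; 0, sqrt(tau^2 + spread^2)) ]`.

Posterior density at zero: moment-matched normal of the MCMC draws (the
delta posteriors are near-Gaussian here), with a Gaussian KDE as cross-check;
a >25% disagreement triggers a warning since the normal approximation is
then questionable. Moment matching is preferred because KDE tail densities
at a point are noisy exactly where strong evidence lives.

Log BFs map onto the conventional ladder with edges at ln 3, ln 10, ln 30,
ln 100 (anecdotal / moderate / strong / very strong / extreme, for H+ above
zero and mirrored for H0 below; exactly zero is no evidence). Edge values
are assigned to the stronger band.

## Classical replication statistics

* **Priming vs. chance** — two-sided one-sample t-test of per-subject
  priming proportions (cue-matching fraction of decided reports, mixed
  removed) against 0.5, with Cohen's d.
* **Correlations** — Pearson r with a default two-sided correlation Bayes
  factor: the exact sampling density of r is integrated over a uniform
  stretched-beta prior on the population correlation (kappa = 1). This is a
  reconstruction of the unnamed "BF" convention for correlations; it
  reproduces values like BF = 0.17 at r = 0.03, n = 59, and agrees with the
  closed-form implementation in pingouin to well under 2%.
* **Vividness binning** — per subject, rivalry trials are rank-split into
  four near-equal bins by that subject's own vividness ratings (per-subject
  rather than pooled binning, so every subject contributes to every level);
  the priming proportion is computed per bin. Subjects with constant
  vividness, too few trials, or an undecidable bin are flagged and dropped
  listwise from the ANOVA — which is why its error df can fall below
  `n_subjects - 1`.
* **Repeated-measures ANOVA** — one-way within-subject ANOVA over the
  ordered bins, Huynh-Feldt epsilon (via pingouin, clipped to
  `[1/(k-1), 1]`) multiplying both dfs, plus a linear polynomial contrast
  tested against its own subject-level error term, `F(1, n-1)`. Note the
  textbook monotonicity "corrected p >= uncorrected p" holds when `F >= 1`;
  for `F < 1` shrinking both dfs can lower the p-value, which is a property
  of the F distribution, not an implementation artifact.

## The synthetic-cohort generator

The generator emulates the experiment's design exactly: 10 blocks x 22
trials per subject (220 total), imagery cues counterbalanced within blocks,
round(10%) catch trials spread across blocks, and each of 99 evenly spaced
contrasts in [0, 1] shown exactly once per condition in subject-randomized
order. (A 100-level grid with two conditions cannot fit into 198 rivalry
trials; 99 per condition is the largest even split consistent with the block
structure, and the grid length is configurable.) Fixed-grating contrast:
0.4.

Responses come from the psychometric model with known per-subject truth:
mixed with probability `pi_mixed_i` (contrast-independent — the simplest
model consistent with scoring mixed as 0.5), otherwise manipulated with
probability `(psi - 0.5 pi_mixed_i)/(1 - pi_mixed_i)` clipped to [0, 1], so
the expected dominance score equals `psi` wherever no clipping occurs. Catch
trials are answered "mixed" with probability `1 - bias_i` and with the cued
percept otherwise, so the expected mock-priming score is `0.5 + 0.5 bias_i`.
Any response turns into "none" with a small probability (default 1%).
Vividness is a per-trial truncated normal on [-150, 150]; an optional
coupling scales the trial-level effective `delta_u` linearly with
standardized vividness to emulate vividness-dependent priming (off by
default).

Population heterogeneity mirrors the qualitative structure of the real
cohort: bias profiles (primer / adapter / null at 40/35/25%) and slope
profiles (sensitizer / desensitizer / neutral at 30/30/40%) drawn
independently, with truncated-normal effect sizes
(`sigma_delta_u = 0.12`, `sigma_delta_v = 0.06` contrast units) around a
zero population mean — the regime where group-level evidence can favor the
null while individuals carry strong opposite-signed effects. Baselines:
`u_i ~ N(0.4, 0.12)`, `v_i` log-normal with median 0.3. Constructed outlier
subjects (an extreme response bias of 0.8, and an all-"none" subject) can be
injected for exclusion testing. Randomness flows from one master seed
through per-subject substreams keyed by a CRC32 hash of the subject id, so
datasets are reproducible and insensitive to subject ordering.

What the generator does **not** emulate: sequential/order effects, drift or
learning across blocks, contrast-dependent mixed-report rates, response
times, eye-dominance measurement (a label only), or any stimulus-level
detail. Passing recovery tests on this generator therefore demonstrates the
estimator works when its assumptions hold (plus the stated window-likelihood
caveat); it cannot certify behavior under real-data pathologies outside the
model family.

## Numerical and degenerate-input conventions

* Windowing requires at least `window_size` trials; fewer is an error, as
  are unfiltered "none" responses or catch trials.
* Priming and mock-priming scores are undefined (error) with no decided /
  responded trials; exclusion statistics with zero between-subject SD
  exclude nobody.
* `invert` only accepts dominance strictly inside `(g, 1 - lam)`.
* `condition_params` refuses deltas that drive a condition's `v`
  non-positive; the generator truncates `delta_v_i` to keep both conditions
  positive.
* Bayes-factor density estimation requires >= 1000 draws and errors on
  zero-variance samples.
* Quantile summaries use linear interpolation (the numpy default).

## Known limitations

* The default Gaussian-window likelihood understates uncertainty on windowed
  binary data (see above); use `likelihood="trials"` when honest subject-
  level uncertainty on raw trial data matters.
* Savage-Dickey by moment matching assumes near-Gaussian marginal
  posteriors; heavy skew triggers a warning but is not corrected.
* The slice-within-Gibbs sampler is robust but not gradient-fast; very
  large cohorts (hundreds of subjects) would warrant an HMC backend.
* Group-level BF_+0 is two-sided despite the one-sided-looking subscript:
  the alternative is "a difference exists", matching the evidence ladder
  used for interpretation.
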