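# Methods

## Design and data model

The pipeline targets a two-arm randomized trial crossed with two age groups.
Each participant contributes:

* 72 recognition trials at the final visit — 36 studied and 36 new pictures,
  12 per valence (neutral/positive/negative) per status, answered
  *Remember*, *Know*, or *New*;
* dual-coder recall codings at two visits (Weeks 4 and 5): each studied
  picture coded 0 (not recalled), 1 (recalled), or occasionally 2 (two
  recalled descriptions matched the same picture), plus sentinel
  `incorrect_*` entries for descriptions matching no picture;
* pre- and post-intervention amygdala–mPFC connectivity betas (extracted
  upstream from resting-state fMRI; MRI processing is out of scope here);
* covariates: mood change (mean of Weeks 4–5 minus mean of Weeks 1–2) and
  RMSSD change (mean of Weeks 4–5 minus Week 2).

## Memory scoring

An item is *called old* iff the response is Remember or Know — the standard
Remember/Know convention. Per participant × valence we report hit rate,
false-alarm rate, corrected recognition (hits − FA), and the Remember/Know
decomposition of both rates; denominators (12/12 on conforming designs) are
carried in the output.

Recall codes are reconciled with a configurable rule, default **max-code**
(elementwise maximum, favouring "reported"). Real dual-coding protocols
resolve discrepancies by human adjudication; an automated merge cannot
reproduce that, so the rule is exposed and the discrepancy list is always
returned for audit. Tallies sum codes per valence (a 2 contributes 2), so a
per-valence count can exceed 12 only through code-2 entries.

## Inter-rater reliability

Krippendorff's α = 1 − Do/De over the coder × unit matrix, units being
(participant, picture) pairs. Codes are match categories, not magnitudes, so
the **nominal** metric is the default (an interval metric is exposed for
ordered codes). Missing codings are excluded per unit; units with fewer than
two codings contribute nothing. A matrix whose pairable codings are a single
value has De = 0 and raises a degenerate-input error rather than returning
1.0. The CI is a nonparametric bootstrap over units (default 1000
replicates), percentile method — the same percentile routine used for the
mediation bootstrap; degenerate replicates are skipped and counted.

## Bias composite

`bias = (z_FA_pos − z_FA_neg) + (z_Recall_pos − z_Recall_neg)`, all four
columns z-scored across participants with the sample SD (n − 1 denominator,
the common statistics-package default). Week-5 false alarms are used because
differential false alarms across valences isolate response bias, whereas
differential hits confound bias with accurate memory; Week-5 (not Week-4)
recall keeps the two ingredients contemporaneous and maximizes scope for
retrieval bias once veridical memory has weakened. Z-scoring happens on the
listwise-complete participant set after intersecting the recognition and
recall samples (a flag could standardize before intersecting; the composite
is computed after by default). Constant columns and missing values raise
errors — z-scores are never silently zeroed and missingness is handled
listwise at the pipeline level, never pairwise.

Consequences used as test oracles: every z-column and the composite are
mean-zero; swapping positive and negative columns negates every score;
positive affine rescaling of any raw column leaves scores unchanged.

## Mediation model

Three OLS regressions on the same sample and covariate set:
`m ~ x (+Z)` gives *a*; `y ~ m + x (+Z)` gives *b* and *c′*;
`y ~ x (+Z)` gives *c*; `ab = a·b`, and `c = c′ + ab` holds exactly (this
identity is asserted to 1e−10 in tests). Condition is coded **Osc+ = 0,
Osc− = 1**; with the Osc+ arm raising connectivity and bias, *a*, *c* and
*ab* come out negative, which is the sign convention used throughout.
Covariates enter all three regressions. Pre-intervention connectivity is
always included so the mediator effectively represents intervention-induced
connectivity *change*.

Inference is a case-resampling bootstrap: participants are resampled with
replacement, all regressions refit (vectorized batched normal-equation
solves), and percentile intervals taken with linear interpolation between
order statistics (the `numpy.quantile` default) so intervals are
reproducible. Percentile rather than bias-corrected intervals are used — the
plain percentile interval is the default of current mediation macros and its
coverage is verified directly (below). Replicates with a constant resampled
exposure are redrawn and counted; more than 10% redraws triggers a warning.
The Sobel first-order test (`z = ab/√(b²·se_a² + a²·se_b²)`) is provided as
an analytic cross-check only.

## ANOVA engine

Split-plot designs with up to two between- and two within-subject factors,
each participant contributing exactly one observation per within cell.
Between effects are tested from an OLS fit to subject means (SS rescaled by
the number of within cells) against subjects-within-groups error; each
within-subject term is tested by projecting subject profiles onto an
orthonormal contrast basis for that term and regressing the contrast scores
on the between design, against the term × subjects-within-groups error.
Between-subjects SS are **Type III** via sum-to-zero coding with the full
factorial model, matching SPSS defaults for unbalanced groups; within-effect
tests therefore use unweighted (equally-weighted-cell) means, which differs
from weighted-means packages on unbalanced data and coincides on balanced
data (the test suite checks both regimes against pingouin, statsmodels and a
direct cell-means oracle). No sphericity correction is applied — integer
degrees of freedom are reported, mirroring common reporting practice; users
needing Greenhouse–Geisser should treat within-factor p-values with >2
levels accordingly. Effect size is partial η² = SS_effect/(SS_effect +
SS_error). A constant dv yields SS = 0 everywhere; F is reported as 0 with a
`degenerate` flag rather than NaN. Follow-up pairwise contrasts carry no
multiple-comparison correction anywhere in the pipeline — a
faithful-reporting choice, not a statistical recommendation.

## Synthetic cohort generator

Generative structure (condition x ∈ {0,1}, Osc+ = 0):

```
pre    ~ Normal(0, 1)
post   = rho_pre·pre + true_a·x (+ age offset) + Normal(0, sigma_m)
latent = true_c_prime·x + true_b·post (+ age offset) + Normal(0, sigma_y)
```

The latent bias trait expresses in behavior through range-safe links —
logit-scale shifts of ±bias_gain·latent for hit and false-alarm
probabilities (positive valence up, negative down, neutral unshifted), and
log-scale shifts of expected recall counts; recognition outcomes are
binomial over 12 items per valence × status cell, recall counts Poisson
truncated at 12, with the recalled items drawn uniformly and upgraded to
code 2 with probability 0.01. The second coder flips each code with the
configured disagreement probability (0↔1, 2→1). Incorrect recalls are
Poisson sentinel entries shared by both coders. Age-group effects default to
zero, with optional additive offsets.

Default conditions: 36 participants per design cell (N = 144);
`true_a = −0.4`, `true_b = 0.38`, `true_c_prime = −0.28` (slope-scale
indirect effect −0.152, a small-to-medium effect of the kind such trials
report); base hit 0.87, base false alarm 0.05; Week-5 recall 1.8 per
valence, Week-4 4.0; Remember fraction 0.65 of hits and 0.25 of false
alarms; `bias_gain = 0.35`; coder disagreement 0.025 (yielding α in the low
0.9s); unit-variance noise throughout and standard-normal connectivity
scales — conventional choices, since connectivity betas have no canonical
scale.

What the generator does **not** emulate: dropout/attrition, fMRI/HRV time
series, item-level difficulty or memorability structure, coder biases that
are correlated rather than independent across items, and any nonlinearity in
the connectivity→bias link. Passing calibration therefore shows the
estimator is correct under its assumed linear data-generating process, not
that real data satisfy those assumptions.

## Calibration

Because the behavioral readout (binomial/Poisson links plus
cross-participant z-scoring) rescales the latent effect, calibration studies
that compare estimates to slope-scale truth use the **linear** outcome
configuration — the latent trait itself as y — while the full behavioral
pipeline is checked for sign recovery only. Study sizes: CI coverage over
200 cohorts (n = 60/cell, 1000 bootstrap replicates; target band
0.90–0.99 for a nominal 95% interval), point recovery of ab = 0.30 over 100
cohorts (n = 250/cell, within ±25%), Sobel/bootstrap verdict concordance
over 200 cohorts (n = 150/cell), and behavioral sign recovery over 100
cohorts (|a·b| = 0.36). These sizes keep each study within tens of seconds
on one core while leaving binomial noise on the reported rates well inside
the target bands.

## Pipeline and bookkeeping

`run_pipeline` validates the five input CSVs against their schemas (first
offending row named), then runs scoring → reliability → bias → ANOVAs →
mediation (one model per covariate set: always pre-connectivity; optionally
mood change and RMSSD change). Every stage logs N in/out; participants
dropped by listwise exclusion appear in the manifest with reason codes, and
downstream Ns are never larger than upstream ones. All stage seeds derive
from the single config seed via a seed sequence, so a rerun with the same
config is byte-identical.

## Known limitations

* The automated coder-merge rule is a stand-in for human adjudication.
* No sphericity correction, no multiple-comparison correction, percentile
  (not BCa) bootstrap intervals — all faithful-reproduction choices.
* One mediator, continuous outcome, OLS only; no moderated mediation,
  standardized effect sizes, or sensitivity analysis for unmeasured
  confounding of the mediator–outcome path.
* The generator's effect scales are conventional, not estimated from data.
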