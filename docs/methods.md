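# Methods

This note documents the models, conventions and calibration behind
`dotbias`, in the spirit of a methods appendix: what is simulated, what is
estimated, which choices were genuinely open, and what the synthetic
results do and do not show about real data.

## Stimulus geometry

Stimuli are circular patches (default radius 6 deg of visual angle per
patch, configurable — the patch size is our choice; it comfortably holds
100 dots at the 0.25-deg minimum spacing on a laptop display at 57 cm).
Dots are 2.5 mm disks, half black and half white so mean luminance does
not covary with number.  Units: millimetres for physical sizes, degrees
for coordinates, with the small-angle linear conversion fixed by the
viewing distance (57 cm ⇒ 1 cm = 1 deg).

Connected patterns are cast in two stages, taken literally:

1. *Pairs first.*  `round_to_even(0.4·n)/2` pairs are placed; the second
   dot of a pair sits at a uniform-random direction and uniform-random
   length in [10, 15] mm from the first, and the pair is joined by a
   0.5-mm line of the pair's colour.  "Neighbouring dots" is thus
   operationalized as jointly-cast pairs, not post-hoc nearest neighbours.
   Constraints: minimum spacing between all dot centres, no two
   connectors crossing (exact orientation-test predicate; collinear
   touching counts as crossing), and connectors keep at least
   `dot_radius + line_width/2` from every other dot.
2. *Loose dots second.*  The remaining dots are cast avoiding all dots
   and all connector ink.  The required dot-to-line clearance is not
   quantified in the protocol beyond "not overlapping"; we use exact
   ink non-overlap plus a configurable extra margin (default 0).

Pair colours alternate black/white and loose dots fill the remaining
quota, so the black/white counts differ by at most one.  (With
`connect_fraction = 1` and an odd number of pairs, exact balance is
impossible for monochrome pairs; the default 0.4 never hits this corner.)
Placement is rejection sampling with a cap of 10,000 attempts per
element; exhaustion raises `PlacementError`, signalling that the field
cannot hold the requested numerosity at the configured spacing.

Sessions do not rasterize a pattern per trial: the decision model
consumes numerosities, so geometry is generated on demand (for figures,
fixtures and the invariant checks).

## QUEST engine

A discretized-grid posterior over the PSE, updated in linear numerosity
with a cumulative-Gaussian likelihood at criterion 0.5 ("PSE mode", guess
rate 0) and a symmetric lapse floor:
`P(chose probe | PSE=x) = λ + (1−2λ)·Φ((probe − x)/σ_q)`, λ = 0.02.
None of the engine's hyperparameters are given by the protocol, so they
are package choices, all configurable:

* prior: Gaussian centred on the reference with SD 40% of the reference,
  discretized on a 301-point grid spanning ±4 prior SDs (clipped below at
  1 dot);
* assumed spread `σ_q` = 0.25 × reference, matching the synthetic
  observers' decision noise convention;
* PSE estimator fed to probe placement: the posterior mean;
* probe = round(posterior mean + N(0, 0.5 dots)), clamped at ≥ 2 dots;
  the first trial uses the same rule applied to the prior.  The 0.5-dot
  jitter is used at every numerosity, as specified by the protocol, even
  though at N=100 it spans a negligible fraction of the discrimination
  range (a per-numerosity fractional override is exposed); at high
  numerosities the spread of sampled probes comes mostly from the
  posterior-mean trajectory itself.
* the engine is re-initialised for every (numerosity × condition) block.

Updates are exact Bayes on the grid, hence order-equivariant; probes
outside the grid are clamped with a warning.  Probes may equal the
reference, and such trials are retained.

## Synthetic observers

`perceived numerosity`: isolated patterns are veridical; connected
patterns are underestimated by a two-level step — `bias_low` for N ≤ 50,
`bias_high` for N = 100 — because the analysis (and the phenomenon)
separates exactly these regimes.  Per-numerosity overrides are available;
any smoother interpolation would be unconstrained by the group data the
model is anchored to.

Decision rule: `P(choose probe) = λ/2 + (1−λ)·Φ((probe − ref_perc)/(w·ref_perc))`
with lapse λ = 0.02 and `w` the coefficient of variation of the decision
noise (default 0.25).  Note the fitted Weber fraction is
`0.6745·w·(ref_perc/PSE) ≈ 0.17` under this convention; no result depends
on the absolute WF, only on its equality across groups, which holds by
construction (`w` is drawn independently of AQ, SD 0.03).

Reaction times are lognormal (log-mean ln 0.6 s, log-SD 0.3) with a 1.5%
mixture of long outliers (×6).  The outlier mixture is deliberate: under
a per-subject mean ± 2 SD trimming rule a pure lognormal loses ~4% of
trials at any log-SD, whereas rare extreme outliers inflate the SD enough
that trimming removes only ~1.5% — the regime real unspeeded-response
data sit in.

### Cohort calibration

AQ scores are integers from a truncated normal on [0, 50], centre 14,
spread 9.  The truncation at 0 shifts the distribution right, putting the
integer population median at 15 with quartiles 9/21 and ~3% of scores at
or above the clinical-referral threshold of 32 — the intended sample
profile.  Per-observer biases are linear in the integer AQ score (no
latent trait), clipped to [0, 0.6]:

| regime | intercept | slope (per AQ point) | median-split group means |
|---|---|---|---|
| low (N ≤ 50) | 0.374688 | −0.011141 | 27% / 13% |
| high (N = 100) | 0.132234 | −0.002366 | 11% / 8% |

The coefficients were solved once, by Monte-Carlo, so that the *expected
median-split group means over 21-subject cohorts* equal the four anchor
percentages; these are acknowledged calibration targets of the generator,
not free parameters.  Because the bias is a deterministic function of AQ,
synthetic cohorts produce bias–AQ correlations near 0.97 — higher than
any real sample, where trait scatter and day-to-day variability attenuate
the correlation.  Passing tests therefore demonstrate pipeline
correctness and calibration, not realistic effect-size forecasts.

## Analysis

* RT trimming: one pass per subject over the whole session, mean ± 2
  sample SDs (ddof 1); a zero-SD subject keeps everything.
* Psychometric fits are per subject × condition × numerosity:
  maximum-likelihood Bernoulli fits of `Φ((x − PSE)/σ)` in linear
  numerosity, no lapse term by default (available as an option).
  Optimisation: L-BFGS-B on (PSE, log σ) with analytic gradients,
  three deterministic starts seeded from empirical quantiles, tolerance
  1e-8, bounds PSE ∈ data range ± 2 spans and σ ∈ [10⁻³, 10] × scale.
  Separable (step) data drive σ to its lower bound; all-identical
  responses raise an estimation error.  JND = Φ⁻¹(0.75)·σ; WF = JND/PSE
  (the *perceived* quantity, i.e. the fitted PSE, is the denominator);
  per-subject WF summaries average over all numerosities and both
  conditions.
* Median split: scores equal to the sample median join the LOW group —
  the convention that reproduces an 11/10 split for 21 subjects with
  median 15.
* Regimes: low = {15, 25, 50} (unweighted mean across numerosities),
  high = {100}; configurable.
* ANOVA: classical balanced two-way within-subject sums-of-squares
  decomposition, each effect tested against its subject-by-factor
  stratum.  No sphericity correction (none is applied in the analyses
  this mirrors) and no Bayesian model-averaged ANOVA (out of scope; the
  classical F table stands in).

## Bayes factors

All four integrators use adaptive quadrature with absolute tolerance
≤ 1e-10 and are validated against dense-grid trapezoid oracles (1e-6
relative) and against pingouin's independent implementations.

* `bf_ttest_jzs(t, n1, n2, scale=1/√2)`: Rouder-style two-sample JZS BF,
  integrating over the inverse-gamma mixture representation of the
  Cauchy prior with effective N = n1·n2/(n1+n2), ν = n1+n2−2.
* `bf_ttest_jzs_paired(t, n)`: the same integral with N = n, ν = n−1.
* `bf_pearson(r, n, width=1)`: exact stretched-beta correlation BF —
  Fisher's sampling density of r (via ₂F₁) integrated against a
  Beta(1/k, 1/k) prior stretched to (−1, 1).
* `bf_pearson_jzs(r, n)`: the regression-form JZS correlation BF of
  Wetzels & Wagenmakers (2012).

**Reproducing the published values.**  The published group-comparison
log-BFs (1.08 for t = 3.32; −0.56 for t = 0.62, groups 11/10) do *not*
arise from the canonical two-sample JZS at scale 1/√2 (which gives 1.05
and −0.35); they are matched exactly, robustly to rounding of t, by the
JZS integral with 20 paired differences — the numbers the original JASP
workflow evidently produced from a paired-design entry of the 21
subjects' data.  Likewise the published correlation log-BFs (2.1 for
r = 0.72; −0.55 for r = 0.24, n = 21) match the Wetzels regression form,
not the stretched-beta default (2.18 / −0.34).  The package therefore
ships both forms: the canonical ones drive the pipeline's own reports,
and the paired/regression forms are used when reproducing the published
numbers (`scripts/acceptance.py`); report output prints both.

## Problem sizes and degenerate inputs

The shipped tests exercise the full 1440-trial default session per
subject for bookkeeping and calibration checks; the 50-cohort null-model
sweep uses 60 trials per cell over the low-regime numerosities, which
only adds measurement noise and is therefore conservative for a null
check.  Degenerate inputs are defined, not left to chance: zero RT
spread keeps all trials, an empty high group after a degenerate median
split warns, missing ANOVA cells raise (no imputation), probes outside
the QUEST grid clamp with a warning, and placement failure raises rather
than looping forever.

## Known limitations

* No display calibration, timing, or trial-by-trial stimulus images in
  the simulated sessions; the link from geometry to perception is the
  two-level bias surface, not an image-computable model.
* The bias–AQ relation is noiseless by construction (see above).
* AQ item-level structure (five subscales) is not modelled; only the
  mechanical 0–50 scoring rule is implemented.
* The JND reading "difference between the 50% and 75% points" is mapped
  to 0.6745·σ of the fitted probe-choice function; folded-function
  readings are not implemented.
* Cumulative-Gaussian fits are frequentist point fits; no bootstrap or
  Bayesian CIs on the PSE.
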