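# dotbias

Connecting pairs of dots with thin lines makes a cloud of dots look *less*
numerous: the visual system groups each connected pair into a single
perceptual unit before numerosity is estimated.  The strength of this
connectedness illusion is a behavioural probe of perceptual grouping, and
it varies systematically with autistic-like personality traits measured by
the autism-spectrum quotient (AQ): observers with higher AQ show a weaker
illusion, consistent with a more local, less grouping-driven perceptual
style.

`dotbias` is a simulation-and-analysis package for this paradigm, aimed at
psychophysicists who want to prototype, power-analyse, or reanalyse
connected-dots numerosity experiments.  It provides:

* **Stimulus geometry** — constrained random dot patterns (2.5 mm disks,
  half black / half white, minimum spacing 2.5 mm) with 40% of dots cast as
  pairs joined by 10–15 mm non-crossing lines, plus loose dots that avoid
  all ink; patterns can be rendered, serialized, and invariant-checked.
* **QUEST engine** — a discretized-posterior Bayesian adaptive procedure
  that tracks the point of subjective equality (PSE) and places each probe
  at the running estimate perturbed by N(0, 0.5 dots).
* **Synthetic observers** — a generative cohort model: integer AQ scores
  from a truncated normal, connectedness bias linear in AQ (calibrated so
  median-split group means reproduce the canonical 27%/13% underestimation
  at N=15 and 11%/8% at N=100), Weber-scaled decision noise equal across
  groups, lapses, and skewed reaction times.  Plus the mechanical 50-item
  AQ scoring rule for real questionnaires.
* **Psychometrics** — per-subject RT trimming (mean ± 2 SD) and
  maximum-likelihood cumulative-Gaussian fits:

  `P(probe judged more numerous | x) = Φ((x − PSE)/σ)`,
  `JND = Φ⁻¹(0.75)·σ ≈ 0.6745 σ`, `WF = JND / PSE`,
  `bias% = 100·(PSE − N_ref)/N_ref`.
* **Group statistics** — AQ median split, pooled-variance t tests, Pearson
  correlations, two-way within-subject ANOVA, Jarque–Bera, and Bayes
  factors by direct numerical integration: the JZS t-test BF (Cauchy prior
  on effect size, default scale 1/√2, two-sample and paired forms), the
  stretched-beta correlation BF, and the regression-form JZS correlation
  BF.

## Worked example

Simulate the default experiment (21 observers × 4 reference numerosities
× {isolated, connected} × 180 trials = 1440 trials each), fit, and report:

```python
from dotbias.pipeline import (RunConfig, simulate_cohort_trials, analyze,
                              report, render_report_text)

trials, aq_table = simulate_cohort_trials(RunConfig(seed=1))   # 30240 trials
fits = analyze(trials)                                         # 168 fits
print(render_report_text(report(fits)))
```

Output (seed 1):

```
N = 21 subjects; AQ median split at 14 -> 12 low / 9 high
AQ normality: JB = 0.07, p = 0.97
[low_regime] connected bias: low-AQ -24.9 +/- 0.8%, high-AQ -18.4 +/- 0.9%
  bias~AQ: r = 0.97, p = 1.69e-13, log10 BF = 10.71 (jzs) / 10.30 (stretched beta)
  groups: t(19) = -5.52, p = 2.53e-05, log10 BF = 2.98 (paired-eq) / 2.80 (two-sample)
[high_regime] connected bias: low-AQ -11.5 +/- 0.7%, high-AQ -9.3 +/- 0.8%
  bias~AQ: r = 0.58, p = 0.0057, log10 BF = 0.87 (jzs) / 0.99 (stretched beta)
  groups: t(19) = -2.18, p = 0.0417, log10 BF = 0.20 (paired-eq) / 0.28 (two-sample)
ANOVA reference_n: F(3,60) = 40.29, p = 2.17e-14
ANOVA condition: F(1,20) = 405.69, p = 9.44e-15
ANOVA reference_n:condition: F(3,60) = 59.32, p = 6.09e-18
WF: low-AQ 0.141, high-AQ 0.133; t = 0.58, log10 BF = -0.35
```

Read this as: connected patterns are underestimated strongly at low
numerosities and weakly at N=100; the underestimation shrinks with AQ
(positive bias–AQ correlation — less negative bias at higher AQ) in the
low regime with decisive Bayes evidence, while the numerosity × condition
interaction confirms the illusion's dependence on numerosity; Weber
fractions do not differ between AQ groups, so the groups differ in
grouping, not in discrimination precision.  (The synthetic bias–AQ
correlation is near-deterministic by construction; real observers add
trait scatter that lowers it — see `docs/methods.md`.)

The same workflow is available from the shell:

```
dotbias simulate --seed 1 --out run1      # per-subject CSV trial logs
dotbias analyze run1 --out fits.csv
dotbias report fits.csv --out report.json
dotbias figures run1                      # psychometric curves + stimuli
dotbias bf t 3.32 --n1 11 --n2 10         # standalone Bayes factors
dotbias bf r 0.72 --n 21 --jzs
```

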