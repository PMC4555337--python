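# orcurve

Monte Carlo study of what happens to odds ratios when a continuous
exposure, measured with error, is categorized — and of the differential
misclassification that categorization manufactures.

Epidemiologists routinely dichotomize continuous exposures (a pollutant
level, gestational age) at a cutoff, then report an odds ratio from
logistic regression. The cutoff is a free choice, and when the exposure
carries classical measurement error the choice has consequences beyond
attenuation: the binary misclassification it induces becomes
*differential* — classification accuracy differs between cases and
controls — even though the underlying error is non-differential. This
package simulates that situation end to end in a large synthetic birth
cohort modeled on an enriched-risk autism pregnancy cohort, and maps the
bias as a function of the cutoff.

## Model

A cohort of n = 1,000,000 children is generated with

* true exposures X₁, X₂ ~ N(0, 1), Pearson corr(X₁, X₂) = ρ = 0.7
  (only X₁ is causal);
* sex Z ~ Bernoulli(0.5); true gestational age X_ga = 43 − γ weeks,
  γ ~ χ²(3), one week subtracted for a random 5% of boys; observed
  gestational age rounded to completed weeks and restricted to
  [23, 43] (live-birth inclusion);
* observed exposures under classical error, W₁ = X₁ + ε₁ with
  ε₁ ~ N(0, σ²), σ² ∈ {0, 0.0625, 0.25, 1}, and W₂ = X₂ + ε₂,
  ε₂ ~ N(0, 0.25);
* a latent outcome Y with one of three exposure-response shapes around
  the inflection point mean(X₁) − SD(X₁):

  | shape      | slope below inflection | slope at/above |
  |------------|-----------------------|----------------|
  | linear     | β₁                    | β₁             |
  | threshold  | 0                     | 1.5 β₁         |
  | saturation | 1.5 β₁                | 0.5 β₁         |

  plus β₂X₂ + β₃Z + β₄X_ga + ε_y with β₂ = 0, β₃ = 1, β₄ = 0.1,
  ε_y ~ N(0,1), and β₁ ∈ {0.15, 0.25, 0.5} (weak/moderate/strong);
* Y mapped monotonically onto an integer severity score in [0, 18]
  (AOSI-like); score ≥ 7 defines a case.

For each cutoff φ in a 61-point grid (mean ± 3 SD, step 0.1 SD) the
observed exposure is dichotomized (W₁c = 1 iff W₁ ≥ φ) and

    logit P(case) = c₀ + c₁ W₁c + c₂ W₂c + c₃ Z + c₄ W_gac

is fitted by maximum likelihood (W₂c = 1[W₂ ≥ 1], W_gac = 1[W_ga ≥ 37]);
OR₁ = exp(c₁) plotted against φ is the **OR curve**. A five-category
coding (four cutoffs symmetric about the mean, reference width δ swept
from 0.5 to 1.5 SD) yields category ORs against the central reference.
Misclassification diagnostics take truth to be X₁ dichotomized at the
same cutoff:

    sensitivity = #(W₁ ≥ φ and X₁ ≥ φ) / #(X₁ ≥ φ)
    specificity = #(W₁ < φ and X₁ < φ) / #(X₁ < φ)

computed separately among cases, controls and overall, plus ROC curves
sweeping W₁ as a classifier of each fixed true dichotomy.

Because all predictors are categorical, fits run on covariate-pattern
counts (≤ 2⁴ patterns per outcome class) with frequency weights —
exactly the row-level likelihood, at desk-scale cost even for a million
subjects.

## Worked example

```
$ python analysis/01_simulate_cohort.py
cohort: n=100,000, shape=linear, beta1=0.5, sigma2=0.25
  corr(X1, X2)                       0.7014  (generative 0.7)
  var(W1)                            1.2500  (generative 1.25)
  corr(W1, X1)                       0.8942  (generative 0.8944)
  mean gestational age (weeks)      39.9702  (generative 39.98)
  P(male)                            0.5043  (generative 0.5)
  case prevalence (AOSI >= 7)        0.1717
  observed GA range: [23, 43] weeks, AOSI range: [0, 18]
```

The sample moments recover the generative parameters: the exposure
correlation and error-inflated variance match their targets, and
corr(W₁, X₁) shows the classical-error attenuation factor
1/√(1+σ²) ≈ 0.894. The remaining drivers run the full 36-scenario sweep
and summarize it:

```
python analysis/02_run_study.py                      # tables under results/study/
python analysis/03_summarize_bias.py                 # OR-by-cutoff-by-error table
python analysis/04_differential_misclassification.py # case/control divergence
python analysis/05_figures.py                        # PNG/SVG figures
```

`03` prints, e.g., the strong linear scenario's OR at the mean cutoff
falling 3.456 → 3.308 → 2.919 → 2.255 as σ² rises 0 → 0.0625 → 0.25 → 1
(attenuation), while the same curve is U-shaped in φ (OR 11.8 at −2 SD
vs 3.5 at the mean with no error); for the threshold shape the OR *at
the inflection point* instead rises with error, in all three effect
sizes. `04` confirms that the case/control gap in sensitivity grows with
both the effect size and the error variance.

The same sweeps are available from the command line
(`orcurve simulate | run | plot`), e.g.

```
orcurve run --reduced --seed 11 --outdir results/study
```

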