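# Methods

`lipidmr` implements a two-sample summary-data Mendelian randomization (MR)
analysis contrasting the causal effect of LDL cholesterol on coronary heart
disease (CHD) with its effect on ischemic stroke (IS) and the TOAST
etiologic stroke subtypes. This note records the statistical model, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions.

## Model

For variant *j*, let β̂<sub>Xj</sub> (SE σ<sub>Xj</sub>) be its estimated
per-allele effect on the exposure (LDL-C, in mmol/L after unit scaling) and
β̂<sub>Yj</sub> (SE σ<sub>Yj</sub>) its per-allele log-odds effect on a
binary outcome, taken from non-overlapping studies. Under the instrumental
variable assumptions, β<sub>Yj</sub> = θ·β<sub>Xj</sub> with a single
causal parameter θ (log odds ratio per 1 mmol/L), and horizontal pleiotropy
enters as a per-variant intercept α<sub>j</sub>:
β<sub>Yj</sub> = θ·β<sub>Xj</sub> + α<sub>j</sub>.

### Estimators

With weights w<sub>j</sub> = 1/σ<sub>Yj</sub>²:

- **IVW** — weighted regression through the origin,
  θ̂ = Σw<sub>j</sub>β<sub>Xj</sub>β<sub>Yj</sub> / Σw<sub>j</sub>β<sub>Xj</sub>²,
  SE<sub>fixed</sub> = (Σw<sub>j</sub>β<sub>Xj</sub>²)<sup>−1/2</sup>.
  The default is the *multiplicative random-effects* form: the SE is
  inflated by max(1, √(Q/(J−1))) where Q is Cochran's heterogeneity
  statistic at θ̂. Multiplicative rather than additive because it never
  shrinks the SE below the fixed-effects value and matches the summarized-
  data random-effects construction; the additive form requires a separate
  τ² estimate that is unstable at J ≲ 100.
- **MR-Egger** — the same regression with a free intercept. The slope is
  consistent when pleiotropy is independent of instrument strength (InSIDE);
  the intercept estimates the mean directional pleiotropy per allele.
  Requires the positive-β<sub>X</sub> orientation that harmonization
  produces (the fit is not invariant to per-variant sign flips); the
  operation asserts this rather than silently re-orienting. Overdispersion
  scaling max(1, √(Q/(J−2))) applies to both SEs.
- **Weighted median** — the weighted median of the per-variant Wald ratios
  θ<sub>j</sub> = β<sub>Yj</sub>/β<sub>Xj</sub> with first-order inverse
  ratio variance weights β<sub>Xj</sub>²/σ<sub>Yj</sub>². Mid-cumulative
  weights are linearly interpolated at probability 0.5. The SE comes from a
  parametric bootstrap (default 1000 replicates; β̂<sub>X</sub>, β̂<sub>Y</sub>
  redrawn from normals at their SEs). The bootstrap replicate count and CI
  convention are package choices; the point estimate never depends on the
  seed.
- **Multivariable MR** — weighted regression of β<sub>Y</sub> jointly on
  the LDL-C, HDL-C and triglyceride effect columns with a zero intercept;
  the LDL coefficient is its direct effect adjusting for the other lipid
  fractions. Identically-zero secondary columns are dropped before fitting
  (the fit then reduces exactly to univariable IVW); any remaining rank
  deficiency raises with the design's condition number. Degrees of freedom
  J−k for k fitted columns.

Confidence intervals use θ̂ ± 1.96·SE and two-sided normal p-values
throughout (a Student-t option is not exposed; at J ≥ 60 the difference is
negligible and normal theory matches the reporting convention of consortium
MR analyses).

### Instrument construction

1. genome-wide significance on the exposure: retain p < 5×10⁻⁸ (strict
   inequality);
2. greedy LD clumping: repeatedly index the smallest-p unprocessed variant
   and discard same-chromosome variants within ±1000 kb (center-to-center,
   boundary inclusive) with r² ≥ 0.01. Ties break by smaller p, then
   smaller position, then lexicographic id, which makes the result
   invariant to input row order. Variant pairs absent from the LD matrix
   count as unlinked;
3. lipid specificity: exclude variants whose smallest HDL-C/triglyceride
   p-value (from the table, or a two-sided normal p computed from beta/se)
   is below 5×10⁻⁴. Variants with no secondary statistics are retained with
   a warning rather than dropped — absence of evidence of pleiotropy is the
   weaker error here.

Variance explained in the exposure is Σ<sub>j</sub> 2β<sub>j</sub>²·MAF<sub>j</sub>(1−MAF<sub>j</sub>)
with β in SD units (before mmol/L scaling) and the folded frequency
MAF = min(f, 1−f); folding keeps the formula invariant to allele
orientation. Unit scaling multiplies exposure betas and SEs by a
configurable SD→mmol/L factor, default 1.0 (1 SD of LDL-C ≈ 1 mmol/L);
every causal estimate downstream is then "per 1 mmol/L".

### Harmonization

Outcome and secondary records are aligned to the exposure's effect allele:
identical allele pairs pass through, swapped pairs negate the beta and
complement the frequency, anything else drops the variant with a log entry.
Strand-ambiguous (A/T, C/G) variants are dropped by default because strand
cannot be resolved without frequency heuristics; `palindrome_policy="keep"`
is available for pre-aligned consortium data. Finally every row is oriented
so the exposure beta is non-negative (effects "per LDL-C-increasing
allele"). Harmonizing already-harmonized tables is a no-op, and a missing
effect-allele frequency is tolerated until an operation (variance
explained) actually needs it.

### Pleiotropy diagnostics

Cochran's Q around a causal estimate θ uses the same w<sub>j</sub> weights,
J−1 df, chi-square upper tail; at the IVW point estimate it is *the* Q that
drives the random-effects scale factor (shared computation, asserted equal
in tests).

The residual-sum outlier procedure follows the MR-PRESSO construction:
each variant's expected outcome effect is taken from the leave-one-out
*fixed-effects* IVW fit (fixed effects, because the expected value should
not be inflated by the very heterogeneity being tested); the observed
weighted residual sum of squares is compared against parametric simulations
in which outcome effects are redrawn from Normal(θ̂₍₋ⱼ₎β<sub>Xj</sub>, σ<sub>Yj</sub>)
and the statistic — including the leave-one-out fits — recomputed.
Empirical p-values use (1 + #exceed)/(n_sim + 1), so they are never zero.
Per-variant outliers are flagged at Bonferroni-adjusted 0.05; flagged
variants are removed and IVW/Egger/weighted-median/Q rerun, reported as
before/after pairs. The distortion test is deliberately out of scope. Note
the resolution constraint: flagging requires 1/(n_sim+1) < α/J, so the
pipeline default is n_sim = 2500 (the library-level default of 1000 is
fine for the global test); a warning fires when the floor makes flagging
impossible.

### Between-outcome comparison

Two causal estimates from independent case-control samples are compared
with a two-estimate Cochran Q around their inverse-variance-weighted mean
(df = 1), algebraically the squared z of the difference. CHD and stroke
estimates come from different consortia, so independence is reasonable;
stroke *subtypes* share controls and their mutual comparisons ignore that
covariance — a documented limitation, not an adjustment the summary data
support.

### Power

For a binary outcome with n₁ cases and n₀ controls, the effective sample
size is n_eff = n₁n₀/(n₁+n₀) and the asymptotic SE of the causal log-odds
estimate is 1/√(R²·n_eff), where R² is the instrument's variance explained
in the exposure. Power for a two-sided level-α test of OR = exp(θ₁) is
Φ(λ − z₁₋α/₂) + Φ(−λ − z₁₋α/₂) with λ = |θ₁|/SE; at OR = 1 this reduces to
α exactly. The variance approximation is validated empirically: the closed
form agrees with the rejection rate of fixed-effects IVW over 2000
simulated instruments within 0.01 (tests).

## Synthetic data generator

The generator emulates the *structure* of consortium summary statistics
without individual-level genotypes:

- true per-allele exposure effects γ<sub>j</sub> ~ Uniform(0.02, 0.10)
  mmol/L — a uniform draw on the observed per-allele range reproduces the
  ~5-fold spread seen in lipid instruments better than a normal tail;
- effect-allele frequencies ~ Uniform(0.05, 0.95); sampling noise uses the
  standardized-trait approximation σ = 1/√(2p(1−p)N), with N the exposure
  GWAS size for quantitative traits and n_eff for log-odds outcomes;
- outcome truth Γ<sub>j</sub> = θγ<sub>j</sub> + Σθ<sub>s</sub>γ<sub>sj</sub> + α<sub>j</sub>,
  with pleiotropy α drawn as none / balanced(0, sd) / directional(mean, sd)
  / correlated-with-strength (InSIDE violated at a configurable
  correlation), optional mediation through secondary traits, and optional
  planted outliers shifted by a configured number of outcome-SEs;
- secondary lipid traits with a configurable genetic correlation and an
  optional set of variants planted with unmistakable (10 SE) secondary
  effects, so the specificity filter has a structural 62/37-style split to
  find;
- LD is block-diagonal with a configured within-block r²; blocks sit
  within one clumping window, distinct loci ≥ 10 Mb apart;
- rows are re-oriented to the *observed* exposure-increasing allele, as
  harmonization of real tables would do.

Named scenarios fix all parameters: `null`, `causal`, `balanced`,
`directional`, `inside_violated`, `outliers`, `paper_mimic`,
`paper_mimic_full`. The consortium-scale scenarios use the published study
layouts (exposure GWAS 188,577; CHD 60,801/123,504; IS 12,389/62,004;
subtypes 2,365 / 2,167 / 1,894 cases against the IS controls) and
generating odds ratios 1.49 (CHD), 1.12 (IS), 1.06 (cardioembolic); the
large-artery and small-vessel generating ORs (1.40, 1.35) are package
choices in the plausible between range, since only their study sizes are
externally constrained. In `paper_mimic` the drawn γ are rescaled by a
common factor so the instrument explains exactly 4% of exposure variance
(11% for the 99-variant `paper_mimic_full`); an unscaled 62-variant draw
would explain ~9%.

Two estimator-validation scenarios deliberately use a much larger exposure
GWAS (5×10⁶): MR-Egger's intercept and the multivariable fit are only
consistent as instrument measurement error vanishes (the NOME condition),
and at consortium-scale noise the weak-instrument dilution of the Egger
slope leaks ~7×10⁻⁴ into the intercept — resolvable at Monte-Carlo
precision and therefore fatal to a recovery test of a 0.01 planted mean.
The realistic-noise conditions remain in `paper_mimic`, where recovery is
asserted for IVW (dilution ≈ 0.8% of θ, within Monte-Carlo error at 500
replicates) and CI coverage.

### What the generator does not emulate

Winner's curse (effects are drawn, not selected on significance, so a few
simulated variants fall below genome-wide significance where real deposited
instruments would not), sample overlap between exposure and outcome
studies, shared controls across stroke subtypes, realistic genome-wide LD,
allele-frequency–dependent effect sizes, and population stratification.
Passing recovery tests therefore demonstrates correctness of the estimators
under the stated sampling model, not robustness to these real-data
features.

## Numerical conventions and edge cases

- Monte-Carlo acceptance bands use 3×MCSE (MCSE = SD/√reps); binomial
  bands use the normal approximation at 95%.
- Weighted least squares is solved by normal equations; condition numbers
  above 10¹² raise. Tests cross-check against statsmodels WLS.
- Wald ratios are undefined at β<sub>X</sub> = 0 (error, not NaN);
  bootstrap resamples drop zero-crossing draws of β<sub>X</sub>.
- Empirical p-values cannot be zero by construction; chi-square p at 0 df
  is NaN.
- The pipeline is a pure function of (inputs, config, seeds): weighted-
  median and PRESSO sub-seeds are derived deterministically from the run
  seed, the forest-plot SVG is rendered with a fixed hash salt and no
  date metadata, and reruns are byte-identical (asserted in tests).
- Problem sizes in the validation studies — 500 recovery replicates, 500
  null and 200 planted-outlier diagnostic replicates, 1000/2000-replicate
  calibration checks — were chosen as the smallest sizes at which the
  targeted 3×MCSE / binomial bands are decisive.

## Known limitations

No proxy-variant lookup, liftover or strand inference; multi-allelic
sites are treated as independent allele pairs; no correction for shared
subtype controls; no Steiger filtering, mode-based or robust-regression
estimators; the MR-PRESSO distortion test is omitted by design.
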