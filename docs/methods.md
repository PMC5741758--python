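# Methods

## Study design being modelled

The package implements the analysis of a nested 1:1 matched case-control
study of incident general obesity: each case (BMI ≥ 30 kg/m²) is
individually matched to a normal-weight control of the same sex within
five years of age, drawn from the same cohort. Matching makes the natural
model for general obesity the conditional logistic likelihood, which
eliminates a per-pair nuisance intercept and with it everything shared
within a pair (the matching factors, and any pair-level confounding they
carry). Abdominal phenotypes — waist circumference above 95 cm, or
waist-to-hip ratio above 0.8 in men / 0.9 in women — are analysed
unconditionally because the controls were selected on BMI, not on
abdominal measures, so pairs are not matched with respect to those
outcomes; those models instead adjust directly for age, sex, smoking,
physical activity, education and energy intake.

The WHR cutoffs are implemented exactly as stated for the source analysis
(0.8 for men, 0.9 for women) even though they are transposed relative to
the common convention; both are keys of `OutcomeThresholds`, so users who
want the conventional assignment can flip them.

## Genetic risk score

The weighted GRS multiplies each SNP's risk-allele dose gᵢ ∈ {0,1,2} by its
literature odds ratio and rescales by n/ΣOR so the score spans 0..2n:

GRS = (Σᵢ ORᵢ gᵢ) · n / Σᵢ ORᵢ.

Two consequences are worth noting and are enforced by tests: with equal
weights the GRS is exactly the risk-allele count, and a subject
heterozygous at every SNP scores exactly n regardless of the weights. The
weights are fixed inputs from published meta-analyses (bundled in
`data/fto_panel.yaml`, Σ = 8.18); they are never re-estimated from the
analysed sample, so the GRS is an externally-weighted score, not a fitted
one. Subjects missing any panel genotype cannot be scored and are excluded
from GRS analyses (with their matched partner in conditional analyses).
The GRS is dichotomized at the sample median by default, ties to the high
group ("GRS ≥ median"); the threshold is configurable.

## Hardy-Weinberg QC

`hwe_test` is the Pearson goodness-of-fit chi-square on 1 df without
continuity correction: allele frequency p estimated from the genotype
counts, expected counts (np², 2npq, nq²). A Levene-Haldane exact test
(summing probabilities of heterozygote counts no more probable than the
observed one, conditional on the allele counts) is available via
`exact=True` but is not the default, since the chi-square is the canonical
QC statistic for samples of this size. The test is undefined for
monomorphic SNPs and raises rather than returning p = 1.

On the bundled published genotype table, note that several case-group rows
(and one control row) depart from HWE at the 5% level with heterozygote
excess. Departure in cases is not by itself a genotyping red flag: cases
are ascertained on phenotype, and a locus associated with the phenotype
need not be in HWE within cases. The QC report therefore presents
per-group p-values and leaves the judgement to the analyst.

## Exposures

Fiber is expressed as a density, g per 4186 kJ (1000 kcal), which removes
the mechanical correlation between absolute intake and body size/energy.
Quartiles are formed from the empirical 25/50/75 percentiles of the
analysed sample by default; fixed cutoffs (e.g. the published
7.06 / 9.13 / 11.26 g/4186 kJ) may be supplied instead, in which case
boundaries follow the printed 2-decimal convention: values are rounded to
two decimals first, Q2 and Q3 are closed intervals, and a value in a
printed gap goes to the nearer interval. The cutoff population default
(whole analysed sample rather than controls only) matches standard nested
case-control practice. The alternative high/low fiber stratification uses
ABSOLUTE intake at 14 g/day — deliberately a different scale from the
density quartiles, mirroring how the two stratifications were defined in
the source analysis.

The energy-misreport filter removes subjects whose reported/predicted
energy ratio lies outside mean ± 3 SD (sample SD, ddof = 1), together with
their matched partner so the pair structure survives. No published
prediction equation was specified for this design, so the default
predictor is the sex-specific mean reported intake — it preserves the ±3 SD
mechanic without inventing an equation — and any callable can be supplied
in its place. A zero-SD ratio distribution excludes nobody.

## Regression machinery

Both likelihoods are maximised by Newton-Raphson from β = 0 with
step-halving (acceptance requires the log-likelihood not to decrease),
gradient-norm tolerance 1e-8, at most 100 iterations. Both likelihoods are
concave, so the trace is monotone and convergence is typically reached in
4–8 iterations. The covariance matrix is the inverse observed information
at the optimum; Wald CIs are exp(β ± z·SE).

Identifiability is checked before fitting: the unconditional design must
have full column rank; the conditional design must have full rank *after
within-set centring*, which also catches the classical degenerate case of
all pairs concordant on a covariate (its conditional likelihood is flat).
Separation is detected scale-invariantly: a fit aborts with a named
`SeparationError` when any |β_j|·sd(x_j) exceeds 15, i.e. when one
covariate standard deviation moves the log odds by more than 15 — a
magnitude no epidemiological dataset supports. This keeps the
likelihood-ratio statistic invariant to affine rescaling of covariates
(a property under test) while still catching genuinely separated data.

The likelihood-ratio test requires nested column sets from the same model
family on the same observations, clips the statistic at zero, and treats
the vacuous df = 0 comparison as p = 1. The trend test replaces the
quartile factor with each subject's quartile median density as one
continuous covariate and reports its Wald p by default (LR optional) —
which of the two the original analysis used is not stated, and at these
sample sizes they agree to the order of magnitude.

statsmodels appears only in the test-suite, as the independent oracle for
coefficients and standard errors (`ConditionalLogit`, `Logit`, both driven
to tight convergence with their Newton optimiser); the package's own fits
never call it.

## Interaction pipeline

Subjects are cross-classified into fiber × genetic strata. The joint-group
dummy coding (one indicator per non-reference cell: 7 dummies for
quartiles × binary, 3 for binary × binary) is a reparametrisation of the
main-effects-plus-products model, so the saturated fit yields per-cell
odds ratios against a single reference cell (OR ≡ 1 by construction), and
the interaction LR test compares it to the nested main-effects model on
(levels_F − 1)(levels_G − 1) df — 3 for quartiles × binary, 1 for
binary × binary. The interaction p is invariant to which cell is declared
the reference (also under test). The default reference is the highest
fiber stratum crossed with the protective genetic stratum;
`AnalysisConfig(reference_genetic="risk")` reproduces the alternative
convention in which the high-fiber/high-GRS cell anchors the table.

Per-genetic-stratum trend tests are fitted in a single model containing
the genetic main effect plus one trend slope per stratum
(median × stratum indicator), never by splitting the data: in the matched
analyses pairs stay intact and the set-level conditioning keeps absorbing
the matching factors even when a pair straddles strata. The quartile
medians entering the trend scores are computed once from the pooled
exposure distribution — they are a property of the exposure, not of the
stratum. No multiple-testing correction is applied; all p-values are raw.

## Synthetic cohorts

`simulate_population` draws, per subject: six independent genotype doses
Binomial(2, f) at the control risk-allele frequencies (0.38, 0.37, 0.38,
0.34, 0.33, 0.33) — Hardy-Weinberg by construction, no linkage
disequilibrium, matching the reported absence of r² among the six SNPs;
age N(38, 11²) clipped to 18–80; sex 50/50; energy lognormal (median
≈ 9200 kJ/day, log-sd 0.40); education N(11, 4²); smoking 15/10/75% and
activity 40/40/20% categories. Fiber density is lognormal with log-mean
2.19 and log-sd 0.35, chosen so the 25th/75th percentiles land at the
published 7.06 / 11.26 g/4186 kJ cutoffs (median 8.92, against a printed
9.13–9.14 boundary — the closest a two-parameter lognormal gets to the
three printed cutoffs); absolute fiber g/day is then backed out as
density × energy / 4186. Disease status is Bernoulli with

logit P = β₀ + β_G·carrier + β_F·(d − d₀) + β_GF·carrier·(d − d₀)
        + 0.01·(age − 45) − 0.15·I(education > 14),

with carrier the dominant coding of a configurable causal SNP
(rs3751812 by default), d the fiber density centred at d₀ = 9.5, and
β₀ = −1.9 giving a baseline prevalence near 13% so a 6000-person source
population supports 627 cases. Centring d makes β₀ interpretable and
leaves β_GF unchanged (the interaction coefficient is invariant to
centring when both main effects are in the model). Anthropometry is drawn
consistently with the case definition (cases 30 + Gamma BMI, controls
18.5–24.9), with waist and WHR tracking BMI loosely so the abdominal
outcomes are correlated with, but not identical to, case status.

Matching is greedy in randomized case order: each case draws a random
unused control of the same sex within ±5 years. Greedy randomized matching
can strand a few cases that optimal matching would pair, which is why the
default source population is ~10× the pair count; unmatched cases are
dropped and counted. The matched cohort's invariants (one case and one
control per set, same sex, age gap ≤ 5) are asserted on every output.

What the generator does *not* emulate: food-frequency-questionnaire
measurement error, the multi-phase accrual of cases over follow-up
(collapsed to a single cross-section), linkage disequilibrium, and any
secular trends in diet. Passing tests therefore demonstrate that the
estimators and tests are correct and calibrated under the design's own
assumptions — not that those assumptions hold in any particular real
cohort.

## Validation by parameter recovery

`parameter_recovery_suite` runs simulate → match → conditional interaction
fit (carrier, density, carrier × density, plus the matched-analysis
adjustments) over replicates and summarises bias, empirical vs model SE,
95% Wald CI coverage of the true β_GF, and the LR rejection rate. At the
study scale (627 pairs) with 500 replicates the suite shows a null
rejection rate within Monte-Carlo noise of 5%, bias under 0.01 on a true
interaction of ln 1.5 ≈ 0.405, and coverage near 95% — exercised by the
test-suite at 500 replicates per arm and by `scripts/acceptance.py` at
300 per arm (about a minute of runtime; the larger run adds nothing but
narrower Monte-Carlo error).

## Known limitations

- 1:M matched sets (M > 1) are supported by the conditional likelihood
  but the synthetic generator only produces 1:1 pairs.
- No Firth correction or robust variances; sparse cells in the 8-group
  coding can separate, which is reported as an error naming the cell's
  dummy rather than silently returning an enormous OR.
- The published odds-ratio tables of the motivating cohort are not
  recomputable without its raw data; the pipeline reproduces their
  structure and is validated on synthetic data instead.
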