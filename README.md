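# fibergxe

Gene–diet interaction analysis for 1:1 matched case-control studies of
obesity, built around the six-SNP *FTO* panel (rs1121980, rs1421085,
rs9939973, rs8050136, rs17817449, rs3751812). The package is aimed at
nutritional and genetic epidemiologists who want to test whether dietary
fiber modifies the effect of *FTO* risk alleles — singly or combined into a
weighted genetic risk score — on obesity phenotypes, and at methodologists
who want a fully simulatable version of that design to study the behaviour
of the tests.

## What it computes

**Weighted genetic risk score.** Each SNP is coded 0/1/2 risk alleles and
weighted by its published per-SNP odds ratio OR<sub>i</sub>:

    GRS = (OR₁·g₁ + OR₂·g₂ + … + OR₆·g₆) × (n / Σ ORᵢ)

With the bundled panel Σ ORᵢ = 8.18 and n = 6, so the score runs from 0 to
12 and one GRS point corresponds to one average-weight risk allele.
Subjects are stratified at the median GRS (ties to the high group).

**Hardy-Weinberg QC.** Pearson's chi-square on 1 df (no continuity
correction) comparing observed genotype counts with (np², 2npq, nq²) at the
estimated allele frequency; an exact test is available as an option.

**Exposure derivation.** Fiber is analysed as a nutrient density,
g per 4186 kJ (= g/1000 kcal), split into quartiles (empirical, or the
fixed published cutoffs 7.06 / 9.13 / 11.26), with an alternative absolute
high/low split at 14 g/day. Energy misreporters (reported/predicted intake
outside mean ± 3 SD) are excluded together with their matched partners.

**Matched interaction testing.** For general obesity the model is
conditional logistic regression on the matched pairs, maximising

    ℓ(β) = Σ_pairs [ x'_case β − log(exp(x'_case β) + exp(x'_control β)) ]

by Newton–Raphson; abdominal outcomes (waist > 95 cm, high WHR) use
unconditional logistic regression with a wider covariate set. Subjects are
cross-classified into fiber × genetic strata (8 or 4 joint groups with one
reference cell), per-cell odds ratios come with Wald 95% CIs, dose-response
across quartiles is tested by replacing the categories with their median
densities (trend test), and the gene-by-fiber interaction p-value is the
likelihood-ratio test of the joint model against the main-effects model.

**Synthetic cohorts.** A generator draws a source population with genotypes
under Hardy-Weinberg equilibrium at the published control allele
frequencies, lognormal fiber density matching the published quartile
cutoffs, and disease status from a logistic model with configurable
genotype, fiber and interaction effects — then greedily matches each case
to a normal-weight control of the same sex within ±5 years of age. Because
the truth is known, the whole pipeline is validated by parameter recovery.

## Worked example

```python
import numpy as np
from fibergxe import SimulationConfig, simulate_cohort, run_snp_fiber_analysis

config = SimulationConfig(n_pairs=627, beta_interaction=-np.log(1.5), seed=11)
cohort, truth = simulate_cohort(config)
report = run_snp_fiber_analysis(cohort, "rs3751812", outcome="obesity")
print(report.or_table.round(2).filter(like="_OR"))
print(f"interaction: LR = {report.interaction_stat:.2f} on "
      f"{report.interaction_df} df, p = {report.interaction_p:.3g}")
```

prints

```
           F1_OR  F2_OR  F3_OR  F4_OR
GG          0.95   1.24   0.83   1.00
T carrier   7.44   3.41   1.70   0.26
interaction: LR = 75.00 on 3 df, p = 3.62e-16
```

Here a protective gene-by-fiber interaction (true per-density-unit log-OR
−ln 1.5 in T-allele carriers) was simulated in 627 matched pairs. Reading
across the rows: among GG homozygotes the obesity odds ratio is flat across
fiber-density quartiles (F1..F4, reference = highest-fiber non-carriers in
F4), while among T-allele carriers the odds ratio falls monotonically from
7.4 in the lowest quartile to 0.26 in the highest — carriers benefit from
fiber, non-carriers don't — and the 3-df likelihood-ratio interaction test
detects this decisively.

The same analyses are scriptable from a shell:

```
fibergxe simulate --n-pairs 627 --seed 7 --out-dir sim
fibergxe qc       --phenotypes sim/phenotypes.csv --genotypes sim/genotypes.tsv --out qc.tsv
fibergxe grs      --phenotypes sim/phenotypes.csv --genotypes sim/genotypes.tsv --out grs.tsv
fibergxe interact --phenotypes sim/phenotypes.csv --genotypes sim/genotypes.tsv \
                  --genetic grs --outcome obesity --out report.tsv
```

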