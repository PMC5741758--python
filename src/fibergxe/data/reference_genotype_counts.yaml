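# Published genotype counts for the six-SNP FTO panel in a nested
# case-control sample of Tehran Lipid and Glucose Study adults
# (627 obese cases, 627 normal-weight controls; a few genotypes are
# missing per SNP, so totals fall slightly short of 627).
# Counts are keyed by risk-allele dose: hom_risk = 2 risk alleles,
# het = 1, hom_nonrisk = 0. Used by the QC demo and by tests of the
# allele-bookkeeping and Hardy-Weinberg routines.
rs1121980:            # risk allele A
  controls: {hom_risk: 92, het: 279, hom_nonrisk: 238}
  cases:    {hom_risk: 77, het: 320, hom_nonrisk: 216}
rs1421085:            # risk allele C
  controls: {hom_risk: 87, het: 272, hom_nonrisk: 260}
  cases:    {hom_risk: 72, het: 314, hom_nonrisk: 228}
rs9939973:            # risk allele A
  controls: {hom_risk: 93, het: 282, hom_nonrisk: 243}
  cases:    {hom_risk: 76, het: 319, hom_nonrisk: 220}
rs8050136:            # risk allele A
  controls: {hom_risk: 78, het: 261, hom_nonrisk: 281}
  cases:    {hom_risk: 66, het: 303, hom_nonrisk: 246}
rs17817449:           # risk allele G
  controls: {hom_risk: 75, het: 264, hom_nonrisk: 284}
  cases:    {hom_risk: 68, het: 308, hom_nonrisk: 247}
rs3751812:            # risk allele T
  controls: {hom_risk: 78, het: 249, hom_nonrisk: 290}
  cases:    {hom_risk: 61, het: 305, hom_nonrisk: 247}
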