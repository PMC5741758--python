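# Six-SNP FTO obesity panel: risk alleles per the GWAS catalog / PheGenI,
# per-SNP effect sizes (odds ratios on BMI/obesity) from published
# meta-analyses. These weights feed the weighted genetic risk score;
# their sum is 8.18. rs9939609 is deliberately absent (r^2 = 1 with
# rs8050136/rs3751812/rs17817449 in South/East Asian panels).
snps:
  - snp_id: rs1121980
    major_allele: G
    minor_allele: A
    risk_allele: A
    weight: 1.34
  - snp_id: rs1421085
    major_allele: T
    minor_allele: C
    risk_allele: C
    weight: 1.43
  - snp_id: rs9939973
    major_allele: G
    minor_allele: A
    risk_allele: A
    weight: 1.10
  - snp_id: rs8050136
    major_allele: G
    minor_allele: A
    risk_allele: A
    weight: 1.25
  - snp_id: rs17817449
    major_allele: T
    minor_allele: G
    risk_allele: G
    weight: 1.54
  - snp_id: rs3751812
    major_allele: G
    minor_allele: T
    risk_allele: T
    weight: 1.52
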