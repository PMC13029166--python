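# SNP panel for the UP-AMIGOS lipid GRS analysis: 18 annotated variants in
# three lipoprotein-metabolism pathways plus one genotyped CD36 variant that
# failed Hardy-Weinberg screening in the cohort and never enters a score.
#
# counted_allele: the allele the 0/1/2 dosage counts (the published risk
#   allele). The partner allele (allele_a/allele_b pairing) is reconstructed
#   reference metadata: taken from dbSNP where the variant is well known,
#   otherwise a plausible partner; no computation depends on the letter.
# maf_global / maf_mxl / maf_cohort: 1000 Genomes global, 1000 Genomes MXL,
#   and UP-AMIGOS cohort frequencies of the counted allele.
# phenotype_restriction: the ABCA1 pair is in strong D' but negligible r2,
#   so both variants stay on the panel and each serves one phenotype's score.
panel_name: up-amigos-lipid-grs
pathways:
  RCT: reverse cholesterol transport
  CLU: cellular lipid uptake
  LPF: lipoprotein formation
snps:
  - snp_id: rs1532624
    gene: CETP
    chromosome: "16"
    pathway: RCT
    allele_a: C
    allele_b: A
    counted_allele: A
    maf_global: 0.31
    maf_mxl: 0.35
    maf_cohort: 0.39
  - snp_id: rs289714
    gene: CETP
    chromosome: "16"
    pathway: RCT
    allele_a: T
    allele_b: C
    counted_allele: C
    maf_global: 0.29
    maf_mxl: 0.24
    maf_cohort: 0.35
  - snp_id: rs5882
    gene: CETP
    chromosome: "16"
    pathway: RCT
    allele_a: A
    allele_b: G
    counted_allele: G
    maf_global: 0.37
    maf_mxl: 0.44
    maf_cohort: 0.44
  - snp_id: rs4149310
    gene: ABCA1
    chromosome: "9"
    pathway: RCT
    allele_a: G
    allele_b: A
    counted_allele: A
    maf_global: 0.46
    maf_mxl: 0.35
    maf_cohort: 0.38
    phenotype_restriction: TG
  - snp_id: rs9282541
    gene: ABCA1
    chromosome: "9"
    pathway: RCT
    allele_a: C
    allele_b: T
    counted_allele: T
    maf_global: 0.01
    maf_mxl: 0.07
    maf_cohort: 0.10
    phenotype_restriction: HDL
  - snp_id: rs805743
    gene: LOC
    chromosome: "20"
    pathway: RCT
    allele_a: A
    allele_b: C
    counted_allele: C
    maf_global: 0.35
    maf_mxl: 0.33
    maf_cohort: 0.30
  - snp_id: rs10889337
    gene: ANGPTL3
    chromosome: "1"
    pathway: CLU
    allele_a: G
    allele_b: A
    counted_allele: A
    maf_global: 0.41
    maf_mxl: 0.34
    maf_cohort: 0.43
  - snp_id: rs1044250
    gene: ANGPTL4
    chromosome: "19"
    pathway: CLU
    allele_a: C
    allele_b: T
    counted_allele: T
    maf_global: 0.31
    maf_mxl: 0.40
    maf_cohort: 0.40
  - snp_id: rs2278236
    gene: ANGPTL4
    chromosome: "19"
    pathway: CLU
    allele_a: T
    allele_b: C
    counted_allele: C
    maf_global: 0.49
    maf_mxl: 0.49
    maf_cohort: 0.48
  - snp_id: rs7255436
    gene: ANGPTL4
    chromosome: "19"
    pathway: CLU
    allele_a: C
    allele_b: A
    counted_allele: A
    maf_global: 0.49
    maf_mxl: 0.49
    maf_cohort: 0.49
  - snp_id: rs1527483
    gene: CD36
    chromosome: "7"
    pathway: CLU
    allele_a: C
    allele_b: T
    counted_allele: T
    maf_global: 0.10
    maf_mxl: 0.08
    maf_cohort: 0.12
  - snp_id: rs10499859
    gene: CD36
    chromosome: "7"
    pathway: CLU
    allele_a: A
    allele_b: G
    counted_allele: G
    maf_global: 0.35
    maf_mxl: 0.50
    maf_cohort: 0.48
  - snp_id: rs12678919
    gene: LPL
    chromosome: "8"
    pathway: CLU
    allele_a: A
    allele_b: G
    counted_allele: G
    maf_global: 0.05
    maf_mxl: 0.05
    maf_cohort: 0.05
  - snp_id: rs1260326
    gene: GCKR
    chromosome: "2"
    pathway: LPF
    allele_a: C
    allele_b: T
    counted_allele: T
    maf_global: 0.38
    maf_mxl: 0.35
    maf_cohort: 0.31
  - snp_id: rs1800588
    gene: LIPC
    chromosome: "15"
    pathway: LPF
    allele_a: C
    allele_b: T
    counted_allele: T
    maf_global: 0.29
    maf_mxl: 0.49
    maf_cohort: 0.41
  - snp_id: rs2286276
    gene: MLXIPL
    chromosome: "7"
    pathway: LPF
    allele_a: A
    allele_b: G
    counted_allele: G
    maf_global: 0.27
    maf_mxl: 0.35
    maf_cohort: 0.40
    aliases: [rs2886276]
  - snp_id: rs1801282
    gene: PPARG
    chromosome: "3"
    pathway: LPF
    allele_a: C
    allele_b: G
    counted_allele: G
    maf_global: 0.11
    maf_mxl: 0.13
    maf_cohort: 0.12
  - snp_id: rs12639162
    gene: PPARG
    chromosome: "3"
    pathway: LPF
    allele_a: A
    allele_b: G
    counted_allele: G
    maf_global: 0.43
    maf_mxl: 0.49
    maf_cohort: 0.46
  - snp_id: rs3173798
    gene: CD36
    chromosome: "7"
    pathway: CLU
    allele_a: C
    allele_b: T
    counted_allele: T
    maf_global: 0.11
    maf_mxl: 0.10
    maf_cohort: 0.12
    flags: [reported_hwe_fail]
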