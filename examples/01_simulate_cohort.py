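"""Simulate a study-scale cohort and inspect its structure.

Draws 580 individuals at the packaged panel's cohort allele frequencies,
with two LD blocks, two-way admixture, and lipid phenotypes generated from
the additive model the analysis later fits (log-scale TG, raw-scale HDL-C).
"""

import pathgrs as pg

config = pg.default_study_config(n_individuals=580, seed=1)
genotypes, aims, phenotypes = pg.simulate_cohort(config)

print(f"genotypes: {genotypes.codes.shape[0]} individuals x "
      f"{genotypes.codes.shape[1]} SNPs")
print(f"AIMs: {aims.codes.shape[1]} markers; "
      f"mean admixture proportion {aims.admixture.mean():.2f}")
print(phenotypes[["age", "bmi", "tg", "hdl"]].describe().loc[["mean", "std"]].round(1))

# TG is log-normal by construction: its mean exceeds its median
print(f"\nTG mean {phenotypes['tg'].mean():.1f} vs median "
      f"{phenotypes['tg'].median():.1f} mg/dL (right-skewed, as in real lipid data)")
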