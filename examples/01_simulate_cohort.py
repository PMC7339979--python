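"""Simulate a patient-derived-cell (PDC) pharmacogenomic screen.

Generates a cohort with a planted genotype -> drug-class sensitivity rule:
binary mutation profiles over a gene panel, class-structured drug
fingerprints, and a dose-response AUC matrix (lower AUC_DR = more sensitive)
with missing entries.
"""

import numpy as np

import pdcrx

cfg = pdcrx.SimConfig(n_cells=100, n_drugs=24, n_genes=40, n_classes=4, seed=42)
mutations, drugs, sensitivity, rule = pdcrx.generate_pdc_cohort(cfg)

print(f"mutation matrix: {mutations.shape[0]} cells x {mutations.shape[1]} genes, "
      f"mutation frequency {mutations.to_numpy().mean():.3f}")
print(f"drugs: {len(drugs)} in {drugs['drug_class'].nunique()} mechanism classes, "
      f"{len(drugs['fingerprint'].iloc[0])}-bit fingerprints")
print(f"sensitivity matrix: {sensitivity.shape}, "
      f"{np.isnan(sensitivity.to_numpy()).mean():.0%} missing")
print("planted rule (class -> sensitising gene):")
for cls, gene in rule.class_target.items():
    print(f"  {cls} -> {gene}")

# the planted signal: cells mutated in a class's target gene have lower
# AUC_DR (are more sensitive) for that class's drugs, by ~effect_size
drug0 = drugs.index[0]
target = rule.class_target[drugs.loc[drug0, "drug_class"]]
col = sensitivity[drug0]
mut_mask = mutations[target].astype(bool)
gap = col[~mut_mask].mean() - col[mut_mask].mean()
print(f"\n{drug0}: mean AUC_DR gap (wild-type minus {target}-mutant) = {gap:.3f} "
      f"(planted effect size {cfg.effect_size})")
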