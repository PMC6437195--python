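"""Simulate a family cohort: pedigree, phased SNPs, methylation, traits.

Builds 100 nuclear families with two offspring each, drops 200 common SNPs
through them by Mendelian transmission (phased, paternal allele first), and
simulates one CpG with a planted maternal-imprinting effect plus four traits.
"""

import numpy as np

from poekit import simulate as sim

spec = sim.PedigreeSpec(n_families=100, offspring_per_family=2, seed=1)
ped = sim.simulate_pedigree(spec)
geno = sim.simulate_genotypes(ped, n_snps=200, maf_range=(0.1, 0.5), seed=2)

plan = sim.EffectPlan(poe_model="maternal_imprinting", causal_snp=0,
                      poe_effect_size=0.8, seed=3)
cpg = sim.simulate_methylation(ped, geno, plan)
trait_tab = sim.simulate_traits(ped, n_traits=4, seed=4)

counts = ped.pair_counts()
print(f"pedigree: {ped.n} individuals; "
      f"{counts['full_sib']} full-sib, {counts['father_offspring']} "
      f"father-offspring, {counts['mother_offspring']} mother-offspring, "
      f"{counts['couple']} couple pairs")
print(f"genotypes: {geno.n_snps} SNPs, mean MAF "
      f"{geno.variants['maf'].mean():.2f}")
print(f"CpG phenotype: variance {np.var(cpg):.2f} "
      f"(1 = baseline + planted imprinting term)")
print(f"traits: {trait_tab.shape[1]} columns, "
      f"mean |cross-correlation| "
      f"{np.abs(np.triu(trait_tab.corr().to_numpy(), 1)).mean():.3f}")
# The pair counts mirror a family cohort; the CpG carries extra variance from
# the imprinting term at SNP 0, which later examples detect and localise.
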