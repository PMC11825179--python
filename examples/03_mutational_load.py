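"""Derived mutational load per individual: LoF, missense, dnsSNP, synonymous.

Alleles are polarized against an outgroup (ancestral = outgroup allele that
is also the major allele in the focal population); load is the count of
heterozygous plus derived-homozygous genotypes per category.  The
homozygous-load ratio 2*hom/(2*hom + het) measures how much of the load is
exposed in homozygous state.
"""

import purgekit as pk
from purgekit.synthetic_data import PopulationConfig, SimConfig

sim = pk.simulate(SimConfig(seed=3, populations={
    "large": PopulationConfig(n_individuals=8),
    "small": PopulationConfig(n_individuals=8, autozygous_fraction=0.3),
}))

# Grantham distance drives the dnsSNP class (missense with D >= 150)
print(f"Grantham L->I: {pk.grantham('L', 'I'):.0f} (benign), "
      f"C->W: {pk.grantham('C', 'W'):.0f} (dnsSNP)")

polar = pk.polarize(sim.variants, sim.outgroup, sim.panel, "large")
counts = pk.tabulate_load(sim.variants, sim.effects, polar, sim.panel)
print("\nper-population load (mean per individual):")
print(counts.per_population.to_string(index=False))

ratio = pk.hom_load_ratio(counts, "LoF")
print("\nhomozygous LoF load ratio per population:")
print(ratio.groupby("population")["hom_ratio"].mean().to_string())
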