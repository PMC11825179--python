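"""Derived-allele site-frequency spectra for damaging vs neutral classes.

Each site's called alleles are projected onto a fixed subsample size with
the exact hypergeometric expectation (a deterministic alternative to random
subsampling); bins 0 (absent) and 2n' (fixed) are part of the spectrum.
A damaging class depleted of high-frequency bins relative to neutral is the
classic signature of selection against deleterious variants.
"""

import numpy as np

import purgekit as pk
from purgekit.synthetic_data import PopulationConfig, SimConfig

sim = pk.simulate(SimConfig(seed=5, populations={
    "A": PopulationConfig(n_individuals=10),
    "B": PopulationConfig(n_individuals=10),
}))
polar = pk.polarize(sim.variants, sim.outgroup, sim.panel, "A")

res = pk.sfs(polar, sim.effects, sim.panel, "B", subsample_2n=10)
print("population B, subsample 2n' = 10 alleles")
print("bin:      " + "  ".join(f"{k:5d}" for k in range(11)))
for cls, spec in res.spectra.items():
    print(f"{cls:9s} " + "  ".join(f"{p:5.3f}" for p in spec))

fixed = pk.proportion_fixed(res)
print("\nproportion of spectrum mass in the fixed bin:")
for cls, frac in fixed.items():
    print(f"  {cls}: {100 * frac:.2f}%")
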