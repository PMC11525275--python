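"""Estimate fluid-cognition and domain factor scores.

Residualizes the 12-test battery on vocabulary and sex, takes the first
unrotated principal-axis factor as the general fluid-cognition score, and
per-domain first factors for perceptual speed, executive function, memory.
Writes results/factors.csv (phenotypes + score columns).
"""

import numpy as np

from wmhnet import factors, io

pheno = io.read_phenotypes("results/data/phenotypes.csv")
scored = factors.fluid_factor(pheno)
scored.to_csv("results/factors.csv", index=False)

print(f"fluid factor score: r with age        = "
      f"{np.corrcoef(scored.age_years, scored.fluid)[0,1]:+.3f}")
print(f"fluid factor score: r with latent g   = "
      f"{np.corrcoef(scored.fluid, pheno.latent_g)[0,1]:+.3f} (generator truth)")
for d, name in [("ef", "executive function"), ("ps", "perceptual speed"), ("mem", "memory")]:
    r = np.corrcoef(scored.age_years, scored[f"{d}_score"])[0, 1]
    print(f"{name:18s} score: r with age = {r:+.3f}")
dd = scored[["ef_score", "ps_score", "mem_score"]].corr()
print(f"domain score correlations: EF-PS {dd.iloc[0,1]:.3f}, "
      f"EF-M {dd.iloc[0,2]:.3f}, PS-M {dd.iloc[1,2]:.3f}")
print("wrote results/factors.csv")
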