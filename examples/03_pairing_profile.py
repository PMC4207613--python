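"""Zone-based homolog pairing profiles for two simulated genotypes.

The distal gonad is divided into five equal-length zones (position
along the axis proxies meiotic time).  A wild-type-like genotype pairs
progressively to 100%; a pairing-defective genotype plateaus near 25%.
Per-zone fractions are compared across genotypes with two-tailed t
tests, treating the gonad as the replicate unit.
"""

import numpy as np

from meioquant import (
    SimulationConfig,
    compare_profiles,
    pairing_profile,
    simulate_pairing_gonad,
)


def genotype(curve, base_seed):
    records = []
    for g in range(6):
        cfg = SimulationConfig(
            nuclei_per_gonad=300, pairing_curve=curve, seed=base_seed + g
        )
        gonad = simulate_pairing_gonad(cfg)
        for r in gonad.nuclei:
            r.gonad_id = f"g{g}"
        records.extend(gonad.nuclei)
    return pairing_profile(records, n_zones=5)


wild_type = genotype((0.35, 0.75, 0.95, 1.0, 1.0), base_seed=100)
mutant = genotype((0.15, 0.25, 0.25, 0.25, 0.25), base_seed=200)
pvals = compare_profiles(wild_type, mutant)

print("zone  WT %paired (SD)   mutant %paired (SD)   t-test p")
for z in range(5):
    print(
        f"  {z + 1}   {100 * wild_type.mean[z]:5.1f} ({100 * wild_type.sd[z]:4.1f})"
        f"      {100 * mutant.mean[z]:5.1f} ({100 * mutant.sd[z]:4.1f})"
        f"        {pvals[z]:.2e}"
    )
# The wild-type profile climbs to full pairing while the mutant never
# exceeds ~25%; the per-zone p-values quantify where the curves differ.
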