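"""Parameter recovery: both heritability estimators on a known truth.

Simulates 200 000 adoptive families under the liability-threshold model
with h2 = 0.40, c2 = 0 and 2% prevalence, then re-estimates heritability
from the binary affection statuses alone via (a) the tetrachoric
correlation of adoptee x biological-parent pairs and (b) Falconer
regression on parental prevalence among affected vs unaffected adoptees.
"""

import numpy as np

from adoptherit import (
    FalconerInputs,
    SimulationConfig,
    falconer_heritability,
    heritability_from_correlation,
    simulate_families,
    tetrachoric_from_counts,
)

cfg = SimulationConfig(
    n_adoptees=200_000, h2=0.40, c2=0.0, prevalence=0.02, seed=11
)
draws = simulate_families(cfg)

adoptee = np.concatenate([draws.affected["adoptee"]] * 2)
parent = np.concatenate(
    [draws.affected["bio_mother"], draws.affected["bio_father"]]
)
tet = tetrachoric_from_counts(
    int((adoptee & parent).sum()), int((adoptee & ~parent).sum()),
    int((~adoptee & parent).sum()), int((~adoptee & ~parent).sum()),
)
est_tet = heritability_from_correlation(tet.r, relatedness=0.5,
                                        se_r=tet.se_r)
est_fal = falconer_heritability(
    FalconerInputs(
        q_g=float(parent[~adoptee].mean()),
        q_r=float(parent[adoptee].mean()),
        n_g=int((~adoptee).sum()), n_r=int(adoptee.sum()),
    )
)

print(f"true h2              : {cfg.h2:.2f}")
print(f"tetrachoric estimate : {est_tet.h2:.3f} (SE {est_tet.se_h2:.3f})")
print(f"Falconer estimate    : {est_fal.h2:.3f} (SE {est_fal.se_h2:.3f})")
print(
    "\nBoth routes recover the simulated heritability from nothing but"
    "\ndichotomous affection statuses, which is what registry data offer."
)
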