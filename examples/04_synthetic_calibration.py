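"""What the synthetic-cohort generator actually delivers.

The generator promises cohorts whose ordinal covariates hit configured
Spearman correlations with survival. Discretising latent normals and the
survival-time noise both attenuate rank correlations, so each latent loading
is calibrated above its target; this example prints the calibrated loadings
and the correlations realized on a large draw, plus the censoring fraction
and prognosis-group margins at the default study size.
"""

import numpy as np

from isir import SimulationConfig, calibrate_copula, generate_cohort, spearman
from isir.survival import survival_groups

config = SimulationConfig(n=5000, seed=3)
loadings = calibrate_copula(config.target_correlations, config)
cohort = generate_cohort(config)

print(f"{'variable':<8}{'target r_s':>11}{'latent rho':>12}{'realized r_s':>14}")
for name, target in config.target_correlations.items():
    if target == 0:
        continue
    realized = spearman(cohort.column(name), cohort.survival_times).r_s
    print(f"{name:<8}{target:>11.2f}{loadings[name]:>12.3f}{realized:>14.3f}")

small = generate_cohort(SimulationConfig(n=63, seed=3))
groups = survival_groups(small.survival_times, small.events)
print(f"\nat n=63: censored {sum(1 for e in small.events if e == 0)}/63, "
      f"groups le12/mid/ge60 = "
      f"{groups.count('le12')}/{groups.count('mid')}/{groups.count('ge60')}")
print("(latent rho exceeds its target because discretisation into a few")
print(" ordinal levels attenuates rank correlation)")
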