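"""Convergence diagnostics and the ordered-z goodness-of-fit check.

PSRF compares between- and within-chain variance (values near 1 indicate
mixing); Geweke compares early and late segments of each chain; the
ordered-z discrepancy checks mean structure and residual normality by
comparing observed and replicated sorted standardized residuals against
expected normal order statistics.
"""

import numpy as np

from matalloc import (AllocationModel, McmcSettings, ModelSpec,
                      SimulationConfig, generate_colony, hdi)

observations, _ = generate_colony(
    SimulationConfig(seed=21, n_mothers=120, n_years=10))
spec = ModelSpec(response="weaning", age_form="log",
                 include_birthdate_quadratic=True)
model = AllocationModel(observations, spec)
# the individual-effect SD mixes slowly (most mothers contribute one
# season), so give the chains some room
draws = model.fit(McmcSettings(n_chains=3, n_iter=8000, n_burn=4000, seed=2))

print("PSRF per monitored parameter (threshold 1.1):")
print(draws.psrf.round(3).to_string(index=False))
worst = max(draws.geweke_z, key=draws.geweke_z.get)
print(f"\nmax |Geweke z| over chains: {draws.geweke_z[worst]:.2f} "
      f"({worst})")
print("variance-component chains wander slowly, so their Geweke scores")
print("run high at desk-scale lengths; coefficient scores stay near")
print("the null range.")
coef_z = max(v for k, v in draws.geweke_z.items() if k.startswith("beta"))
print(f"max |Geweke z| among coefficients: {coef_z:.2f}")

mass = draws.beta_column("maternal_mass")
interval = hdi(mass, mass=0.90)
print(f"\nparturition-mass coefficient: {mass.mean():.2f} kg per 2 SD "
      f"(90% HDI {interval.lower:.2f}, {interval.upper:.2f})")

gof = model.gof(draws, rng=np.random.default_rng(0))
print(f"ordered-z discrepancy Bayesian p = {gof.p_value:.2f}")
print("p near 0 or 1 would flag misfit; mid-range values are consistent")
print("with the model's normal residual assumption.")
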