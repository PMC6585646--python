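"""IV quantile regression: does the elasticity vary across the expenditure
distribution?

The inverse-quantile search scans candidate elasticities and, at each
quantile, picks the value that makes the instrument irrelevant in a quantile
regression of the partialled outcome.  The generator is a pure location-shift
model, so all quantile elasticities share the same truth (1.4).
"""

import numpy as np

from simulelast import ModelSpec, SimulationConfig, generate_panel, iv_quantile

cfg = SimulationConfig(n_entities=24, n_periods=10, missing_rate=0.0,
                       pi=0.3, sigma_u=0.15, seed=3)
data, _ = generate_panel(cfg)
spec = ModelSpec("log_pharma", endogenous=("log_gdp",), instruments=("log_tourism",))

results = iv_quantile(spec, data, taus=(0.1, 0.25, 0.5, 0.75, 0.9),
                      grid=np.linspace(0.4, 2.4, 41))
print("tau   elasticity   SE")
for r in results:
    print(f"{r.tau:4.2f}   {r.coefficient:8.3f}   {r.std_error:.3f}")
print("\nUnder a location-shift model the estimates scatter around the common "
      "truth 1.4; in real data a declining profile would indicate pharmaceutical "
      "spending behaves more like a luxury at low spending levels.")
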