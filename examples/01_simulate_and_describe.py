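"""Draw a synthetic country-year panel and summarize it.

The generator solves a simultaneous two-equation system in log public
pharmaceutical expenditure and log GDP per capita, with an exogenous
tourist-receipts-style instrument, country/year effects, and ~15% missing
cells (an unbalanced 136 x 12 panel).
"""

from simulelast import SimulationConfig, generate_panel, summarize_panel

data, truth = generate_panel(SimulationConfig(seed=1))
print(data)
print(summarize_panel(data).round(3))
print(f"\ntrue income elasticity beta = {truth.config.beta}")
print(f"true reverse effect    delta = {truth.config.delta}")
print("Columns are in logs; 'n' counts non-missing cells per variable.")
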