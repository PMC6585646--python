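"""The two-step procedure: reverse effect of expenditure on GDP.

Step 1 estimates the elasticity beta by IV; the adjusted series
y* = y - beta_hat * x (expenditure variation not driven by income) then
instruments expenditure in the income equation.  Naive OLS is upward biased
because income raises expenditure; the two-step estimate removes that
feedback.  Cluster-bootstrap SEs propagate the generated-instrument noise.
"""

from simulelast import ModelSpec, SimulationConfig, fe_ols, generate_panel, two_step

data, truth = generate_panel(SimulationConfig(seed=1))
ts = two_step(data, y="log_pharma", x="log_gdp", z="log_tourism",
              n_boot=199, seed=1)

naive = fe_ols(ModelSpec("log_gdp", controls=("log_pharma",)), data)
print(f"step-1 elasticity beta_hat = {ts.step1.params['log_gdp']:.3f}")
print(f"naive OLS reverse effect   = {naive.params['log_pharma']:.3f}  (upward biased)")
print(f"two-step reverse effect    = {ts.step2.params['log_pharma']:.3f}"
      f"   [truth {truth.config.delta}]")
print(f"  analytic SE  = {ts.step2.std_errors['log_pharma']:.4f}")
print(f"  bootstrap SE = {ts.bootstrap_se['delta']:.4f} "
      f"({ts.n_boot} entity-cluster replicates, {ts.n_boot_failed} failed)")
print("\nThe bootstrap SE exceeds the analytic one because the instrument is "
      "constructed from the estimated beta_hat.")
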