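"""Which input variable drives the simulated intake?

Two contribution-to-variance estimators on each packaged scenario: the
simulation-based normalized squared rank correlation, and the exact
log-variance decomposition available because the model is a pure
product/quotient of independent lognormals.
"""

import dustintake as di

for name in di.PACKAGED_SCENARIOS:
    scenario = di.load_scenario(name)
    inputs, output = di.simulate_input_output_draws(scenario, 200_000, seed=3)
    rank = di.contribution_rank_correlation(inputs, output)
    analytic = di.contribution_log_variance(scenario)
    print(f"\n{name}:")
    print(f"  {'variable':<8}{'rank-correlation':>18}{'log-variance':>15}")
    for var in ("conc", "ir", "bw"):
        print(f"  {var:<8}{rank.shares[var]:>17.1f}%{analytic.shares[var]:>14.1f}%")

print(
    "\nReading: concentration carries most of the output variance on every "
    "route, ingestion rate is secondary, and body weight is negligible — "
    "high intakes happen when concentrations are high, not when children "
    "ingest unusually much dust."
)
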