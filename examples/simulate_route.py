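"""Monte Carlo %ADI percentiles for one route, checked against the exact law.

Loads the packaged chlorpyrifos-via-indoor-dust scenario, runs a reduced
version of the protocol (the study scale is 1e6 iterations x 30 replicates),
and prints the percentile table next to the closed-form lognormal
product/quotient quantiles — for a pure-lognormal scenario the two agree up
to Monte Carlo error.
"""

import dustintake as di

scenario = di.load_scenario("chlorpyrifos_dust")
settings = di.SimulationSettings(iterations=200_000, replicates=10, seed=1)
report = di.simulate(scenario, settings)

print(di.render_percentile_table(report, title="Chlorpyrifos via indoor dust (% of ADI)"))
print("\nClosed-form check (exact lognormal product/quotient):")
oracle = scenario.pct_adi_spec()
for p, point in zip(report.percentiles, report.point):
    exact = oracle.quantile(p)
    print(f"  {di.percentile_label(p):<7} simulated {point:9.4f}%   exact {exact:9.4f}%"
          f"   rel.err {abs(point - exact) / exact:7.2%}")
print("\nReading: daily intake stays far below the acceptable daily intake "
      "(ADI) up to P99; only the extreme upper tail approaches a few percent.")
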