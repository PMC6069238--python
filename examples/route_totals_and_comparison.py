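"""Total non-dietary intake (dust + soil) and comparison with dietary intake.

Sums the two route intakes per iteration (one shared body weight per child),
then sets the result against published dietary-intake percentiles for the
same compounds; the dietary/non-dietary ratio at each shared percentile shows
how the route balance shifts in the upper tail.
"""

import dustintake as di

settings = di.SimulationSettings(iterations=200_000, replicates=10, seed=2)

for compound in ("chlorpyrifos", "cypermethrin"):
    routes = [di.load_scenario(f"{compound}_dust"), di.load_scenario(f"{compound}_soil")]
    total = di.simulate_total(routes, settings)
    comparison = di.build_comparison(total, di.load_dietary_table(compound))
    print(f"\n=== {compound} ===")
    print(comparison.render())

print(
    "\nReading: dietary ingestion dominates at every percentile, but the "
    "ratio shrinks sharply at P99.9 — a highly contaminated home can push "
    "non-dietary intake toward the dietary level."
)
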