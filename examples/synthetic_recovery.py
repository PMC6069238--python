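"""Ground-truth validation: generate -> fit -> simulate vs the known answer.

Draws a synthetic study (censored concentration sample, ingestion-rate
sample, noise-free growth chart) from known lognormal truths, refits every
distribution from the synthetic evidence, simulates the fitted scenario, and
compares the %ADI percentiles against the closed-form law of the truths.
"""

import dustintake as di

study = di.SyntheticStudySpec(
    truth_ir=di.LognormalSpec(2.7539, 1.0285, "mg/day"),
    truth_conc=di.LognormalSpec(-1.0631, 1.9517, "ug/g"),
    truth_bw=di.LognormalSpec(2.8578, 0.1396, "kg"),
    n_homes=20_000,      # large sample => fitting error is small
    n_ir=20_000,
    lod=0.025,           # ug/g; censors ~9% of the concentration draws
    seed=4,
)
settings = di.SimulationSettings(iterations=200_000, replicates=5, seed=4)
out = di.end_to_end_recovery(study, settings, adi=0.01)

print(f"censored fraction: observed {out['censored_fraction']:.3f}, "
      f"closed form {out['expected_censored_fraction']:.3f}")
print(f"fitted conc: mu={out['fits']['conc'].mu:+.3f} (truth {study.truth_conc.mu:+.3f}), "
      f"sigma={out['fits']['conc'].sigma:.3f} (truth {study.truth_conc.sigma:.3f})")
print("\npercentile   simulated-vs-truth relative error")
for p, err in zip(settings.percentiles, out["relative_errors"]):
    print(f"  {di.percentile_label(p):<8}   {err:+8.2%}")
print(
    "\nReading: even with large samples, ~9% censoring leaves a visible "
    "half-LOD substitution bias — largest around the median, smaller in the "
    "upper tail that drives risk.  Rerun with lod=1e-6 (no censoring) and "
    "the errors collapse to pure Monte Carlo noise."
)
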