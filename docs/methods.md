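# Methods

## Model and assumptions

The quantity of interest is a young child's (3–6 years) daily intake of a
contaminant through incidental ingestion of house dust or yard soil,

    intake = IR · C · CF / BW    [µg/kg/day],

with IR the matrix ingestion rate (mg/day), C the contaminant concentration
in the matrix (µg/g), CF = 10⁻³ g/mg, and BW body weight (kg). Risk is
expressed as %ADI = 100 · intake / (1000 · ADI), ADI in mg/kg/day.

Assumptions inherited from the modelling tradition this package implements:

* **All inputs are lognormal** (or degenerate point masses). No other
  family is supported; ingestion-rate distributions from activity-based
  simulation models, residential concentration data, and growth-chart body
  weights are all right-skewed and conventionally modelled as lognormal.
* **IR, C and BW are mutually independent.** No correlation structure is
  modelled.
* **No absorption or bioavailability factor** — the intake equation is pure
  mass bookkeeping — and no dermal/inhalation routes.
* Units are fixed package-wide exactly as above. Any other unit must be
  converted before the configuration boundary; this removes silent drift
  across the two factors of 10³ in the arithmetic.

Because the model is a product/quotient of independent lognormals, the
intake itself is lognormal with `µ = µ_IR + µ_C + ln CF − µ_BW` and
`σ² = σ²_IR + σ²_C + σ²_BW`. This closed form (`combine_product_quotient`)
is used throughout as the independent oracle for the simulation engine — a
deliberate dual route: the Monte Carlo path never calls it, and the tests
compare the two.

## Fitting lognormals from published evidence

* **Moments** (`fit_from_moments`): `σ² = ln(1 + (sd/mean)²)`,
  `µ = ln(mean) − σ²/2`; exact inverse of the lognormal's moment formulas,
  so the round trip reproduces mean and SD to machine precision. `sd = 0`
  yields a point mass at the mean.
* **Percentiles** (`fit_from_percentiles`): ordinary least squares of
  `ln(value)` on `Φ⁻¹(p)` — probit regression. Two points solve exactly; on
  an exactly lognormal-consistent table of any size the recovery is exact to
  solver precision (≤ 1e−9). Chosen over iterative quantile matching for
  reproducibility: closed form, no starting values, no convergence policy.
  The normal quantile comes from `scipy.stats.norm.ppf` (|error| ≪ 1e−9),
  which matters because P99.9 results are sensitive to z₀.₉₉₉.
* **Censored samples** (`fit_from_censored`): below-LOD values are replaced
  by LOD/2 (the conventional substitution for left-censored assay data),
  then the substituted sample's mean and SD (ddof = 1) are moment-matched.
  Maximum-likelihood and regression-on-order-statistics censored estimators
  are deliberate non-goals: the aim is to mirror the half-LOD convention,
  not to improve on it. Substitution bias is real and quantifiable — with
  the LOD near the median it deflates both mean and SD relative to the
  uncensored sample (largest effect near the median of the fitted law, less
  in the risk-driving upper tail); the synthetic module's
  `end_to_end_recovery` measures it rather than hiding it.

**Parameterization choice.** Published summary tables often print mean/SD
*and* percentiles that are mutually inconsistent under a single lognormal
(heavily censored, extremely skewed concentration data practically
guarantees it). The packaged scenarios default to **moment matching**, the
only evidence printed completely for every variable row; a
`parameterization="percentiles"` switch fits the printed percentiles instead
so the discrepancy can be explored. `scenario_consistency()` reports the
relative error between a fitted law's quantiles and the printed percentiles
and flags gross (> 100%) disagreement — notably the cypermethrin-in-dust row
— without correcting anything. Body weight prints only percentiles (7-point
growth chart for the combined 3–6-year range), so it is always
percentile-fitted. Distributions are **not truncated** at printed maxima by
default; the un-truncated heavy tail is what drives P99.9.

## Monte Carlo protocol

Study scale is 10⁶ iterations × 30 replicates. Per replicate: draw
(IR, C, BW) triples independently, apply the intake equation, convert to
%ADI, and take empirical percentiles of the default grid
P50/P75/P90/P95/P97.5/P99/P99.9 by the **inverse empirical CDF (lower
nearest-rank)** rule — deterministic, exact over the full replicate vector
(no streaming approximation), and indistinguishable from other quantile
definitions at 10⁶ draws. Replicate streams derive from
`SeedSequence([base_seed, replicate_index])`, so they are independent,
order-insensitive, and bit-reproducible; identical (scenario, settings)
yield byte-identical report CSVs.

The percentile point estimate is the mean of the 30 replicate estimates;
its 95% CI is the t-interval `mean ± t₀.₉₇₅,ₙ₋₁ · SD/√n` across replicates.
(Spreadsheet risk tools print replicate CIs without documenting their
construction; the t-interval is this package's explicit choice and is
recorded in report metadata.) Empirical coverage of the closed-form quantile
is verified at 90–99% over seeded meta-replication, and CI width scales as
1/√replicates.

**Route totals** (`simulate_total`) draw one shared body weight per
iteration (one child, one body weight) and independent (IR, C) per route,
summing intakes before ADI normalization. Whether a published total shared
BW across routes is generally unknowable from a printed table; the shared
default is flagged in metadata and `shared_bw=False` is available. A total
over a single scenario is bit-identical to the single-route simulation.

Requested percentiles finer than 1/iterations trigger a non-fatal
`ResolutionWarning`.

## Sensitivity analysis

Two contribution-to-variance estimators are reported side by side, because
printed "contribution to variance" splits in the literature rarely state
their formula:

* **Rank correlation** (primary; what spreadsheet tools compute): Spearman
  ρᵢ between each input's draws and the output draws (midrank ties),
  normalized as 100·ρᵢ²/Σρⱼ². Constant inputs get share 0 with a degeneracy
  flag.
* **Log-variance** (analytic cross-check): for this model
  ln(intake) = ln IR + ln C − ln BW + const exactly, so shares are
  100·σᵢ²/Σσⱼ² with no simulation.

Both are monotone-dependence measures of the same structure and agree within
a few points on lognormal-product scenarios; both are invariant to monotone
rescaling of the output (intake vs %ADI). On the packaged moment-matched
scenarios concentration dominates (≈ 68–79%), ingestion rate is secondary,
body weight is < 1%.

## Reporting conventions

Rendered %ADI tables print `<0.001%` below the 0.001% display floor, three
decimals below 10%, two decimals at or above 10%; CI bounds follow the same
rule in parentheses. Dietary/non-dietary ratios are computed from unrounded
values and rounded exactly once, at render time, to two decimals. Dietary
percentiles are external constants read from CSV (the packaged tables come
from a published probabilistic assessment of vegetable residues for 2–6 year
olds in Zhejiang Province); the package never recomputes dietary intake.

## Synthetic data

The generator emulates the study's evidence shapes with known ground truth:
lognormal concentration samples left-censored at a stated LOD (true values
retained internally so substitution bias is measurable; censoring fraction
matches Φ((ln LOD − µ)/σ) within binomial error), lognormal ingestion-rate
samples, and noise-free growth-chart percentile tables (published charts are
smoothed; treating them as exact quantiles makes the percentile-fit round
trip exact, which is the property worth testing). It does **not** emulate:
measurement noise on concentrations, spatial or seasonal structure,
between-home correlation, or non-lognormal truth. Passing recovery tests
therefore demonstrate correctness of the fitting/simulation machinery under
the model's own assumptions, not robustness to real-data violations of them.

## Problem sizes and numerical choices

The default test suite runs reduced sizes (10³–10⁵ draws) chosen so each
check's Monte Carlo error is several times smaller than its assertion
tolerance; oracle-agreement and sensitivity checks additionally run at the
full 10⁶-per-replicate scale, and `scripts/acceptance.py` executes the
complete 10⁶ × 30 protocol for all scenarios and totals. Tie-breaks and
degenerate inputs: all-equal samples fit as point masses (an SD below
1e−12 · mean is treated as rounding); a percentile-fit slope below 1e−12 in
magnitude likewise degenerates to a point mass; point masses still consume
their RNG draws so parallel streams stay aligned; an all-point-mass scenario
has an undefined variance decomposition and raises rather than returning
arbitrary shares.

## Known limitations

* Simulated upper-tail percentiles depend strongly on how the lognormals
  were parameterized from summary tables; with mutually inconsistent printed
  moments and percentiles, no single choice reproduces every published
  number, which is exactly why both parameterizations are first-class and
  the consistency diagnostic exists.
* Half-LOD substitution is a convention, not an estimator with good
  properties; heavy censoring biases the fitted law (see above).
* The replicate CI quantifies sampling (Monte Carlo) uncertainty only — not
  the uncertainty in the fitted input distributions; no two-dimensional
  variability/uncertainty separation is attempted.
* Plain Monte Carlo only; no Latin-hypercube or quasi-random sampling.
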