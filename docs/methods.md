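# Methods

This note records the models, parameter choices and limitations behind
`beeflca`, in the order the pipeline uses them.

## Inventory engine

The engine implements the standard matrix formulation of life-cycle
inventory analysis. Processes are mono-functional (exactly one reference
product); multi-output activities are allocated into mono-functional
processes *before* they enter a product system, so the technosphere matrix
is square by construction. Product flows and processes are indexed in
declaration order, which makes matrices and results bit-reproducible across
runs. The solver is a dense LU solve (`numpy.linalg.solve`); at the
desk scale of this package (tens of processes, far below 10³) sparsity
buys nothing, and the contract is the residual bound
`‖A s − f‖ / ‖f‖ < 1e-10`, not the algorithm. A brute-force Neumann-series
oracle (`s = Σ (I − D⁻¹A)ᵏ D⁻¹ f`) is kept in the test suite as an
independent check on random systems.

Sign conventions: emissions (elementary outputs) and resource extractions
(elementary inputs: water, crude oil, gas, coal, land occupation) both
enter the inventory with positive sign, and characterization factors are
defined on that basis. Units are opaque labels validated when a consumer is
linked to a supplier; there is no automatic conversion. Elementary flows
without a factor in any category contribute zero and are logged once.

The four impact categories are fixed (climate change, land use, water use,
fossil energy) but the factor *values* are configuration: the methane and
nitrous-oxide global-warming potentials default to 28 (biogenic CH₄),
29.8 (fossil CH₄) and 265 (N₂O) kg CO₂ eq/kg — conventional 100-year
midpoint values — and live in `GeneratorConfig`, not in code paths.

## Supply-chain model

Feeding stages are built from `FeedTrial` records in two flavours.
Gate-to-gate processes express feed, utilities and emissions per 1000 kg of
live weight gain; the combined BG+FY boundary mixes the two stage flows by
their share of total gain. Chain processes express everything per kg of
live animal leaving the stage and consume the incoming animal mass, so live
weight is conserved along cow/calf → backgrounding → feed yard → carcass →
harvest and a cradle-to-harvest system can be demanded in kg of retail
cuts. Animal-mass links are definitional and carry no uncertainty; feed and
utility inputs carry the input CV, emissions the emission CV.

Indirect nitrous oxide is added to every stage from its ammonia emission as
`NH₃ · (14/17) · EF · (44/28)` with the volatilization factor `EF = 0.01`
(configurable, sanity-bounded to [0, 0.1]), as a distinct elementary flow
so it is never double-counted.

The cull-cow co-product of the cow/calf stage is handled by the bypass:
calves carry 100 % of the cow/calf burden and cull cows enter the carcass
process from a burden-free supply. The package also implements the explicit
allocate-then-recombine wiring (burden split between calves and cull cows
with an arbitrary factor, recombined at the carcass process); the two are
algebraically equivalent for any allocation factor, which the tests verify
to 1e-9 — this is also why the revenue shares chosen for the cow/calf split
cannot influence results. Harvest co-products (retail cuts 0.68, rendering
0.27, hide 0.05 kg per kg carcass) are allocated by revenue shares
(defaults 0.90/0.06/0.04); dressing percentages are 0.50 (cull cows) and
0.63 (finished cattle). Cull-cow supply is pinned at 0.15 kg live weight
per kg finished live weight; because cull cows arrive burden-free this
only sets the carcass mass balance.

Scenario boundaries: (1) feed-yard trial as observed; (2) full 92-day
backgrounding trial; (3) backgrounding truncated to the feed-yard start
weight — truncation interpolates linearly in cumulative live weight, so the
day count is derived (`round(days · gain fraction)`), not fixed;
(4) truncated BG + full FY, gate-to-gate and cradle-to-harvest;
(5) both stages re-simulated with identical start/end weights per treatment
(380 → 662 kg at the feed yard), removing the feed-conversion ×
weight-gain interaction and shrinking the conversion benefit to ~1.5 %
(larger animals convert feed less efficiently); (6) feed yard re-simulated
from the full backgrounding end weight with the trial live weight gain
maintained and feed scaled up 8 % for the larger animals' maintenance.
Scenario 4 is additionally evaluated cradle-to-feed-yard-gate (per 1000 kg
finished live weight, no harvesting), matching the extra boundary row of
the decision table. Calves moving directly from cow/calf to the feed yard
are not modelled.

## Surrogate intake model and calibration

The surrogate farm model is an energy-balance fill model, deliberately
*not* a re-implementation of any whole-farm simulator: each head demands a
fixed NEm-equivalent energy per day; non-silage ingredients are consumed at
`min(inclusion limit, remaining demand / NEm)` in declaration order; the
single silage ingredient fills the remainder, making its dry-matter intake
strictly inversely proportional to its NEm. Per-ingredient digestibility
multipliers on effective NEm are exposed as free fine-tuning parameters
without asserting any particular values. Herd weight is
`herd · (start + daily gain · days)`.

Calibration mirrors manual simulator calibration: round-robin bisection on
each non-silage inclusion limit against its observed consumed mass
(bracket widening ×2, at most 8 times; 200-iteration budget), then
bisection on silage NEm against the observed silage mass, then a ±2-head
search on herd size (ties to the smaller herd). Composition fractions are
checked only after the NEm stage, because a mis-specified silage energy
density distorts the denominator of every fraction through no fault of the
limits. Success requires all residuals ≤ 1 %; failure raises with the
residual table attached.

## Uncertainty and the decision rule

Dispersion follows the 5 % (inputs) / 10 % (emissions) CV convention. The
default distribution is lognormal with matching mean and CV (impact
quantities are positive and multiplicative); a zero-truncated normal is
available as a configuration switch. Draws preserve the sign of the
nominal amount and are mean-one multipliers, so the sample mean converges
to the nominal value.

The paired Monte-Carlo engine gives one common draw per iteration to every
exchange of processes present in both systems (matched by process id) and
independent draws to treatment-specific exchanges. This encodes the
paired construction in which the conventional system enters with a positive
and the treated system with a negative reference flow: background
uncertainty is common mode and cancels from Δ. A flag switches to fully
independent draws for sensitivity analysis. Iterations whose perturbed
matrix fails to solve are recorded and dropped; the run aborts if more than
1 % fail.

The decision rule resamples m = 30 of the n = 250 differences with
replacement, computes the one-sided one-sample t-test of `mean(Δ) > 0`
(zero-variance samples: p = 0 if the common value is positive, else 1),
repeats 300 times and takes the *nearest-rank* 99th percentile of the
p-value distribution; the null is rejected iff that percentile is below
0.01. The t-test is a one-sample test on the paired differences — the
bootstrap sample's own pairing, with no pooled-variance variant. All
randomness flows from a root seed through named substreams, so results are
bit-reproducible.

## Synthetic generator

The generator's defaults are the study conditions: 60 head per treatment,
weights 244.5 → 380 kg (92-day backgrounding), 293 → 570/590 kg feed yard,
a 5 % feed-yard and 3.5 % backgrounding feed-conversion improvement, the
live-weight interaction on (treated cattle finish 20 kg heavier), and the
paired-weight variant at 380 → 662 kg with a 1.5 % improvement. The
backgrounding end weight of 380 kg lets one bundle exercise both the
truncation (to the 293 kg feed-yard start) and the heavier-feeder
scenarios. The contrast is exact by construction: the treated trial's
gain-to-feed ratio is `1/(1 − improvement)` times the conventional one, and
emissions scale with intake, so gate-to-gate percent decreases equal the
imposed improvement (plus a small contribution from per-head-day utilities
when the interaction raises gain). Conventional feed-conversion ratios are
5.8 (BG) and 6.1 (FY) kg DM per kg gain.

Emission surrogates (kg per kg dry-matter intake: enteric CH₄ 0.016 BG /
0.007 FY, manure CH₄ ≈ 0.0025, manure N₂O ≈ 0.0003, NH₃ 0.010–0.012) and
the upstream intensities of the ~13-process background database are
plausibility constants chosen to give a realistic *structure* — enteric
methane the largest single climate contributor at the animal stages, crop
production dominating land and water, the cow/calf stage dominating the
cradle-to-harvest footprint — and are not asserted as values of any
external database or simulator. Consequently absolute category totals are
not comparable to published beef-LCA figures; only within-run ratios
(percent decreases, contribution shares, significance patterns) are
meaningful, and that is what the tests assert. The generator is fully
deterministic for a given configuration; trials are written with fixed
precision so files are byte-identical across platforms.

What passing tests show, and do not show: the pipeline recovers an imposed
treatment effect of the study's magnitude under the study's dispersion
conventions, the null configuration produces no false rejections, and the
dilution of gate-to-gate benefits in the full supply chain emerges as
expected. They do not validate the surrogate emission constants against
real herds, nor reproduce any published absolute impact value.

## Numerical choices

- Solve residual bound 1e-10; bypass-equivalence tolerance 1e-9;
  contribution-conservation tolerance 1e-9 (all relative).
- Truncation day counts round half to even (Python `round`), with a floor
  of one day; cumulative feed is kept exact by rescaling daily intake.
- Bisection terminates on a 1e-12 relative interval; nearest-rank
  percentile uses `ceil(q·n)` ranks.
- Matrix perturbation is batched over iterations (`numpy` batched solve);
  250 iterations of a scenario system take ~20 ms, which is why the
  200-replication null-calibration study runs in seconds.

## Limitations

- No crop-growth, weather, manure-storage or grazing simulation; the
  surrogate intake model's behavioural contract (fill order, inverse NEm
  response) is the only claim made for it.
- No pesticide inventory detail, no regionalized factors, no endpoint
  modelling, no post-harvest stages, no economic modelling beyond
  allocation shares.
- The decision rule's power depends on how concentrated each category's
  burden is in few uncertain exchanges; with the synthetic inventory the
  weakest category (land, driven largely by the corn-grain input) still
  rejects at the default effect size, but a substantially more concentrated
  inventory would not.
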