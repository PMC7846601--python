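# Methods

This note documents the models implemented in `peatcarbon`, the defaults
that matter, and what the synthetic-data tests do and do not demonstrate.

## Conventions

Depths are cm below the peat surface, half-open increments
`[top, bottom)`; cores are sampled at 1-cm resolution. Calendar ages are
cal yr BP with BP = 1950 CE (`BP = 1950 − CE`); ages after 1950 are
negative, so a 2017 coring surface is −67 cal yr BP. Ring widths are mm;
Tucson files store 0.01-mm integers and both the `999` and `-9999`
terminator dialects are accepted (values are interpreted as 0.01 mm in
either case).

## Radiocarbon calibration

A lab age `t ± s` is mapped to the calendar grid θ (default step 1 yr over
the curve's span) by

    p(θ) ∝ exp(−(t − μ(θ))² / 2(s² + σ_c(θ)²)) / sqrt(s² + σ_c(θ)²)

with μ, σ_c linearly interpolated from the curve. Posteriors are
normalised by log-sum-exp (so near-exact dates collapse to a grid point
instead of underflowing), trimmed where relative mass < 1e-12, and kept in
full — multimodal posteriors are not reduced. Summaries are the weighted
50th percentile (computed with a midpoint cumulative, so symmetric
posteriors have exactly central medians) and the central 2.5–97.5 %
quantile interval. A central interval, not an HPD region, was chosen
because it is deterministic, order-preserving and sufficient for
median-based reporting; the "±" on a basal age can therefore be quoted
either as the posterior sd or as half the 95 % interval, and exporters
label which. No reservoir or offset corrections are applied (terrestrial
plant macrofossils are assumed). Calibration refuses curves whose ¹⁴C
range does not span `t ± 10s`.

## ²¹⁰Pb constant-rate-of-supply dating

Supported activity is the mean (± standard error) of the deepest `tail_n`
(default 4) total activities — a deep-tail estimate chosen because no
²²⁶Ra assay is assumed. Unsupported activities (clipped at zero) are
converted to inventories with `a · ρ · h · 10` (Bq kg⁻¹ × g cm⁻³ × cm →
Bq m⁻²) and cumulated from the bottom; ages at increment boundaries are
`λ⁻¹ ln(A(0)/A(z))` with λ = ln 2 / 22.3 yr⁻¹, mid-increment ages by
linear interpolation of ln A. Boundaries with non-positive remaining
inventory are below the dateable horizon and are dropped with a notice.
Age sigmas propagate the per-sample activity sigmas to first order through
both log-inventories (the supported-level uncertainty is not propagated;
its effect is documented by the sensitivity tests instead). Reported
activities are treated as total ²¹⁰Pb (²¹⁰Po equilibrium assumed).

## Age–depth modelling

The chronology is a clam-style Monte-Carlo piecewise-linear interpolator:
per iteration one age is drawn per dated horizon (¹⁴C from its calibrated
posterior, ²¹⁰Pb/surface/event dates from Gaussians) and the whole
iteration is redrawn until ages increase strictly with depth (up to 1000
rounds; persistent failures are discarded, and fewer than 50 % accepted
iterations aborts with an error pointing at reversals). Accepted
iterations are interpolated to the core's boundaries; medians, central
95 % bands, and per-increment deposition times (iteration-wise slopes,
yr cm⁻¹) are summarised across iterations. An autoregressive
accumulation-prior model was deliberately not implemented: the downstream
quantities (deposition times, horizon lookups) only need a monotone
interpolant with honest uncertainty, and the rejection scheme preserves
all dates rather than deleting outliers. Consequences worth knowing:
between widely spaced dates the model is linear, so a real change in
accumulation rate between two dated horizons (e.g. at a stratigraphic
kink) is smoothed across the span — visible in the synthetic tests as a
last-fire age estimated from the bracketing dates rather than the kink
itself.

CRS horizons enter the ensemble thinned to one Gaussian date per 5 cm
(default) down to 20 cm: adjacent centimetre-scale ²¹⁰Pb ages are nearly
coeval, and feeding all of them to a strict-monotonicity sampler would
reject almost every iteration while adding no chronological information.
`n_iter` defaults to 2000 with a mandatory seed in the configuration;
tests and the acceptance script use 300–1000 iterations, which keeps
ensemble medians stable to well under a year on these cores.

## Charcoal fire layers

A fire layer is a maximal run of increments with charcoal count ≥
threshold (default 1 fragment cm⁻³ — presence — since distinct
charcoal-rich horizons are treated as events without a canonical numeric
cutoff); runs separated by less than `min_gap` (default 2 cm) merge. The
post-fire boundary is the **top** of the shallowest layer, so post-fire
stocks integrate `[0, last_fire_depth)`; the alternative (layer midpoint)
would shift recent stocks by at most one increment's mass. The last-fire
age is the ensemble median at that boundary.

## Peat carbon accounting

Per increment: `om = ρ · LOI`, `c = f_C · om` with `f_C = 0.50` by
default (configurable); `CAR = 10⁴ · c / deposition-time`; cumulative
stock `10 · Σ c·h` (kg C m⁻²). CAR quantiles are the (monotone)
reciprocal transform of the deposition-time quantiles, so the identity
`Σ CAR·dep·h = 10³ · stock` holds exactly (asserted at 1e-9 relative).
LORCA divides the total C mass by the basal median age in cal yr BP
itself — not by basal age + 67 — because that is the definition whose
arithmetic is internally consistent with the published per-site values
this package uses as worked examples. RERCA denominators are calendar
years before coring (117 and 67 yr for the 1900/1950 horizons of a 2017
coring); the horizon depth is the ensemble-median depth at the target
age, partial increments are interpolated linearly, and the quoted sigma
is the 95 % depth interval mapped through the mass profile divided by
3.92. RERCA and LORCA are never compared programmatically: surface peat
has undergone far less decomposition than older peat. No decomposition
modelling or decay-corrected net uptake is attempted.

## Tree biomass

AGB per tree is `Σ β₁·DBH^β₂` over components. The shipped default
coefficient set (stem wood 0.0477·D^2.5094, bark 0.0153·D^2.2122,
branches 0.0291·D^2.0751, foliage 0.1648·D^1.4143) is a black-spruce-like
placeholder: it produces realistic magnitudes for testing, but scientific
use requires supplying a published, cited set through the configuration.
Root (BGB) equations default to three alternatives (root:shoot 0.222,
root:shoot 0.30, and 0.0239·D^2.23); their mean is the central value and
min/max the range — which of several published root equations should
anchor the centre is genuinely open, so the mean/min/max convention is the
package's own and is labelled in reports. Tree carbon is 0.50 × biomass.

DBH trajectories are `2 × cumulative mean-of-radii width`, rescaled
multiplicatively so the final year equals the measured DBH; the rescaling
absorbs bark and missed-pith bias. Whether field radii should be averaged
before or after biomass conversion is unspecified in practice; the I/O
layer can combine radii by id prefix (averaging widths per year) and the
biomass layer then sees one series per tree — converting radii separately
and averaging biomass afterwards would differ only through the (convex)
allometry, by far less than the allometric uncertainty itself. Years with
a locally absent ring are zero increments (flat years). Census trees under
1 cm DBH are rejected with a notice. Shrub and deadwood biomass are out of
scope.

## Comparison

Ratios are `peat / tree C` on totals and on the post-fire window, with the
same tree stock in both (the even-aged stand postdates the last fire).
`agb_multiplier` answers "how many times larger would aboveground tree
carbon need to be to match the whole peat store". Report text rounds half
away from zero to one decimal; CSVs keep raw values.

## Synthetic generator

Scenarios stack constant-rate segments (thickness, deposition time, OM
density, LOI fraction); compaction is not simulated as a process — the
segments state the final observed densities, which is all any pipeline
stage consumes. Fires deposit a charcoal spike in the increment containing
their calendar age; ²¹⁰Pb follows a constant flux (150 Bq m⁻² yr⁻¹)
decayed by true age over a supported level (15 Bq kg⁻¹), measured to 30 cm
by default so the tail of the profile is effectively supported; ¹⁴C lab
ages are true ages mapped through the supplied curve. Noise defaults:
¹⁴C reported sigmas drawn uniformly from 40–70 yr, ²¹⁰Pb 5 % CV, ring
widths 10 % CV; all scatter *and the reported sigmas* scale with
`noise_scale`, so a zero-noise site is exactly invertible and the
ensemble collapses to the deterministic model (reported sigmas are floored
at 1e-9 to satisfy the positivity invariants).

The `cas0/cas50/cas100` presets share a ~20-cm light acrotelm (OM
≈ 0.075–0.08 g cm⁻³ at 3 yr cm⁻¹ — CAR above 100 g C m⁻² yr⁻¹), a denser
transition to the last fire at ~26 cm (~175 cal yr BP), and deep woody
peat (OM 0.15–0.17 g cm⁻³ at 70–180 yr cm⁻¹ — CAR under
5 g C m⁻² yr⁻¹), reaching basal ages of 1255, 7667 and 7522 cal yr BP at
38, 69 and 95 cm. Tree cohorts are even-aged (1839/1838 establishment,
sech²-shaped ring increments), 20 ring-sampled trees with plot censuses
of 35/37/64 stems and mean DBH 10.0/9.1/5.6 cm. These presets emulate the
*structure* of real cores — monotone deposition, density banding,
charcoal spikes, flux-consistent ²¹⁰Pb — but not humification gradients,
hiatuses, bioturbation/charcoal taphonomy, rootlet intrusion of old peat,
or curve plateaus (the default synthetic curve is near-identity).
Recovery tests therefore demonstrate the correctness of the estimators
under their own assumptions, not robustness to violations of them.

## Numerical choices and degenerate inputs

Calibration grid step 1 yr (halving it moves medians by less than the
step); sigmas below 1e-8 are treated as exact point dates; curves in
descending order are sorted with a notice, non-monotone curves rejected;
zero deposition times flag the affected increments and leave CAR
undefined there rather than failing; an empty fire record makes the
post-fire stock equal the total with a warning; a census that is empty
after the DBH filter yields zero stocks with a warning; zero tree carbon
makes ratios NaN with a flag. Problem sizes in the shipped tests and the
acceptance script (300–1000 Monte-Carlo iterations, five seeds per
recovery average) are the package's default desk scale; all results
quoted in the README were produced at those sizes.

## Known limitations

* The age–depth model is piecewise linear between dated horizons; it will
  not reproduce an accumulation-prior (Bacon-style) posterior, and its
  deposition times are constant between dates.
* LORCA/RERCA are *apparent* rates; no decomposition correction is made.
* The default allometry is a documented placeholder; stand stocks are only
  as good as the coefficient provenance.
* Supported ²¹⁰Pb from a deep-tail mean is biased high if the profile is
  truncated before the unsupported component has decayed away; the
  generator's 30-cm default avoids this, real profiles may not.
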