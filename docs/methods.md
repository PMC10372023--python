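# Methods

## The FTGR indicator

Subcutaneous tumor volumes are taken as the ellipsoid approximation
`V = 0.5·w²·l` from caliper width (short axis) and length. Records with
`width > length` are treated as transposed columns and swapped with a
warning rather than rejected; the two readings are the same pair of jaws.

All headline statistics run on the **group-mean** volume series (the mean
over animals still being measured on that day, with the per-day n reported
so composition changes are visible), not on a mean of per-animal
statistics. A per-animal FTGR is available as a diagnostic via
`animal_series`. Dead or censored animals simply stop contributing from
their last measurement onward — the standard field practice.

FTGR at an interior grid day `t_n` with step `h` is the forward minus the
backward percent growth:

```
FTGR = 100·(V(t_n+h) − V(t_n))/V(t_n) − 100·(V(t_n) − V(t_n−h))/V(t_n−h)
```

Properties that the tests pin down: scale invariance (units of V cancel);
identically zero on exact exponentials (constant fold-change) and constant
series; and exact agreement with a per-triplet brute-force evaluation.

**Label conventions.** A triplet value needs data through `t_n + h`. The
package supports two labellings and computes both when comparing against
external plots:

* `latest` (default) — the value sits at `t_n + h`, the last day it needs.
  This is the causal convention: a decision taken at its label day uses no
  future data, so it is the only convention the trigger engine accepts.
* `middle` — the value sits at `t_n`; element-wise identical to `latest`
  shifted one step, and natural for retrospective figures.

**Grid gaps** are a hard error by default. Optional repair interpolates
per-animal in log-volume (growth is multiplicative, so the geometric
midpoint is the right notion of "halfway"). Repair is never silent because
an interpolated point can fabricate or erase a trigger crossing.

## Trigger rule and regimen engine

The boost rule is strict: the engine fires on the first measurement day
whose (causal) FTGR value is **strictly greater** than the threshold
(default 0); an exact 0 waits. The boost is executed the same measurement
day the crossing is observed — no lookahead, no lag parameter. `max_boosts`
(default unlimited: the engine stops adaptively when the trace stays at or
below threshold) and a refractory `min_gap_days` bound the schedule; a
crossing inside the refractory window is suppressed and logged.

TGI at an evaluation day is `[1 − (T_t/T_0)/(C_t/C_0)]·100%` with the 0
subscript at the post-randomization baseline (day 0). It is 0 for equal
fold-changes, approaches 100% as the treated arm vanishes, and is invariant
to per-arm unit changes applied to both time points.

## Synthetic cohorts

The generator's job is to produce data with the statistical structure the
analysis assumes — a decelerating untreated growth law, a transient
treatment-induced suppression deep enough to push FTGR below zero and
transient enough to let it rally — not to model immunology. In log-volume
`u = ln V`:

```
du/dt = a·(ln K − u) − k(t),   k(t) = Σᵢ k₀·exp(−(t − tᵢ − lag)/τ_eff)
```

for irradiation events at days `tᵢ` once their onset lag has passed.
Gompertz (rather than exponential) growth is deliberate: untreated FTGR is
then slightly negative late (deceleration), so a positive crossing is
attributable to the treatment pulse waning, not to the growth law. An
exponential mode exists for closed-form tests.

Defaults (one cohort = 6 animals, enrolled at 60 mm³, measured every
2 days to day 20): `a = 0.1/day`, `K = 3000 mm³` (untreated growth to
~1.8 cm³ by day 20, typical of an aggressive syngeneic graft),
`k₀ = 0.35/day`, `τ_eff = 8 d`, `lag = 3 d`, measurement noise CV 8%.
The treatment parameters were calibrated once, on the noiseless mean
trace, to the qualitative signature the indicator is designed to detect:
FTGR dips below −10% and makes exactly one −→+ sign change inside days
6–12, with the first positive value at day 8. They are this package's own
fixture values, not measurements.

Two structural choices matter downstream:

* **Noise is multiplicative lognormal, applied at measurement** (caliper
  error scales with size), mean-unbiased
  (`exp(σZ − σ²/2)`, `σ² = ln(1+CV²)`), and drawn up-front for every
  animal × day from the seed. Because the draws never depend on the event
  schedule, a zero-magnitude treatment is *bit-identical* to an untreated
  run, and injecting an event mid-trial never perturbs past measurements —
  the causality and null-treatment properties the tests assert.
* **Integration is fixed-step RK4 (0.01 day) on `u`**, which is exact
  enough for this smooth ODE (closed-form agreement ≲ 1e−13 relative) and,
  unlike adaptive steppers, bit-reproducible across platforms.

Caliper width/length are back-solved from the noisy volume with a fixed
aspect ratio (0.8), so `compute_volume` reproduces the generated volume
exactly; the ratio is arbitrary by construction.

**Why the on-time boost wins the day-20 sweep.** In log-space the Gompertz
dynamics are linear, so a kill pulse applied at time `s` survives to the
endpoint `T` attenuated by `e^{−a(T−s)}` (the tumor partially regrows
toward its untreated trajectory). Early boosts are therefore partially
"healed" by the endpoint, while a late boost's pulse is truncated by the
horizon before it has delivered its area. With the defaults the optimum of
`∫ k(s)·e^{−a(T−s)} ds` falls near day 8 — the trigger day — and the sweep
over {trigger−4, trigger, trigger+6} ranks on-time > earlier > later.
That ordering (earlier above later) is what the default decay constants
give; a faster-decaying pulse can swap the two losers without moving the
winner.

## Photothermal efficiency

Lumped single-compartment energy balance for a stirred sample of mass `m`
(g) and specific heat `C` (J/g/K) under incident power `I` (W) with
absorbance `A` at 808 nm:

```
m·C·dT/dt = η·I·(1 − 10⁻ᴬ) + Q_dis − hS·(T − T_surr)
```

* Phases are segmented by maximal runs of the laser flag; each needs ≥ 2
  samples.
* The plateau rise `ΔT_max` is the mean of the last 10% (configurable) of
  the hottest heating segment minus ambient — robust to sensor noise
  without a curve fit. The estimator is accordingly honest only when the
  trace was heated to plateau (≳ 5–8 τ_s); the round-trip tests heat for
  8 τ_s, where the residual bias is < 0.2% absolute in η.
* Cooling is normalized as `θ = (T − T_surr)/(T_max − T_surr)` and `τ_s`
  fitted by least squares of `t` against `−ln θ`, restricted to
  `θ ∈ (0.1, 0.9)` to exclude the logarithmic blow-up near ambient and
  transients near the plateau. r² < 0.99 warns: the decay is not a clean
  single exponential (e.g. convective regime change), and τ_s is suspect.
  The fit keeps a free intercept, making it invariant to time shifts and
  to °C↔K offsets of trace and ambient together.
* `hS = m·C/τ_s` (the returned pair satisfies this identity exactly), and
  `η = (hS·ΔT_max − Q_dis)/(I·(1 − 10⁻ᴬ))`, clipped at 0 with a warning.
  `Q_dis` (solvent/cuvette absorption, laser-driven, hence absent from
  cooling) defaults to 0 with a logged warning in the CLI: without a blank
  trace η is an upper bound.
* `T_surr` defaults to the first trace sample; the incident power is
  density × spot area and the spot area must be supplied — a power density
  alone does not determine it.
* The forward model `T(t) = T_surr + ΔT_eq·(1 − e^{−t/τ_s})`,
  `ΔT_eq = (η·I·(1−10⁻ᴬ) + Q_dis)/hS`, needs `hS` as an input; it lives in
  `SystemConstants.heat_transfer` since it is a property of the setup
  geometry. The thermal-trace generator chains this solution piecewise
  over an on/off schedule and adds Gaussian sensor noise. The default test
  constants (1 g water, 0.65 W, A = 0.5, hS = 0.0181 W/K) put the η ≈ 0.73
  plateau at ≈ 43 °C from 25 °C ambient, matching the characterization
  regime of the nanoparticle suspensions this estimator targets.

## Problem sizes and determinism

All randomness flows from explicit integer seeds (`numpy` `SeedSequence`
spawning separate treated/control streams); identical inputs and seed give
byte-identical cohorts, traces, and trial logs. The shipped test suite and
the acceptance script use small problems — cohorts of 6 animals over
20 days, 1000-series property sweeps, 100-seed noise ensembles, thermal
traces of a few thousand samples — chosen as the smallest sizes at which
the assertions are meaningful; everything runs in seconds.

## Known limitations

* The treatment pulse is phenomenological. It reproduces the dip-then-rally
  FTGR signature and the timing trade-off, but no dose–response links
  °C·min of hyperthermia to kill rate, so absolute TGI values from the
  simulator carry no biological meaning.
* Animals within a cohort share one latent trajectory and differ only by
  measurement noise; real cohorts have growth-rate heterogeneity, which
  widens the FTGR noise band and can shift trigger days by a grid step.
  Passing tests therefore demonstrate correctness of the machinery, not
  field performance of the trigger rule.
* The energy-balance η assumes a spatially uniform sample temperature and a
  single heat-loss pathway; it does not address tissue optics or in vivo
  thermometry.
* FTGR on small cohorts inherits caliper noise amplified by differencing;
  with the default 8% CV and n = 6 the day-to-day standard deviation of
  FTGR is of order 10 percentage points, which is why the refractory gap
  and threshold are exposed as policy parameters rather than hard-coded.
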