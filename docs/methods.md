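# Methods

This note documents the models behind `manostat`, the defaults and why they
were chosen, the numerical decisions, and what the synthetic reactor does
and does not emulate.

## Reactor model

One reactor is a sealed, stirred vessel at constant temperature whose
headspace pressure encodes biogas production. The state variables are the
headspace gas inventory `G` and the dissolved gas pool `D`, both held in mL
of gas at standard conditions (T_N = 293.15 K, P_N = 1.013 bar). Pressure
follows from the ideal-gas law,

    P = G · P_N · T / (V_head · T_N),

so one 0.15 bar hysteresis cycle in a 50 mL headspace at 37 °C holds
50 · (0.15/1.013) · (293.15/310.15) ≈ 7.0 mL STP of biogas. A reactor
producing 63.8 mL/d therefore degasses about 9 times a day; one producing
1.8 mL/d about once every four days.

**Production** is an exogenous profile (constant, piecewise-constant, or
first-order decaying), not a microbial model: the package quantifies gas,
it does not explain it. The constant profile is the validation default;
the observed range in comparable systems (roughly 2–64 mL/d) guides the
rates used in tests and benchmarks.

**Degassing controller.** Strict hysteresis: idle → degassing when
`P ≥ p_high` (default 1.2 bar), degassing → idle when `P ≤ p_low` (default
1.05 bar). The controller is evaluated once per sample on the *true*
pressure rather than the quantized noisy reading. With 0.75 mbar noise the
two differ only in trigger timing by at most a sample or two; acting on the
true state keeps the ground-truth event log deterministic for a seed and
makes the log a clean oracle for pipeline validation.

**Pump-out.** The pump removes gas at a constant volumetric rate at reactor
conditions (default 20 mL/min, which empties a 0.15 bar band in a 50 mL
headspace within one 20-s sample). Within an integration step, removal is
capped so the pressure does not undershoot `p_low`: pump and release
threshold act continuously inside the step, which reproduces the designed
1.2 → 1.05 bar cycle rather than a rate-dependent undershoot.

**Gas–liquid re-equilibration.** After a degassing drop the liquid is
supersaturated relative to the new headspace pressure, and dissolved
CO₂/CH₄ outgasses, producing a small convex bump at the start of each
cycle. This is modelled as a first-order relaxation of `D` toward
`D* = k_H · P` at rate `reequil_rate_per_h` (default 2 h⁻¹). The capacity
`k_H` (`henry_capacity_mL_per_bar`) defaults to **0** — the bump is a
cosmetic, second-order feature of real traces and is deliberately off in
the validation conditions; ≈40 mL/bar is a physically plausible value for
~150 mL of liquid at mesophilic temperature when the bump is wanted.

**Sensor model.** reading = round((P + ε)/q)·q with quantization step
q = 0.0015 bar (the sensor's stated sensitivity) and Gaussian noise
ε with SD 0.75 mbar (half a step) by default. Sensitivity and noise are
distinct parameters on purpose: a sensor's resolution bounds what it can
report, not how much it jitters.

**Integration** is explicit Euler with one step per sensor sample (20 s).
The fastest process in the model (pump-out) is handled by the capped
removal above; everything else changes over hours, so fixed 20-s steps are
far inside the accurate regime and keep simulator state aligned with
logged samples. Gas bookkeeping is by construction: every mL produced is
credited to `G` or `D`, every mL pumped is tallied, so the balance
`produced = ΔG + degassed + ΔD` closes to floating-point round-off
(measured < 10⁻¹² relative) for every configuration.

**Feed/waste pulses** are logged events only (default 24 × 0.5 mL/d each,
i.e. 12 mL/d of wasting, a 15-day hydraulic retention time at 180 mL
working volume). They do not perturb the pressure: matched feed and waste
keep the working volume constant, and no biology is modelled that dilution
could affect. Note the default working volume (150 mL) with 12 mL/d
wasting gives HRT = 12.5 d; the package reports HRT as configured V/Q and
asserts nothing about it.

**Artifacts.** Three kinds can be superimposed on the sensor trace:
transient *spikes* (add a magnitude for n samples, then revert — sensor
glitches), persistent *steps* (baseline shifts, as when liquid sampling
expands the headspace), and *leaks* (a deficit accumulating at a fixed
rate over a window, frozen afterwards). Placement can be explicit or drawn
reproducibly from a seed. The distinction between spikes and steps
matters: a transient spike contributes equal and opposite increments and
therefore cancels out of any cumulated signal on its own, while a step or
leak permanently biases the record unless the spike filter removes its
super-threshold increments.

## Signal pipeline

1. **Degassing removal.** With an event log, its start/end pairs are
   authoritative. Without one, an event is a maximal run of consecutive
   negative steps whose total drop is ≥ 0.05 bar, starting within 0.02 bar
   of (or above) `p_high` and ending within 0.02 bar of (or below)
   `p_low`. On simulator output the two modes agree to within one sample.
   Stitching zeroes the increments inside each event window (samples there
   are flagged and carry the pre-event value — no signal is invented while
   the pump runs) and accumulates the remaining increments, so the final
   cumulated pressure equals the final raw pressure plus the sum of drops,
   exactly. Production during the one or two bridged samples per event is
   absorbed into the measured drop and lost; at 9 events/day this costs
   ≈0.4 % of the rate, the dominant (and conservative) bias at high rates.

2. **Spike rejection.** Any increment of the cumulated curve beyond the
   ±10 mbar allowance is zeroed in one forward pass; the sample is flagged
   and contributes nothing. Two readings of the published ±10 mbar·min⁻¹
   rule are implemented. The default treats it as a **per-measurement**
   allowance (±10 mbar for one sample, scaled proportionally across data
   gaps). The alternative (`per_minute=True`) treats it as a rate, i.e.
   ±3.33 mbar per 20-s sample. The default was chosen on quantitative
   grounds: with 1.5 mbar quantization and 0.75 mbar noise, the trace
   occasionally jumps 3 quanta (±4.5 mbar) and reverts. Under the
   per-minute reading the jump is zeroed but its reversion frequently
   splits into two sub-threshold steps that survive, stranding a permanent
   ±4.5 mbar offset; at 1.8 mL/d this corrupts the recovered rate by
   3–16 % across seeds. The per-measurement reading leaves the quantized
   staircase untouched (errors < 2 % at every benchmark rate, < 0.7 %
   typical) while still removing genuine ±15 mbar excursions. Both
   readings are idempotent by construction.

3. **STP normalisation.** `V(t) = ΔP_cum(t) · V_head/1.013 · 293.15/T`,
   linear in ΔP and headspace and inverse-linear in temperature. The
   reactor temperature is used throughout; no vapor-pressure or
   gas-composition correction is applied (total biogas only).

4. **Rate estimation.** Ordinary least squares of volume on time in days
   (scipy's `linregress`), reporting slope, r², slope SE and n. Weekly
   windows are aligned to the experiment start; weeks with fewer than
   3 samples are omitted with a warning. Weekly slopes are normalized by
   the daily COD load, gCOD/d = OLR × working volume.

## Group statistics

The Kruskal–Wallis H statistic is computed from mid-ranks with the tie
correction `1 − Σ(t³−t)/(N³−N)` and referred to χ²(k−1); when every
observation is identical, H = 0 and p = 1 by convention. Dunn's pairwise
z uses the pooled-rank variance `N(N+1)/12 − Σ(t³−t)/(12(N−1))`, two-sided
normal p-values, and Holm adjustment by default (Bonferroni and no
adjustment are available; the method used is recorded in every output).
The post-hoc table is produced only when the omnibus test is significant
at α = 0.05, unless forced.

Two calibration facts worth knowing. First, the χ² approximation is
slightly conservative at small group sizes (empirical type-I error ≈ 0.044
at n = 10 per group, ≈ 0.049 at n = 25; the Monte-Carlo checks use n = 25).
Second, a 3-groups-of-4-replicates design has a hard power ceiling in
Dunn's test: with fully separated groups the rank means are fixed, an
adjacent pair's z cannot exceed 4/√6.5 ≈ 1.57 (p ≈ 0.12), and only the
extreme pair (z ≈ 3.14) can reach significance. Weekly pairwise
conclusions at four replicates therefore rest on the extreme contrasts.

## Calibration

Pump and sensor calibrations are straight lines fitted by least squares;
pump curves can be constrained through the origin (zero velocity dispenses
zero). The intercept is fitted by default for sensors. A flat response is
reported as slope 0 with r² = 0; inverting a zero-slope curve is an error.
No nonlinear calibration is offered — the devices behave linearly over the
operating range.

## What the synthetic data does and does not emulate

Emulated: the sawtooth trace between the hysteresis thresholds, sensor
quantization and noise, degassing drop shape (complete within 1–2 samples),
post-degassing re-equilibration bumps (when enabled), pulse schedules,
spikes/steps/leaks, and exact ground truth for all of it.

Not emulated: microbial growth and substrate dynamics (production is
prescribed, so tests demonstrate *signal recovery*, not biology), gas
composition (total pressure only), temperature fluctuations, pump wear or
calibration drift, clock jitter or missing samples (gap handling in the
filter is implemented but the simulator always produces uniform logs).
Passing tests therefore show that the pipeline recovers a known gas flux
from a realistic sensor readout; they cannot show that a real community's
biogas curve is linear within a week, which is an assumption of the weekly
OLS summary, not a result.

## Benchmark problem sizes

The benchmark scenario uses four reactors at 1.8, 7.6, 7.8 and 63.8 mL/d
with regression lengths of 24 486, 22 641, 19 182 and 17 862 samples
(4.1–5.7 days at 20-s sampling) — the recorded lengths for this quartet of
rates — and the default sensor model. Precision checks use a 5-day run at
8 mL/d (21 601 samples). Monte-Carlo calibration of the Kruskal–Wallis
test uses 10 000 null draws of three groups of 25. These sizes are the
package's standing validation conditions; all are regenerated from seeds
at run time.

## Known limitations

* Degassing-window bridging loses the production that occurs during
  pump-out (≈0.04 % per event of a day's production), biasing high-rate
  estimates slightly low; a drop-measurement correction was judged not
  worth the added coupling between detection and physics.
* Signature-mode degassing detection assumes drops complete within a few
  samples and reach from near `p_high` to near `p_low`; partial pump-outs
  (overpressure conditions) are flagged by the simulator but not specially
  handled by the detector.
* The spike filter cannot reject a leak slower than the threshold rate;
  sustained sub-threshold leaks must be caught by inspection of the event
  log or the cumulated curve.
* Dunn's test at four replicates can only separate extreme groups (see
  above); this is a property of rank statistics, not an implementation
  limit.
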