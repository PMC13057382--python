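# Methods

This note documents the models, detection rules, numerical choices and
known limitations behind `ventsync`. Units throughout: pressure cmH2O,
flow L/min (inspiratory positive), volume mL, time s unless stated.

## 1. The simulator

### Respiratory mechanics

Each patient is a single-compartment system with airway resistance `R`
(cmH2O·s/L), respiratory-system compliance `C` (mL/cmH2O) and chest-wall
elastance `Ecw` (cmH2O/mL):

    flow = (Paw − PEEP + Pmus − V/C) / R
    Pes  = Pes0 + Ecw·V − Pmus

The volume state is integrated with an exact one-step exponential
integrator (the equation is linear with time constant `R·C`), expressed
as a first-order IIR filter and evaluated with `scipy.signal.lfilter`.
Mechanics are computed on a 4× oversampled internal grid and decimated
to the 50 Hz output rate: the trigger and exhalation-valve transitions
are near-discontinuous, and integrating flow at the output rate alone
would break per-breath volume conservation by a few percent. Sensor
noise (Gaussian, per-channel sd configurable) is added to the recorded
samples only.

Per-profile mechanics ranges (drawn uniformly per patient):

| profile | R (cmH2O·s/L) | C (mL/cmH2O) |
|---|---|---|
| normal | 20–30 | 10–16 |
| obstructive | 40–60 | 10–16 |
| restrictive | 20–30 | 5–8 |
| mixed | 32–48 | 6–10 |

Profiles are sampled with weights 0.44 / 0.28 / 0.16 / 0.12
(mixed / restrictive / obstructive / normal), matching the case mix of a
mixed pediatric ICU cohort. Defaults center on an infant/toddler on PS
8.5 / PEEP 5 cmH2O at ~28 breaths/min with maximal muscle pressure
6–10 cmH2O — the condition the package's validation cohorts emulate.

### Muscle pressure

`Pmus` per neural breath is a smooth burst: a half-cosine activation
ramp (≤ 0.20 s), a plateau, and a brisk half-cosine relaxation
(≤ 0.35 s). Neural inspiratory time `Ti_n` is defined onset →
relaxation midpoint (the landmark the Pes termination rule reads), so
`Ti_n = rise + plateau + fall/2`. Two properties of this shape matter:

* the activation ramp is short and essentially independent of `Ti_n`, so
  the detectability (and detection latency) of effort onset is uniform
  across patients — with a single slow cosine the onset lag grows with
  `Ti_n` and corrupts trigger-timing measurements for long-Ti patients;
* the relaxation is fast, so the post-nadir Pes rise is steep and the
  midpoint-crossing termination estimate is robust to the chest-wall
  recoil term `Ecw·V` riding on Pes.

Per-breath amplitude has log-normal jitter (sd 0.15 in log units), the
breath period log-normal jitter with CV `rate_variability_cv` (0.08).

### The ventilator state machine

Triggering is a latency after neural onset: U(40, 70) ms in the
conventional arm, U(15, 35) ms in the closed-loop emulation. Pressure
rises exponentially to PEEP+PS with time constant `p_ramp_ms/3`; the
exhalation valve releases to PEEP with a 40 ms time constant. A
demand-valve dip (0.3·Pmus, outside machine insufflation) renders effort
against the closed circuit on the Paw trace — this is what the flow-only
ineffective-effort rule (Paw drop ≥ 0.5 cmH2O) and the auto-trigger rule
(absence of a pre-onset dip) read.

Cycling: the conventional arm emulates a *physician-tailored* expiratory
trigger — the realized cycling instant is drawn around the neural
termination (sd 20 ms) rather than computed from a literal
percent-of-peak-flow crossing, whose systematic patient-dependent offset
would contaminate the injected early/late-cycling ground truth. The
closed-loop arm cycles at neural termination + U(10, 40) ms and triggers
with the short latency above; it is synchronous *by construction* — an
idealized oracle emulation of a waveform-driven synchronization
controller, not a reproduction of any proprietary algorithm. Conclusions
about a real controller cannot be drawn from it; it exists to give the
trial-analysis chain a second arm with a known, large effect.

### Asynchrony injection

Per neural breath one anomaly at most is drawn by Bernoulli thinning
(probability = rate/min × nominal period / 60; a sum above 1 raises a
configuration error). Mechanisms and ground-truth metrics:

| type | mechanism | metric logged |
|---|---|---|
| TD | trigger latency drawn in 165–220 ms | latency (ms) |
| EC | cycle forced 200–400 ms before neural termination | termination − cycle (ms) |
| LC | cycle forced 200–400 ms after neural termination | termination − cycle (ms) |
| DB | second machine cycle after a gap of 0.20–0.45·Ti | gap/Ti ratio |
| AT | extra machine cycle in quiet expiration, no effort | — |
| IE | extra weak effort (0.35× amplitude), no machine response | — |
| cough | 0.2 s positive flow (+25 L/min) and Pes (+6) transient | — |

Injected IE efforts and AT cycles are placed strictly after the main
effort's relaxation, so each injected event is a distinct physiologic
event with unambiguous ground truth. TD injection stays inside the
118–234 ms band with margin at both edges because the measured response
time carries ~±15 ms of detection noise.

Default per-minute rates (IE 0.7, AT 0.45, DB 0.3, TD 1.25, EC 1.0,
LC 0.25) put the conventional arm's ground-truth AI median near 13%, and
the closed-loop arm-effect multipliers (AT 0.33, DB 0.125, TD 0.15,
EC 0.07, IE 1.0, LC 1.8) put the closed-loop arm near 5.5% — the
magnitudes and directionality of a physician-tailored versus
closed-loop comparison: large reductions in auto-triggering, double
breaths, trigger delay and early cycling, no change in ineffective
efforts, a modest increase in late cycling.

Gas-exchange channels (EtCO2, SpO2) are breath-independent AR(1) drifts
around configurable means (43/42 mmHg and 96% for the two arms); the
Comfort-B score is drawn per session from a discrete distribution around
a configurable median (14 conventional, 13 closed-loop). These are
*inputs* to the summary statistics, not mechanistically modeled.

Leak is a constant per-session fraction (default 6%) of flow lost on the
expiratory limb; the recorded expiratory flow is scaled by (1 − leak).

Randomness: one root seed; per-patient substreams are spawned from a
`numpy` SeedSequence, so growing a cohort leaves existing patients
bit-identical. Identical inputs and seed give bit-identical sessions.

## 2. Segmentation

**Breath onset.** Candidates come from two sources: upward flow
crossings of 2 L/min, and steep Paw upswings (≥ 75 cmH2O/s — the
pressurization edge; necessary because a double-triggered second cycle
starts with the lung inflated and may never reach the absolute flow
threshold). Every candidate must show a ≥ 1 cmH2O Paw rise within
150 ms. The onset is then refined to the ventilator trigger by
interpolating the 25%-of-rise crossing of the pressurization edge:
patient effort can pull flow through the threshold well before the
machine triggers, and the response-time bins refer to the machine.

**Cycle time.** The ventilator's cycling instant is the steep Paw
*downswing* at valve opening (interpolated 25%-of-fall crossing), with
the interpolated downward zero-crossing of flow as fallback. Under late
cycling, flow decays toward zero long before the valve opens (lung
recoil approaches the support pressure), so a flow-only cycle estimate
is systematically early; the pressure edge is not. Expiratory passivity
is assessed separately by the exponential-decay fit and stored as a flag.

**Passive decay fit.** Least squares of log|flow| against time, samples
below 2 L/min excluded, ≥ 8 usable samples required. Passive iff
r² ≥ 0.95 and the time constant lies in [0.05, 1.5] s (pediatric range).
All three numbers are configuration.

**Efforts (Pes).** The baseline is a centered rolling 70th-percentile
filter (2.5 s window). A rolling *median* fails here: inspiratory effort
can occupy close to half of any window — and more around injected extra
efforts — which drags the median inside the effort envelope and hides
weak efforts. An effort is a contiguous negative deflection with
amplitude ≥ 1 cmH2O. Onset is the interpolated crossing of
`baseline − max(0.05·amplitude, pedestal + 0.2)`, where the pedestal is
the local quiet-expiration deviation (chest-wall recoil keeps Pes
slightly below the upper-quantile baseline, and a fixed 5% threshold
would dive into that pedestal and fire ~100 ms early in high-compliance
patients). Termination is the interpolated midpoint crossing of the
post-nadir rise. Walks are bounded by neighboring effort regions so a
weak effort cannot swallow its neighbor's onset.

**Matching.** Greedy chronological one-to-one: each effort takes the
earliest unmatched breath with onset in
[effort onset − 60 ms, effort onset + 600 ms]. The 60 ms pre-trigger
tolerance absorbs the small negative bias of measured response times
(the effort-onset estimate lags the true neural onset by ~25–40 ms while
the refined breath onset lags the trigger by only ~5 ms); 600 ms is
about one breath period at the fastest pediatric rates. Greedy matching
equals exhaustive maximum matching on all small instances (property
tested) and is order-stable.

## 3. Classification

Precedence, applied in order: (1) DB on consecutive cycle pairs
(Te ≤ Ti/2, attached to the second cycle; the second cycle carries no
trigger-phase label and the first no EC — early cycling relative to a
continuing effort *is* the DB mechanism); (2) per machine breath one
trigger-phase label — TD for matched breaths with response in
(117, 234] ms, AT for unmatched breaths with no pre-onset Paw dip
(≥ 0.3 cmH2O) or Pes dip (≥ 0.8 cmH2O); (3) IE on effort cycles — every
unmatched effort, plus matched efforts with response > 234 ms (never
double-counted with TD); (4) per matched breath one cycling-phase label
from the offset `termination − cycle`: ≥ +100 ms EC, ≤ −100 ms LC (the
negative threshold is the symmetric counterpart of the published
early-cycling bound). Events inside artifact-masked windows are dropped
from the numerator, and breaths overlapping masked windows from the
denominator. Negative response times within the matching tolerance are
clamped to zero (a breath cannot respond before the effort; the clamp
covers measurement jitter on near-simultaneous triggers).

When Pes is absent, flow-only fallbacks apply: IE = expiratory flow
deviation toward zero breaking the passive envelope with a ≥ 0.5 cmH2O
abrupt Paw drop within ±150 ms; EC = the same deviation within 300 ms of
cycling without the Paw drop; LC = a ≥ 1 cmH2O Paw spike just before
cycling. Auto-triggering is not assessed flow-only (the rule requires
knowing which breaths lack efforts). The boundary convention for the
printed integer-ms bins on continuous time is (−∞,117] / (117,234] /
(234,∞).

Artifact masking: cough = a brief (< 0.45 s) positive flow transient
rising ≥ 10 L/min above the local flow baseline, reaching positive flow,
flanked by expiratory flow, with *no* concurrent pressurization edge
(the veto that separates a cough from a short early-cycled machine
breath); active expiration = Pes ≥ 3 cmH2O above its rolling baseline.
Masks are padded ±0.1 s and OR-ed in, so masking is idempotent.

## 4. Outcomes

`AI = Major + Minor` holds bit-exactly because the total is computed as
the sum of the two shared-denominator ratios, not re-divided. The AI
denominator counts machine breaths (auto-triggered cycles included — they
are ventilator cycles) plus ineffective efforts. Mean leak is the mean
of per-breath `100·(Vinsp − Vexp)/Vinsp` clamped to [0, 100], with
inspired volume integrated over the positive-flow span back to the
previous cycle so pre-trigger patient inflow is attributed to the breath
that inhaled it. Channel means use unmasked samples only; a missing
channel yields an absent (None) mean, never zero.

## 5. Statistics

* Routing: parametric iff Shapiro–Wilk p ≥ 0.05 and |skew| ≤ 2 and
  |excess kurtosis| ≤ 7; all four numbers are parameters.
* Wilcoxon: zeros dropped, mid-ranks for ties, exact distribution when
  n ≤ 25 with no ties, else normal approximation with continuity
  correction.
* Hodges–Lehmann: estimate = median of the n(n+1)/2 Walsh averages; CI
  endpoints are Walsh-average order statistics at ranks from the exact
  signed-rank null CDF (dynamic programming) for n ≤ 50, normal
  approximation above. Achieved coverage is ≥ the nominal level
  (discreteness makes it conservative).
* Power: `n_eff = ARE·n`, `df = n_eff − 1` kept continuous (gamma-based
  t and noncentral-t from scipy), `δ = dz·√n_eff`, two-sided power
  `P(T' > t_crit) + P(T' < −t_crit)`. ARE defaults to the normal-parent
  value 3/π ≈ 0.9549 and is exposed. For the reference design
  (dz = 0.86, α = 0.05, n = 21) this gives δ = 3.8512 and power 0.9546;
  a published G*Power run of the same design prints δ = 3.84 and power
  0.9535 — consistent with a pilot dz rounded to 0.86 before printing,
  and left as is rather than patched.
* `required_pairs` scans n upward from 2; power is monotone in n
  (property tested), so the first hit is minimal.
* Crossover analysis is a simple paired comparison per outcome;
  period and sequence effects are not modeled, and no multiple-testing
  correction is applied across outcome rows — matching how such trials
  are conventionally reported. Both simplifications are deliberate.

## 6. Validation scales and what passing shows

The recovery harness simulates 25-patient crossover cohorts with
10-minute measurement periods per arm (a desk-scale stand-in for 60-min
clinical periods; ~280 breaths per session keeps count statistics
meaningful while a 20-seed panel runs in about a minute). On that panel
the detected per-session AI tracks the injection ground truth within
0.8 percentage points worst-case, per-type sensitivity and precision
exceed 0.9, and the paired analysis finds the negative AI difference at
p < 0.05 in every seed.

What this does *not* show: performance on real recordings. The simulator
draws efforts from one parametric family, injects at most one anomaly
per breath, keeps noise Gaussian and stationary, and realizes leak as a
constant fraction; real data have overlapping events, non-stationary
artifacts, secretions, and morphology the model does not produce. The
recovery numbers certify the *pipeline* (given waveforms whose ground
truth is known, the rules recover it), not the clinical sensitivity of
the rule set.

## 7. Degenerate inputs and edge behavior

* Records truncated mid-inspiration drop the unfinished breath.
* A fully masked record yields a zero AI denominator and a domain error.
* Efforts truncated by the record end are discarded.
* Constant samples raise in `assess_normality`; all-zero paired
  differences return a degenerate result (estimate 0, p = 1, flagged).
* Readers reject non-uniform time bases (> 10% step deviation) in
  strict mode and reject files missing time/Paw/flow columns.
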