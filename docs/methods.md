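# Methods

This note records the models behind `dopplercage`, the parameters that
matter, the numerical conventions, and what the synthetic data does and does
not establish.

## Light schedules

A schedule is a binary LIGHT/DARK function of experiment time (seconds from
midnight of day 1), defined by clock hours of light-on and light-off within
a 24 h cycle (default: ON 20:00, OFF 08:00 — the inverted cycle used for
daytime observation of nocturnal animals). Transition instants belong to the
new state (half-open `[on, off)` intervals), so binning is unambiguous.

Phase shifts are `(effective_time, offset_hours)` pairs: every nominal
transition strictly after the effective time moves by the offset. The
`shifted_on_day(day, offset)` helper places the effective time at that day's
dark onset, so a negative offset (advance) shortens that dark phase — the
light returns early, which is how the −6 h advance is administered in the
shift protocol: days 1–3 run dark 08–20 h, day 3's dark phase lasts only
08–14 h, and from day 4 the dark phase is 02–14 h. A shift whose offset
exceeds the surrounding phase length would reorder transitions and is
rejected. Times have 1 s granularity downstream (the logger's RTC); the
schedule itself is continuous.

Out of scope by design: twilight ramps, non-24 h (T-cycle) protocols,
lux-level modeling beyond the binary state plus a two-level analog light
column in the log.

## Synthetic activity

**Event model.** An animal is an inhomogeneous Poisson source. Its rate is
`activity_scale × rate_active` when the clock hour lies in the subjective
dark window `[φ_d, φ_d + dark_length)` (dark_length = the schedule's nominal
dark phase, 12 h by default) and `activity_scale × rate_rest` otherwise.
Events are drawn by thinning against the maximal rate — exact for a
piecewise-constant intensity and independent of bin boundaries.

**Entrainment model.** The internal phase φ_d (clock hour of subjective dark
onset) is updated once per day at midnight:

    φ_{d+1} = φ_d + e · wrap(onset_d − φ_d),   wrap: → (−12, +12] h

where `onset_d` is the schedule's most recent dark-onset hour and
`e ∈ [0, 1]` the entrainment rate. This discrete proportional correction is
deliberately the simplest model with one recoverable parameter; it
reproduces day-resolution re-entrainment without a continuous oscillator
ODE. The wrap convention makes a −6 h advance corrected as an advance, never
as an 18 h delay. With `e = 1` the phase locks to the schedule after a
single update; with `e = 0` it never moves.

**Strain calibration.** The two bundled profiles are calibration choices,
not measured constants (no quantitative entrainment rate exists for either
line; the observations being emulated are qualitative — a quick
re-entrainer versus a non-entrainer with doubled activity):

| parameter        | CD1-like | LAB-like | unit     | why |
|------------------|---------:|---------:|----------|-----|
| rate_active      | 0.5      | 0.5      | events/s | yields ~10⁴ events/day, a realistic detector load |
| rate_rest        | 0.05     | 0.05     | events/s | 10:1 contrast puts >90% of events in the dark phase |
| activity_scale   | 1.0      | 2.0      | —        | the hyperactive line shows ~2× daily activity |
| entrainment_rate | 0.8      | 0.0      | /day     | see below |

With `e = 0.8` the residual phase error after the −6 h advance on day 3 is
1.2 h on day 4, 0.24 h on day 5 and 0.05 h on day 6, so the day-5/6 profile
sits ≈ 5.9 h from baseline and the 1 h-resolution cross-correlation
estimator reads 6 h. A substantially smaller rate (e.g. 0.6) leaves ≈ 0.7 h
mean residual error across days 5–6 and the estimator reads 5 h — i.e. the
recovery analysis itself constrains how fast a "quick re-entrainer" must be
on this 6-day protocol; 0.8 is the chosen calibration and is not revisited
per experiment.

**Clock benchmark.** The bench validation records an analog clock whose
second hand carries a foil flag. The simulator places ticks at multiples of
`tick_interval`, lengthens the k-th interval by
`A·sin(2π·k·Δ/P)` (A = `modulation_amplitude`, a peak *interval* deviation
emulating flag vibration at the hand's rotation period P), jitters each
surviving timestamp with Gaussian noise, and drops ticks independently with
`miss_probability`. The modulation acts on intervals, not timestamps: a
timestamp-domain sinusoid of 10 ms amplitude would induce only ~1 ms of
interval modulation (the finite difference of the sinusoid), invisible under
5 ms jitter, whereas the interval-domain reading makes the 1-min rhythm
detectable exactly as the analysis expects. With all noise at zero the
output is the exact tick grid.

**What the generator does not emulate:** ultradian bout structure,
sleep-stage dynamics, masking by light (activity follows the *internal*
phase only), temperature effects, detector sensitivity drift. Passing tests
therefore show that the analyses recover the parameters of this model family
— not that real recordings satisfy the model.

## Device model

The logging chain is modeled event-wise rather than electrically:

- **Pulse extension** is the union of `[t, t + hold)` over events
  (retriggerable monostable; `hold` default 1 s).
- **Crosstalk** copies each physical event onto every other channel
  independently with the pickup probability in a 6×6 matrix (diagonal 1); a
  foil shield between two cages forces their mutual pickup to 0, matching
  the observed complete elimination.
- **Logging cycle:** the merged event stream is swept in time order. An
  event at least `dead_time` after the previous written record triggers a
  new record whose flags are all channels with an event in
  `(max(t − hold, t_prev_record), t]` — the channels whose stretched pulses
  are still high at the poll, with the lower cut modeling the multivibrator
  reset after each SD write. Simultaneous events (crosstalk copies) land in
  the same record. `dead_time` (default 0.1 s) stands in for the unspecified
  SD-write duration and is a declared, configurable model parameter; at
  0.5 events/s it absorbs few events but biases the measured pickup
  fraction upward by about one percentage point (events absorbed into a
  record's window add pickup opportunities).
- **Timestamps** are floored (not rounded) to whole seconds — RTC read
  semantics — so tests can assert exact values.

The CSV schema is fixed: header `datetime,ch1,ch2,ch3,ch4,ch5,ch6,light`,
`YYYY-MM-DD HH:MM:SS` timestamps, 0/1 flags, integer 10-bit light. A row
flagging no channel is invalid (records exist only after an interrupt) and
is rejected with its line number; non-monotone timestamps warn and are
stably re-sorted. Round-trips are lossless.

## Interval analysis

Summaries use the arithmetic mean and linear-interpolation (type-7)
percentiles — the spreadsheet default, declared because percentile
conventions differ. Histogram bins and the in-range fraction are half-open
`[lo, hi)`, with bin membership computed by integer division so boundary
values land deterministically.

Autocorrelation is computed per lag as the Pearson correlation of the
overlapping pairs `(x_t, x_{t+k})` — not the FFT-based biased estimator —
so small-sample values stay bounded and lag 0 is exactly 1.

**Dominant-period detection** is peak-picking on that autocorrelation over
lags in `(min_lag, max_lag]` (`min_lag` 10 to skip the jitter-induced
short-lag structure; `max_lag` defaults to n/4):

1. The global maximum must clear a white-noise threshold. The per-lag null
   scale is 1/√n, but several hundred lags are examined, so the threshold is
   Bonferroni-corrected to an overall two-sided 1% level; a plain 3/√n band
   is exceeded by pure noise routinely at this many lags.
2. A sinusoidal modulation puts equally high correlation at every multiple
   of its period, so a bare argmax would land on a random harmonic. The
   reported lag is instead the argmax among the earliest cluster of
   near-maximal lags (within 3/√n of the peak, up to 1.5× the first such
   lag) — the fundamental.
3. Below the threshold the result is "no rhythm" (None), not an exception.

The lag is converted to seconds via the mean interval. Recovery is exact to
±1 lag; sampling noise can shift the peak by one lag when the modulation
amplitude is close to the jitter level. Note that detection requires the
modulation variance to be non-negligible against the *total* interval
variance: 2% missed ticks contribute ~2 s gap intervals whose variance
swamps a 10 ms modulation, so in the combined-noise preset the 1-min rhythm
is honestly undetectable and the preset reports None. Long intervals are
never excluded (no outlier rejection by design). Spectral estimators
(periodogram, Lomb–Scargle) are out of scope.

## Actogram analysis

Rows are calendar days starting at midnight, single-plotted (a double-plot
is an output option only). Binning is half-open on a grid whose width must
divide 24 h; counts are conserved. Group SEM is the across-animal sample
standard deviation per bin over √n (not across-day variability — the
documented choice); n = 1 reports SEM 0 with a warning rather than NaN.

The modulation statistic is, per light transition,
`100 × counts[t, t+3 h) / counts[t−3 h, t)`, computed on raw record counts
(the pipeline's activity unit); an empty pre-window yields an undefined
(NaN) entry, never a division error. Only transitions with a full window on
both sides are evaluated. The shift day's transitions can be excluded
downstream by filtering on the transition time.

Phase-shift estimation correlates the mean daily profile of the baseline
days with that of the post days over all 24 circular rotations and returns
the maximizing rotation mapped to (−12, +12] h, ties broken toward the
smallest magnitude. Sign convention: negative = advance (activity earlier).
Flat profiles are rejected (undefined correlation). Resolution equals the
bin width (1 h), which is why the estimator reads an integer 6 even though
the simulated animals' residual error leaves the true displacement at
≈ 5.9 h.

Inferential statistics (ANOVA, post-hoc tests) are out of scope: the module
emits the per-group tables such tests consume.

## Video scoring

"Changed pixel" needs a per-pixel criterion the source material leaves
implicit; `pixel_delta_min` (default 10 gray levels on 8-bit) is that
declared parameter, set above typical sensor noise. A frame pair shows
motion when its changed fraction is strictly greater than
`frame_fraction_threshold` (default 0.085, liberal against a ~0.055 noise
floor). Binning mirrors the detector/observer convention: 2 s any-motion
bins, then 30 s percent-presence bins. Method comparison reports Pearson r
over paired bins and `100 × (mean(a) − mean(b))/mean(b)`.

The synthetic video calibrates its noise floor exactly: each frame
independently raises each pixel by a large offset with probability q, so
consecutive frames differ at a pixel with probability `2q(1 − q)`, and q is
solved from the requested change fraction. Scripted locomotion epochs move a
bright blob one blob-width per frame (disjoint successive positions →
change fraction ≈ 2× its area fraction), giving an oracle-by-construction
for the end-to-end pipeline up to one 2 s bin of quantization. Frame rate is
a free parameter (the source material does not state one); tests use 10 Hz.
Observer (OBS) traces are ingested as already-percent values; no observer
model is simulated.

## Dosimetry

`dbm_to_mw(x) = 10^(x/10)`; `power_density = EIRP/(4πR²)` converted to
mW/cm² (the unit conventions mix W/m² and mW/cm² in this literature, so the
output unit is fixed and the conversion explicit); `duty_cycle = rate ×
width` (error at ≥ 1); `time_avg_density = density × duty`. The far-field
formula over-predicts near-field densities; no correction is applied — the
numbers are deliberate worst-case bounds. SAR, antenna patterns and
regulatory databases are out of scope.

## Problem sizes and determinism

Every stochastic operation takes an explicit integer seed
(`numpy.random.default_rng`); fixed seeds give bit-identical event lists and
byte-identical CSV outputs. Multi-animal and multi-replicate runs derive
31-bit child seeds from one master seed via `numpy.random.SeedSequence`.
The bundled analyses use the protocol-scale sizes throughout: 30 min clock
recordings (~1800 events), 30 min three-cage crosstalk runs, and 6-day
circadian simulations (4 + 3 animals, ~2–5 × 10⁴ events each); replicate
counts are 20 seeds for phase-shift recovery and 10 for crosstalk recovery.

## Known limitations

- The entrainment model is phase-only: no period (tau) mismatch, no
  masking, no transients within a day.
- The device model is event-level; it does not simulate RC timing of the
  multivibrators, SD latency variation, or sensor analog response.
- The pickup estimator counts records, not events, so dead-time absorption
  couples it weakly to the occupied cage's rate (≈ +1 percentage point at
  0.5 events/s, dead time 0.1 s).
- The PD scorer assumes a static camera and background; any global
  illumination change would read as motion.
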