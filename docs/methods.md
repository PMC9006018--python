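# Methods

This note documents the models, conventions and numerical choices behind
the package, and what the synthetic validation does and does not
demonstrate about real field data.

## The two measurement signals

**Nest temperature.** A logger in the nest wall reads the combined effect
of ambient temperature and the occupants' heat output. The detection
criterion is pointwise: a *substantial drop* exists where the
nest-to-ambient difference (T_nest − T_a) falls to ≤ 7 °C (configurable).
All nocturnal statistics are referenced to geometric sunset/sunrise with
standard refraction (solar altitude −0.833°), computed by an internal NOAA
solar-position implementation; the altitude threshold is exposed so the
sensitivity to the rise/set convention can be tested.

**Whole-nest metabolism.** One pooled V̇O2 trace per nest-box night. The
reference resting rate MR_ref is read 30 min after the arrival peak, when
the family has settled; MR_min is the lowest nocturnal value; the relative
reduction (MR_ref − MR_min)·100/MR_ref, with a ≥ 50 % guideline
(boundary inclusive; a replication preset at 48 % admits boundary nights
just under the guideline), corroborated by a same-night temperature drop,
classifies torpor. All quantities describe the pooled family; no
per-individual attribution is attempted.

## Drop detection conventions

The published criterion defines only the pointwise inequality. Durations,
magnitudes and event counts need explicit conventions, which are:

* **Persistence.** A below-criterion run must last ≥ 30 min (6 samples at
  5-min logging). Logger accuracy of ±0.5 °C makes single-sample crossings
  unreliable.
* **Decline start.** The drop magnitude is read "from the time T_nest
  decreased continuously". Raw nest temperature drifts down every evening
  simply because ambient does, so continuity is evaluated on a *detrended*
  signal: T_nest minus ambient passed through a first-order low-pass with
  the assumed nest thermal time constant (default 60 min). For a passively
  coupled nest this filter reproduces exactly how ambient enters the nest
  reading, so ambient swings cancel and only the birds' heat input
  remains. "Declining" means a trailing 30-min slope ≤ −0.02 °C/min;
  isolated sub-threshold flickers are bridged, as are level maintenance
  plateaus (≤ 90 min, no ≥ 1 °C rebound) between the criterion crossing
  and the decline that caused it. The start refines to the latest sample
  within 0.25 °C of the preceding local temperature maximum.
* **Event end.** Recovery to within 2 °C of the start value, capped at the
  next local noon — these are nocturnal daily bouts, and an uncapped
  search would fuse consecutive torpor nights. Events separated by
  < 30 min merge; at most one event per night survives (largest
  magnitude), nights being keyed by the local date of their sunset.
* **Gaps.** Readers never interpolate. Events containing a logger gap
  > 30 min are flagged and excluded from duration statistics.

**Shape screening.** The drop must resemble a torpor cycle. The score in
[0, 1] averages three sub-scores: sustained monotone entry (clear falls,
beyond the trace's own noise scale, from event start to the criterion
crossing, weighted by entry duration — a real entry plus passive cooling
takes an hour or more); plateau depth × duration (the smoothed difference
must sit clearly below the criterion, judged against a robust noise sigma,
for on the order of two hours); and sustained rewarming (steepest ≥ 30-min
rise at least half the cooling rate, monotone over the arousal itself).
Events scoring < 0.5 are rejected as artefacts; abrupt departure cooling
scores 0 on rewarming by construction. The quantitative sub-score design
is this package's own — the field-validated criterion behind it was a
video pilot whose rule is not public.

**Occupancy.** A night is occupied when the mean nocturnal (T_nest − T_a)
exceeds 3 °C — an occupied nest here is warmed ~8–12 °C — or a drop event
(which implies prior warming) spans it; < 50 % nocturnal coverage makes a
night unknown and removes it from denominators. Only nests with ≥ 30
*consecutive* occupied nights enter season tables; observations are the
occupied-night totals of those nests. Season percentages round half-up to
one decimal (nights) and integer (nests); across-season spread uses the
rounded per-season percentages with the sample SD.

## Night scoring conventions

MR_ref is read off a 15-min smoothed trace at exactly peak + 30 min: the
definition is a point value, but a point read of a noisy analyzer would
corrupt every downstream percentage. MR_min uses a wider 45-min window,
applied to the night-truncated trace so windows near sunrise cannot mix in
the post-departure morning decline — the minimum of a noisy trace is
biased low, and the maintenance plateau lasts hours, so the heavier
averaging costs nothing and removes most of that bias. The arrival peak is
the 5-min-smoothed maximum within ±90 min of sunset, accepted if ≥ 1.3×
the pre-window median (ties to the earlier sample); otherwise scoring
falls back to sunset + 30 min, flagged. Onset is the first sustained
(≥ 30 min) excursion below 0.9 × MR_ref within the night, tracked back to
its local start; arousal ends at the first recovery above 0.9 × MR_ref
after the minimum (trace end if none, flagged). The 0.9 factor and
persistence are this package's choices — the endpoints are reported in the
source material without an operational definition.

## The simulator

The generator produces the joint structure the detectors assume, with
known truth:

* **Ambient**: a diel curve (minimum 05:00, maximum 15:00 local) around
  day means drawn from a cold/ordinary two-component mixture
  (P(cold) = 0.2, shift −5 °C, jitter SD 1 °C), linearly interpolated
  between daily noon anchors so weather drifts rather than steps, plus
  Gaussian sensor noise (SD 0.3 °C).
* **Metabolism**: daytime input at 0.7 × resting (adults forage; only
  nestlings heat the nest), a steep arrival spike 20 min before sunset
  (2 × resting, decaying within 30 min), the full-family resting plateau
  (6 ml O2/min for the group) overnight, and on torpor nights an
  exponential entry ramp (τ = 25 min) starting 19 min after sunset toward
  resting × (1 − 0.56), a maintenance plateau, and an exponential arousal
  (τ = 12 min) completing 45 min before sunrise. Non-torpor nights are
  flat by default; a shallow nocturnal reduction is available via
  `nontorpor_fraction`. Torpor is drawn per nest-night (default
  P = 0.03); a logistic coupling to the day-mean ambient temperature is
  available but off by default, since only the group contrast — not a
  functional form — is established. Gas traces are sampled at 1 min
  (analyzers log faster than nest loggers) with Gaussian noise of 5 % of
  resting.
* **Nest temperature**: forward-Euler integration of
  T[k+1] = T[k] + Δt(−λ(T[k] − Ta[k]) + γ·MR[k]) with λ = 1/60 min⁻¹ and
  γ = 1/30 °C·min⁻¹ per unit MR, giving an occupied-nest equilibrium
  elevation γ·MR/λ = 12 °C at full resting and 5.3 °C at 56 % torpor
  depth — the drop crosses the 7 °C criterion with a realistic thermal
  lag. The logger reading adds sensor noise (SD 0.2 °C, within the
  ±0.5 °C instrument accuracy) and quantises to 0.0625 °C.

Defaults were chosen once to match the physiological magnitudes the
pipeline is meant to measure (56 % reduction depth, entry ~19 min after
sunset, arousal complete ~45 min before sunrise, ~8–9 °C drops) and the
colony's location (51.04° N, 7.83° E, UTC+2 civil time).

All randomness derives from one root seed through documented
`SeedSequence` spawn keys (ambient day effects, ambient noise, per
nest-night torpor draw and analyzer noise, per-nest logger noise), so any
single nest-night regenerates in isolation and identical configurations
are byte-identical on disk.

**What the simulator does not emulate**: individual birds (one pooled MR
per family; no huddling geometry or mass allometry), behavioural
variation in arrival time, weather fronts faster than daily, logger
drift/failure, or respirometer washout dynamics. Passing recovery tests
therefore shows the *pipeline* is correct and noise-robust under the
assumed signal structure, not that the structure exhausts real data.

## Validation summary

On noise-free simulated seasons the detectors reproduce ground-truth
labels with sensitivity = specificity = 1 and the nest begins cooling
after the metabolic onset on every torpor night. With all noise sources
on (~200 nest-nights), the reduction percentage is recovered with MAE
< 2 points, classification accuracy is 100 % at the default 56 % / 0 %
generative depths, and drop magnitudes track truth within ~0.3 °C on
average. Artefact nights — a nest hovering at the criterion with
logger-scale noise — are rejected by the shape screen in ≥ 95 % of
events. Sun times agree with an independent sunrise-equation
implementation within ±2 min across the season. The mixed-model contrast
(random intercepts for year and nest via variance components, Wald 95 %
CIs, Nakagawa-style marginal R²) recovers generative group means of
17.3 / 20.8 °C within its CIs in ≳ 90 % of replicates at n = 60, and
collapses exactly to the two-group OLS fit when the random variances are
zero (fits are cross-checked against lme4 in the test suite). Statistics
problem sizes in tests (200 traces, 500 replicates, 1000 artefact nights)
were chosen to make the Monte-Carlo margins decisive while keeping the
default suite quick to run.

## Known limitations

* The thermal-detrending filter assumes a known nest time constant
  (default 60 min); a badly wrong value re-introduces ambient transients
  into the decline test. Estimating λ per nest from unoccupied periods
  would be the natural extension.
* Group-level MR means a single torpid individual inside a large family
  can be masked; the classifier inherits this floor from the measurement,
  not the code.
* The event-end convention (recovery within 2 °C, noon cap) bounds
  durations below ~16 h; published bouts up to 22 h would be truncated.
* Multi-day torpor is out of scope by design (daily torpor only).
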