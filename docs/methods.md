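# Methods

This note documents the models, conventions and numerical choices behind
`fiberfeed`, in the spirit of a package methods appendix. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Signal model and processing chain

A recording is a pair of fluorescence channels sampled on a common clock:
the calcium-dependent 465 nm-evoked signal `f_ca` and the
calcium-independent (isosbestic) 405 nm-evoked signal `f_iso`, acquired by
time-division multiplexing at a nominal 10 Hz (20 Hz in dual-excitation
configurations). Sessions are anchored to Zeitgeber time (ZT, hours after
lights-on; ZT12 = lights-off in a 12:12 cycle) by the start-of-recording ZT.

Two processing chains are enforced, differing in order:

* **short trials (< 1 h)** — Gaussian-smooth both channels (window = 7
  samples, σ = 1 sample), motion-correct, align to the pellet drop, ΔF/F₀
  then z-score against the 3 min–10 s pre-drop window;
* **day-long recordings** — motion-correct the raw channels, ΔF/F₀ against
  the ZT6–ZT9 window (ZT3–ZT6 when fasting starts at ZT6), 30-minute
  trailing mean, then z-score the filtered signal against the same ZT
  window.

Whether the short-trial regression is fit on smoothed or raw channels is
genuinely underdetermined by convention; `motion_correct(presmooth=...)`
exposes the switch, and the short-trial chain defaults to fitting on the
smoothed channels (smoothing is described as a noise-removal step that
precedes correction).

Motion correction is a single ordinary-least-squares fit of `f_ca` on
`f_iso` over the whole recording; the prediction is subtracted and the mean
465 nm signal added back, so `mean(corrected) = mean(f_ca)` exactly (OLS
residuals with an intercept sum to zero). A zero-variance isosbestic
channel degrades to an intercept-only fit — the output equals `f_ca` — with
a logged warning rather than an error, since a dead reference channel
should not abort a batch run.

### Numerical conventions

* All analysis windows are half-open `(start, end]` in recording seconds;
  ZT windows resolve to their first occurrence at or after recording start,
  and an end ≤ start wraps midnight (the ZT12–ZT2 fast window spans 14 h).
* Standard deviations use the n−1 (sample) denominator; configurable via
  `ddof` where it matters.
* The Gaussian kernel spans exactly `window` samples and is renormalized
  after truncation; edges renormalize over the available samples (no
  padding), so constants are fixed points of the filter.
* The trailing mean uses the shrinking available window at the start of a
  recording, so day-long summaries are defined from t = 0.
* Non-finite samples are dropped at load time (with a logged count), never
  interpolated.
* Peri-event snippets are taken on the trace's own sample grid (nearest
  sample to the event); events whose window is incomplete are excluded, not
  padded, so pooled means never mix window lengths.

## Time constants

τ is defined as the earliest sample time at which the baseline-subtracted
signal first reaches `threshold_fraction` (default **0.638**) of its
extremum within a search window. The printed constant 63.8% is honored
exactly rather than rounded to 1 − 1/e ≈ 63.2%; it is configurable. τ is
reported at the sample resolution of the supplied (smoothed) trace, with no
sub-sample interpolation, and is invariant to affine rescaling of the trace
(both extremum and threshold are baseline-relative), so ΔF/F₀ and zΔF/F₀
give identical values.

* **Falls** (food presentation): search −30 s to +5 min around the drop.
  No explicit pre-stimulus baseline window accompanies the fall definition,
  so the estimator reuses the ΔF/F₀ baseline (3 min–10 s pre-drop); this is
  an assumption, flagged here and overridable via `baseline_window`.
* **Rises** (food removal): search ZT11–ZT18 against the ZT11–ZT12
  baseline; τ is reported relative to the fast onset (ZT12), since ZT11
  anchors the baseline, not the clock origin.
* A wrong-signed extremum (no fall/rise present) yields `valid=False` and
  NaN rather than a spurious crossing time.

**Reading a time constant out of a crossing.** For a saturating exponential
with time constant T, the threshold crossing sits at
`T·ln(1/(1−0.638)) ≈ 1.016·T` (window-limited maxima pull it earlier). The
30-minute trailing mean delays a slow crossing by its group delay — exactly
`T·ln((T/w)(e^{w/T}−1))`, ≈ w/2 for T ≫ w. `tau_cross_to_time_constant`
therefore subtracts `smoothing_window/2` before dividing by the log factor.
Recovery tests use this corrected estimate; the pipeline's reported
`tau_h`/`tau_s` columns remain the raw crossing times, which is the
convention in which such values are usually quoted.

Known residual biases, deliberately not corrected: the finite ZT11–ZT18
window truncates slow exponentials (the observed maximum underestimates the
asymptote, shifting the crossing early — ≈ −15% at T = 3 h), and the
circadian component leaks into the baseline-to-extremum contrast (< ±5% at
the default 10:1 rise-to-circadian amplitude ratio). These are properties
of the threshold method itself, and they are what the recovery tests
quantify.

## Event-locked analysis

* **Refractory filter**: a poke is kept iff no poke (either port) occurred
  strictly within the preceding 45 s; the test is against *all* pokes, not
  only previously kept ones.
* **Alignment**: −45 s to +100 s around each kept poke; each snippet is
  independently re-normalized (ΔF/F₀ then z) against its own 45–1 s
  pre-event window. Degenerate baselines (zero mean or zero SD) exclude the
  event with a logged count.
* **Summaries**: the default poke-aligned mean ± SEM pools all pokes from
  all mice; `pool_and_average` provides the two-stage per-mouse variant
  (mean over trials within mouse, then across mice, SEM over mice) used for
  everything else.
* **Poke rate**: pokes/min over a sliding 30-min window, centered by
  default (configurable to trailing); edges normalize by the actually
  covered minutes.
* **Deciles**: poke i of N (time order) has cumulative percentage 100·i/N
  and decile ⌈(100·i/N)/10⌉ clipped to [1, 10] — the ceiling convention is a
  choice; the brute-force evaluation of the rule is the normative test.
  Deciles {1, 4, 7, 10} are flagged for presentation.
* **Feeding phases** (per trial, on ΔF/F₀): pre-drop = 30–20 s before the
  drop (avoiding pre-drop cues), pre-contact = drop to 1 s before contact,
  pre-bite = contact to 1 s before bite, bite = 10 s after the first bite.
  Empty windows are reported as absent, never as zero.

`holm_sidak_adjust` implements the step-down Holm–Šidák adjustment
(sorted-order running maximum of `1 − (1 − p_(j))^(m−j+1)`), for post-hoc
use after omnibus tests; omnibus machinery itself is left to standard
statistics libraries.

## The synthetic generator

The generator emulates exactly the structure the analysis assumes, with a
latent state s(t) that couples to behavior only through the schedule (no
closed loop), so ground truth stays analytically known:

* **latent state**: one circadian cosine harmonic (amplitude 0.05, peak
  ZT14 — daily structure is real but deliberately a single replaceable
  harmonic) plus a condition term: a saturating-exponential rise at the
  fast onset (amplitude 0.5; presets carry time constants 1.78 h for the
  AgRP-like and 0.87 h for the Sim2-like population) or an exponential fall
  at pellet drop (amplitude 0.5, 7.5 s preset). Optional spontaneous
  transients (default amplitude 0, rate fixed at 6/h when enabled) keep the
  default trace deterministic.
* **photometry**: `ca = B_ca·bleach_ca(t)·(1+s) + a(t) + ε`,
  `iso = B_iso·bleach_iso(t) + g·a(t) + ε'`, with a(t) an
  Ornstein–Uhlenbeck motion artifact (1-s correlation time, SD 2 a.u.)
  shared between channels up to gain g = 0.8, white noise SD 1 a.u. (1% of
  the 100 a.u. calcium baseline), mono-exponential bleaching per channel.
  **Bleaching defaults to off**: a bleach trend on the reference channel is
  collinear over a day with slow real activity, so the single
  whole-recording regression — the only corrector in scope — cannot
  separate them (measured at 100/150 h halflives, the induced time-constant
  bias is tens of percent even noiselessly). Bleach-free acquisition is
  therefore the generator's reference condition; bleaching is an opt-in
  non-ideality for robustness studies, and this validity limit applies
  equally to real day-long recordings analyzed this way.
* **behavior**: an inhomogeneous Poisson poke process, held constant within
  1-s bins. Ad-lib intensity is a base rate (0.5 pokes/min) plus
  exponentially decaying meal-cluster bumps (2 clusters/h, +5 pokes/min,
  120-s decay); during the fast window the intensity is
  `floor + burst·e^{−Δt/τ_ext}` (0.2 + 3 pokes/min, τ_ext = 1.5 h) and no
  pellet events occur. Outside the window every poke triggers a pellet drop
  (FR1) and a retrieval after an exponential delay (mean 10 s — delays are
  otherwise unreported, so exponential is the natural one-parameter
  choice).

What the generator does **not** emulate — and hence what passing tests do
not certify about real data: calcium-indicator kinetics (s(t) is the
"activity" itself, not a convolved spike train), state-dependent behavior
feedback, hemodynamic or spectral artifacts that differ between excitation
wavelengths, non-exponential bleaching, and video-derived annotation
jitter (contact/bite marks are placed at fixed 4 s/8 s offsets).

Noise magnitudes for real recordings of this kind are not published; the
defaults were chosen for testability of the pipeline, not to mimic a
specific rig.

## Problem sizes and runtime choices

Recovery simulations span ZT6–ZT18.5 (12.5 h) at 10 Hz — nothing after
ZT18 enters the rise analysis, so longer spans only add cost. The fixture
suite used by the orchestration tests uses 13-h sessions at 1–5 Hz, and the
dispersion/extinction Monte-Carlo checks use 500/200 short behavioral
sessions. The acceptance script runs in a few seconds on one CPU.

## Known limitations

* The threshold-crossing τ is a crossing time, not a fitted time constant;
  its finite-window and smoothing biases are characterized above and in the
  recovery tests rather than removed.
* The fall-τ baseline reuses the ΔF/F₀ window by assumption (see above).
* Whether poke-aligned SEM should be over pokes or over mice is a genuine
  ambiguity; over-pokes is the default, with the per-mouse variant provided.
* `condition_contrast` pairs conditions within mouse and drops unpaired
  mice; it does not model trial-level variance.
* No vendor binary formats, no TTL/video synchronization, no port-preference
  analysis (ports are combined throughout), no plotting beyond what callers
  build from the CSV outputs.
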