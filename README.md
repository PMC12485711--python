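# fiberfeed

Analysis of fiber-photometry recordings from feeding-circuit neurons together
with home-cage operant (FED3) behavior — plus a synthetic-data generator with
fully known ground truth, so the whole pipeline can be validated without any
in vivo data.

## What problem this addresses

Bulk calcium recordings from hypothalamic feeding circuits (e.g. arcuate
AgRP "hunger" neurons and their paraventricular Sim2-expressing excitatory
afferents) are used to ask how fast neural activity reacts when food appears
or disappears: the rapid fall when a fasted mouse is presented with a
pellet, the hours-scale rise after food removal at lights-out, and the
poke-by-poke dynamics of unsuccessful food seeking during operant
extinction. Getting from a raw two-channel fluorescence trace to a defensible
time constant involves a long chain of conventions — motion correction
against the isosbestic channel, baseline windows, smoothing, event
alignment, per-mouse averaging — and each step can silently bias the
result. `fiberfeed` implements that chain as a tested library, and pairs it
with a simulator whose latent dynamics are known, so every stage has a
ground truth to be checked against.

## The model and statistics at the core

**Normalization.** With F the motion-corrected 465 nm-evoked signal,

- ΔF/F₀ = (F − F₀)/F₀, F₀ the mean over a baseline window
  (3 min – 10 s before pellet drop for short trials; ZT6–ZT9 for day-long
  recordings, ZT3–ZT6 when fasting starts at ZT6);
- zΔF/F₀ = (ΔF/F₀ − M)/S with M, S the baseline-window mean and SD.

**Motion correction.** corrected = f_ca − (â + b̂·f_iso) + mean(f_ca), with
(â, b̂) a single ordinary-least-squares fit of the calcium channel on the
isosbestic channel over the whole recording; the trace mean is preserved
exactly.

**Time constants.** τ is the earliest time at which the baseline-subtracted
signal first reaches 63.8% of its extremum within a search window
(−30 s … +5 min around food presentation for falls; ZT11–ZT18 with a
ZT11–ZT12 baseline for fasting rises). For a saturating exponential the
crossing sits at T·ln(1/(1−0.638)) ≈ 1.016·T;
`tau_cross_to_time_constant` inverts this (optionally compensating the
group delay of the 30-min trailing mean) to recover the underlying T.

**Operant behavior.** Pokes (both ports combined) form an inhomogeneous
Poisson process; during the fast window (ZT12–ZT2) pellet delivery pauses
and the intensity follows the extinction-burst law
λ(t) = floor + burst·e^(−(t−t₀)/τ_ext). Analysis uses a 45-s refractory
filter, −45 s…+100 s poke-aligned windows re-normalized per event against
the 45–1 s pre-poke baseline, a 30-min sliding poke rate, and a decile
split by cumulative poke percentage.

## Worked example

Simulate one fasting session from the Sim2-afferent preset (rise time
constant 0.87 h, onset at lights-out), run the long-term pipeline, and read
off the fasting-rise time constant:

```python
import fiberfeed as ff

state = ff.simulate_latent_state(ff.PRESETS["sim2_fast"], "fast",
                                 duration_h=12.5, sample_rate=10.0, seed=1)
rec, truth = ff.simulate_photometry(state, ff.PhotometryNoiseParams(), seed=1)
z = ff.preprocess_longterm(rec)          # regression → dF/F0 → 30-min mean → z
est = ff.rise_tau(z)                     # 63.8% threshold crossing, ZT11–ZT18
tau = ff.tau_cross_to_time_constant(est.tau, smoothing_window=0.5)
```

This prints, via the two estimates:

```
threshold crossing: 1.10 h after fast onset
recovered time constant: 0.84 h (generator value 0.87 h)
```

The crossing time (1.10 h) is what the convention reports directly; dividing
out the 1.016 factor and the 15-min filter delay recovers the generator's
time constant to within 4%. Hourly ZT bins of the same z-scored trace
(`ff.hourly_zt_bins(z)`) rise from 4.4 at ZT11 to 50.8 at ZT15, the
signature of the fasting activation.

The same chain is available from a shell:

```
fiberfeed simulate --out runs/sim --seed 1
fiberfeed analyze-longterm --input-dir runs/sim/sessions --out runs/longterm
fiberfeed analyze-operant  --input-dir runs/sim/sessions --out runs/operant
```

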