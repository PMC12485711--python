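"""Synthetic photometry recordings and operant behavior with known ground truth.

The generator produces the statistical structure the analysis pipeline
assumes, so every stage can be verified without in vivo data:

* a latent population-activity state ``s(t)`` — one circadian cosine harmonic,
  a saturating-exponential rise triggered by food removal (fasting), and a
  fast exponential fall triggered by food presentation;
* dual-channel fluorescence: the calcium channel carries ``(1 + s(t))``
  scaled by a mono-exponential photobleach, plus a low-pass (Ornstein–
  Uhlenbeck) motion artifact shared with the isosbestic channel and white
  shot-like noise;
* FR1 operant behavior from an inhomogeneous Poisson poke process with an
  extinction burst (``floor + burst·e^{−Δt/τ}``) when pellet delivery pauses
  during the fast window.

The latent state couples to behavior only through the schedule — there is no
closed-loop dynamics — so the ground truth stays analytically known.
Identical parameters and seed reproduce every output bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
from scipy.signal import lfilter

from .io import (
    EventLog,
    RawRecording,
    SessionMeta,
    ValidationError,
    save_events,
    save_recording,
    seconds_of_zt,
)

HOURS = 3600.0

#: Correlation time of the shared motion artifact (Ornstein–Uhlenbeck), s.
ARTIFACT_TAU_S = 1.0
#: Rate of spontaneous calcium transients when transient_amplitude > 0, per hour.
TRANSIENT_RATE_PER_H = 6.0
#: Ad-lib meal clusters: added poke rate at cluster onset (pokes/min) and its decay (s).
CLUSTER_BOOST_POKES_PER_MIN = 5.0
CLUSTER_DECAY_S = 120.0
#: Delays from pellet drop to contact and first bite in simulated food trials, s.
CONTACT_DELAY_S = 4.0
BITE_DELAY_S = 8.0

Schedule = Literal["ad_lib", "fast", "food_presentation_trial"]


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


@dataclass(frozen=True)
class StateParams:
    """Latent-state dynamics parameters.

    Amplitudes are dimensionless (fractions of baseline fluorescence); the
    fasting rise time constant is in hours, the food-fall and transient time
    constants in seconds.
    """

    circadian_amplitude: float = 0.05
    circadian_peak_zt: float = 14.0
    fast_rise_amplitude: float = 0.5
    fast_rise_tau: float = 1.78  # hours
    fast_onset_zt: float = 12.0
    food_fall_amplitude: float = 0.5
    food_fall_tau: float = 7.5  # seconds
    transient_amplitude: float = 0.0
    transient_decay: float = 2.0  # seconds

    def __post_init__(self) -> None:
        _require(self.fast_rise_tau > 0, f"fast_rise_tau must be > 0; got {self.fast_rise_tau}")
        _require(self.food_fall_tau > 0, f"food_fall_tau must be > 0; got {self.food_fall_tau}")
        _require(
            self.transient_decay > 0, f"transient_decay must be > 0; got {self.transient_decay}"
        )
        _require(
            0.0 <= self.circadian_peak_zt < 24.0,
            f"circadian_peak_zt must be in [0, 24); got {self.circadian_peak_zt}",
        )
        for name in ("circadian_amplitude", "fast_rise_amplitude", "food_fall_amplitude",
                     "transient_amplitude"):
            _require(math.isfinite(getattr(self, name)), f"{name} must be finite")


@dataclass(frozen=True)
class PhotometryNoiseParams:
    """Acquisition model: baselines, photobleaching, shared artifact, noise.

    ``bleach_halflife_*`` are in hours; the default ``None`` disables
    bleaching. A single whole-recording isosbestic regression cannot separate
    a bleach trend from slow real activity (they are collinear over a day),
    so bleach-free acquisition is the generator's reference condition and
    bleaching is an opt-in non-ideality. The artifact waveform is identical
    on both channels up to ``artifact_gain_iso``.
    """

    bleach_halflife_ca: float | None = None
    bleach_halflife_iso: float | None = None
    artifact_sd: float = 2.0
    artifact_gain_iso: float = 0.8
    white_noise_sd: float = 1.0
    baseline_ca: float = 100.0
    baseline_iso: float = 50.0
    sample_rate: float = 10.0

    def __post_init__(self) -> None:
        _require(self.baseline_ca > 0, f"baseline_ca must be > 0; got {self.baseline_ca}")
        _require(self.baseline_iso > 0, f"baseline_iso must be > 0; got {self.baseline_iso}")
        _require(self.sample_rate > 0, f"sample_rate must be > 0; got {self.sample_rate}")
        _require(self.artifact_sd >= 0, "artifact_sd must be >= 0")
        _require(self.white_noise_sd >= 0, "white_noise_sd must be >= 0")
        for name in ("bleach_halflife_ca", "bleach_halflife_iso"):
            v = getattr(self, name)
            _require(v is None or v > 0, f"{name} must be None or > 0")


@dataclass(frozen=True)
class BehaviorParams:
    """FR1 operant-behavior parameters (rates in pokes/min, times as noted)."""

    adlib_poke_rate_base: float = 0.5
    adlib_meal_cluster_rate: float = 2.0  # clusters/h
    burst_rate: float = 3.0
    extinction_tau: float = 1.5  # hours
    floor_rate: float = 0.2
    fast_window: tuple[float, float] = (12.0, 2.0)  # ZT hours; end < start wraps
    retrieval_delay_mean: float = 10.0  # seconds

    def __post_init__(self) -> None:
        for name in ("adlib_poke_rate_base", "adlib_meal_cluster_rate", "burst_rate",
                     "floor_rate"):
            _require(getattr(self, name) >= 0, f"{name} must be >= 0")
        _require(self.extinction_tau > 0, f"extinction_tau must be > 0; got {self.extinction_tau}")
        _require(self.retrieval_delay_mean > 0, "retrieval_delay_mean must be > 0")


@dataclass
class LatentState:
    """Noiseless latent state trace with the parameters that produced it."""

    t: np.ndarray  # seconds since recording start
    s: np.ndarray
    params: StateParams
    schedule: Schedule
    start_zt: float
    event_time_s: float | None = None  # pellet drop (trials) / fast onset (fast)


@dataclass
class GroundTruth:
    """Everything the generator knows, for recovery tests.

    Beyond the parameter blocks and seed, the realized artifact waveform is
    kept so tests can check the channel-artifact contract exactly.
    """

    state: StateParams | None = None
    noise: PhotometryNoiseParams | None = None
    behavior: BehaviorParams | None = None
    seed: int = 0
    latent_state_trace: LatentState | None = None
    artifact_trace: np.ndarray | None = None

    def to_json_dict(self) -> dict:
        """JSON-serializable parameter record (traces omitted)."""
        out: dict = {"seed": self.seed}
        for name in ("state", "noise", "behavior"):
            block = getattr(self, name)
            out[name] = None if block is None else dataclasses.asdict(block)
        if self.latent_state_trace is not None:
            out["schedule"] = self.latent_state_trace.schedule
            out["start_zt"] = self.latent_state_trace.start_zt
            out["event_time_s"] = self.latent_state_trace.event_time_s
        return out


#: Paper-calibrated presets for the populations the pipeline targets.
PRESETS: dict[str, StateParams] = {
    # arcuate AgRP hunger neurons: slow fasting rise
    "agrp_fast": StateParams(fast_rise_tau=1.78),
    # paraventricular Sim2 afferents: faster fasting rise
    "sim2_fast": StateParams(fast_rise_tau=0.87),
    # fasted food-presentation trial: fast fall on pellet drop
    "food_trial": StateParams(food_fall_tau=7.5),
}


def simulate_latent_state(
    params: StateParams,
    schedule: Schedule,
    duration_h: float,
    sample_rate: float,
    seed: int = 0,
    *,
    start_zt: float = 6.0,
    event_time_s: float | None = None,
) -> LatentState:
    """Generate the noiseless latent state ``s(t)``.

    ``s(t)`` is a circadian cosine peaking at ``circadian_peak_zt`` plus a
    condition term: for ``fast``, a saturating-exponential rise of amplitude
    ``fast_rise_amplitude`` and time constant ``fast_rise_tau`` starting at
    ``fast_onset_zt``; for ``food_presentation_trial``, an exponential fall of
    amplitude ``food_fall_amplitude`` and time constant ``food_fall_tau`` at
    the pellet-drop time (``event_time_s``, default 180 s). Spontaneous
    transients (seeded) are added only when ``transient_amplitude > 0``, so
    the default trace is deterministic given its inputs.
    """
    _require(duration_h > 0, f"duration must be > 0; got {duration_h}")
    _require(sample_rate > 0, f"sample_rate must be > 0; got {sample_rate}")
    if schedule not in ("ad_lib", "fast", "food_presentation_trial"):
        raise ValidationError(f"unknown schedule '{schedule}'")

    n = int(round(duration_h * HOURS * sample_rate))
    t = np.arange(n) / sample_rate
    zt = start_zt + t / HOURS  # unwrapped; cosine is 24 h-periodic anyway
    s = params.circadian_amplitude * np.cos(
        2.0 * np.pi * (zt - params.circadian_peak_zt) / 24.0
    )

    if schedule == "fast":
        onset = seconds_of_zt(params.fast_onset_zt, SessionMeta(recording_start_zt=start_zt))
        event_time_s = onset
        dt = t - onset
        rise = np.where(
            dt >= 0,
            params.fast_rise_amplitude * (1.0 - np.exp(-np.maximum(dt, 0.0) / (params.fast_rise_tau * HOURS))),
            0.0,
        )
        s = s + rise
    elif schedule == "food_presentation_trial":
        if event_time_s is None:
            event_time_s = 180.0
        dt = t - event_time_s
        fall = np.where(
            dt >= 0,
            -params.food_fall_amplitude * (1.0 - np.exp(-np.maximum(dt, 0.0) / params.food_fall_tau)),
            0.0,
        )
        s = s + fall

    if params.transient_amplitude > 0.0:
        rng = np.random.default_rng(seed)
        n_tr = rng.poisson(TRANSIENT_RATE_PER_H * duration_h)
        onsets = np.sort(rng.uniform(0.0, duration_h * HOURS, size=n_tr))
        for t0 in onsets:
            dt = t - t0
            s = s + np.where(
                dt >= 0,
                params.transient_amplitude * np.exp(-np.maximum(dt, 0.0) / params.transient_decay),
                0.0,
            )

    return LatentState(
        t=t, s=s, params=params, schedule=schedule, start_zt=start_zt,
        event_time_s=event_time_s,
    )


def _ou_artifact(n: int, dt: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary Ornstein–Uhlenbeck noise with 1-s correlation time."""
    if sd == 0.0 or n == 0:
        return np.zeros(n)
    phi = math.exp(-dt / ARTIFACT_TAU_S)
    innov = rng.standard_normal(n) * sd * math.sqrt(1.0 - phi * phi)
    innov[0] = rng.standard_normal() * sd  # stationary start
    return lfilter([1.0], [1.0, -phi], innov)


def _bleach(t: np.ndarray, halflife_h: float | None) -> np.ndarray:
    if halflife_h is None:
        return np.ones_like(t)
    return np.power(0.5, t / (halflife_h * HOURS))


def simulate_photometry(
    state: LatentState,
    noise: PhotometryNoiseParams,
    seed: int = 0,
    *,
    meta: SessionMeta | None = None,
) -> tuple[RawRecording, GroundTruth]:
    """Render the latent state into a two-channel recording.

    ``ca = baseline_ca·bleach_ca(t)·(1 + s(t)) + a(t) + ε_ca`` and
    ``iso = baseline_iso·bleach_iso(t) + artifact_gain_iso·a(t) + ε_iso``,
    where ``a(t)`` is the shared low-pass motion artifact and ε white noise.
    The same seed yields identical output.
    """
    _require(len(state.t) > 0, "latent state trace is empty")
    t = state.t
    dt = 1.0 / noise.sample_rate
    rng = np.random.default_rng(seed)
    a = _ou_artifact(len(t), dt, noise.artifact_sd, rng)
    eps_ca = rng.standard_normal(len(t)) * noise.white_noise_sd
    eps_iso = rng.standard_normal(len(t)) * noise.white_noise_sd
    f_ca = noise.baseline_ca * _bleach(t, noise.bleach_halflife_ca) * (1.0 + state.s) + a + eps_ca
    f_iso = (
        noise.baseline_iso * _bleach(t, noise.bleach_halflife_iso)
        + noise.artifact_gain_iso * a
        + eps_iso
    )
    if meta is None:
        meta = SessionMeta(recording_start_zt=state.start_zt)
    rec = RawRecording(t=t, f_ca=f_ca, f_iso=f_iso, sample_rate=noise.sample_rate, meta=meta)
    truth = GroundTruth(
        state=state.params, noise=noise, seed=seed,
        latent_state_trace=state, artifact_trace=a,
    )
    return rec, truth


def _inhomogeneous_poisson(
    rate_per_min: np.ndarray, bin_edges_s: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw event times from a piecewise-constant intensity (1-s bins)."""
    widths = np.diff(bin_edges_s)
    counts = rng.poisson(rate_per_min / 60.0 * widths)
    times = []
    nz = np.nonzero(counts)[0]
    for i in nz:
        times.append(bin_edges_s[i] + rng.uniform(0.0, widths[i], size=counts[i]))
    if not times:
        return np.array([])
    return np.sort(np.concatenate(times))


def simulate_operant_session(
    behavior: BehaviorParams,
    duration_h: float,
    seed: int = 0,
    *,
    condition: Literal["ad_lib", "fast"] = "fast",
    start_zt: float = 6.0,
    state_link: LatentState | None = None,
) -> tuple[EventLog, GroundTruth]:
    """Simulate an FR1 operant session as an inhomogeneous Poisson process.

    Outside the fast window every poke is followed by a ``pellet_drop`` (FR1)
    and a ``pellet_retrieval`` after an exponential delay. Inside the fast
    window (``condition="fast"``) pokes are logged but no pellet events occur,
    and the poke intensity follows the extinction-burst law
    ``λ(t) = floor_rate + burst_rate·e^{−(t − fast_start)/extinction_tau}``.
    Ad-lib poking is a base rate plus exponentially decaying meal-cluster
    bumps. The intensity is held constant within 1-s bins.

    ``food_out``/``food_in`` events mark the fast-window bounds when they fall
    inside the session. ``state_link`` is recorded in the ground truth only;
    there is no closed-loop coupling.
    """
    _require(duration_h > 0, f"duration must be > 0; got {duration_h}")
    total_s = duration_h * HOURS
    rng = np.random.default_rng(seed)
    meta = SessionMeta(recording_start_zt=start_zt, condition=condition)

    edges = np.append(np.arange(0.0, total_s, 1.0), total_s)
    mid = 0.5 * (edges[:-1] + edges[1:])

    # ad-lib intensity: base + meal-cluster bumps
    rate = np.full(len(mid), behavior.adlib_poke_rate_base, dtype=float)
    n_cl = rng.poisson(behavior.adlib_meal_cluster_rate * duration_h)
    cluster_onsets = np.sort(rng.uniform(0.0, total_s, size=n_cl))
    for t0 in cluster_onsets:
        dtc = mid - t0
        rate += np.where(
            dtc >= 0.0,
            CLUSTER_BOOST_POKES_PER_MIN * np.exp(-np.maximum(dtc, 0.0) / CLUSTER_DECAY_S),
            0.0,
        )

    fast_span: tuple[float, float] | None = None
    if condition == "fast":
        z0, z1 = behavior.fast_window
        t_fs = seconds_of_zt(z0, meta)
        span = ((z1 - z0) % 24.0) * HOURS or 24.0 * HOURS
        t_fe = t_fs + span
        if t_fs < total_s:
            fast_span = (t_fs, min(t_fe, total_s))
            in_fast = (mid >= t_fs) & (mid < t_fe)
            rate[in_fast] = behavior.floor_rate + behavior.burst_rate * np.exp(
                -(mid[in_fast] - t_fs) / (behavior.extinction_tau * HOURS)
            )

    pokes = _inhomogeneous_poisson(rate, edges, rng)
    ports = rng.choice(("poke_left", "poke_right"), size=len(pokes))

    rows: list[tuple[float, str, object]] = [
        (float(tp), str(port), None) for tp, port in zip(pokes, ports)
    ]
    in_fast_window = np.zeros(len(pokes), dtype=bool)
    if fast_span is not None:
        t_fs, t_fe = fast_span
        in_fast_window = (pokes >= t_fs) & (pokes < t_fe)
        rows.append((float(t_fs), "food_out", None))
        if t_fe < total_s:
            rows.append((float(t_fe), "food_in", None))
    for tp in pokes[~in_fast_window]:
        rows.append((float(tp), "pellet_drop", None))
        delay = rng.exponential(behavior.retrieval_delay_mean)
        t_ret = float(tp) + float(delay)
        if t_ret <= total_s:
            rows.append((t_ret, "pellet_retrieval", None))

    log = EventLog.from_rows(rows)
    truth = GroundTruth(
        behavior=behavior, seed=seed, latent_state_trace=state_link,
    )
    return log, truth


def simulate_food_trial_events(
    event_time_s: float = 180.0,
    *,
    contact_delay_s: float = CONTACT_DELAY_S,
    bite_delay_s: float = BITE_DELAY_S,
) -> EventLog:
    """Pellet-drop / contact / first-bite annotations for a food trial."""
    return EventLog.from_rows(
        [
            (event_time_s, "pellet_drop"),
            (event_time_s + contact_delay_s, "contact"),
            (event_time_s + bite_delay_s, "first_bite"),
        ]
    )


def simulate_session(
    preset: str | StateParams,
    schedule: Schedule,
    duration_h: float,
    seed: int = 0,
    *,
    noise: PhotometryNoiseParams | None = None,
    behavior: BehaviorParams | None = None,
    start_zt: float = 6.0,
    mouse_id: str = "m0",
    sample_rate: float | None = None,
) -> tuple[RawRecording, EventLog, GroundTruth]:
    """Convenience wrapper: latent state → recording + matching event log."""
    params = PRESETS[preset] if isinstance(preset, str) else preset
    noise = noise or PhotometryNoiseParams()
    if sample_rate is not None:
        noise = dataclasses.replace(noise, sample_rate=sample_rate)
    state = simulate_latent_state(
        params, schedule, duration_h, noise.sample_rate, seed, start_zt=start_zt
    )
    condition = {"ad_lib": "ad_lib", "fast": "fast", "food_presentation_trial": "fasted"}[schedule]
    meta = SessionMeta(mouse_id=mouse_id, condition=condition, recording_start_zt=start_zt)
    rec, truth = simulate_photometry(state, noise, seed, meta=meta)

    if schedule == "food_presentation_trial":
        log = simulate_food_trial_events(state.event_time_s or 180.0)
    elif schedule == "fast":
        beh = behavior or BehaviorParams()
        log, op_truth = simulate_operant_session(
            beh, duration_h, seed, condition="fast", start_zt=start_zt, state_link=state
        )
        truth.behavior = beh
    else:
        beh = behavior or BehaviorParams()
        log, op_truth = simulate_operant_session(
            beh, duration_h, seed, condition="ad_lib", start_zt=start_zt, state_link=state
        )
        truth.behavior = beh
    return rec, log, truth


def write_fixture_suite(
    out_dir: str | Path,
    seed: int = 0,
    *,
    n_mice: int = 2,
    long_duration_h: float = 13.0,
    long_sample_rate: float = 5.0,
    trial_sample_rate: float = 10.0,
) -> list[Path]:
    """Emit a directory of paired recording + event-log CSVs with ground-truth
    JSON sidecars: per mouse one ad-lib and one fast long session (ZT6 start)
    and one fasted food-presentation trial.

    Returns the list of session directories written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for i in range(n_mice):
        mouse = f"m{i}"
        sessions = [
            ("ad_lib", "agrp_fast", "ad_lib", long_duration_h, long_sample_rate),
            ("fast", "agrp_fast", "fast", long_duration_h, long_sample_rate),
            ("food_trial", "food_trial", "food_presentation_trial", 27.0 / 60.0, trial_sample_rate),
        ]
        for j, (name, preset, schedule, dur, rate) in enumerate(sessions):
            sdir = out_dir / f"{mouse}_{name}"
            sdir.mkdir(exist_ok=True)
            sess_seed = (seed * 1009 + i * 97 + j * 7) % (2**31)
            rec, log, truth = simulate_session(
                preset, schedule, dur, sess_seed, mouse_id=mouse, sample_rate=rate
            )
            save_recording(rec, sdir / "recording.csv")
            save_events(log, sdir / "events.csv")
            (sdir / "truth.json").write_text(
                json.dumps(truth.to_json_dict(), indent=2, sort_keys=True)
            )
            written.append(sdir)
    return written
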