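"""Event-locked analysis: poke filtering, alignment, rates, deciles, phases.

Peri-event analysis follows the operant-photometry convention: pokes during
the fast period with no preceding poke within 45 s are aligned on a
−45 s…+100 s window, each snippet independently re-normalized (ΔF/F₀ then
z-score) against its own 45 s–1 s pre-event baseline, and summarized as the
mean ± SEM over pooled pokes from all mice. Per-mouse (two-stage) averaging
is available through :func:`pool_and_average`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .io import EventLog, ValidationError
from .preprocess import NormalizedTrace

logger = logging.getLogger(__name__)


def refractory_filter(
    events: EventLog | np.ndarray,
    refractory_s: float = 45.0,
) -> np.ndarray:
    """Keep each poke that has no poke (either port) in the preceding window.

    An event at time ``e`` is kept iff no poke occurs in the open interval
    ``(e − refractory, e)``. The test is against *all* pokes, not only
    previously kept ones, so removal decisions are independent.
    """
    if refractory_s < 0:
        raise ValidationError(f"refractory must be >= 0; got {refractory_s}")
    times = events.poke_times() if isinstance(events, EventLog) else np.asarray(events, float)
    times = np.sort(times)
    if len(times) == 0:
        return times
    # pokes strictly inside (e - refractory, e); endpoints do not block
    lo = np.searchsorted(times, times - refractory_s, side="right")
    hi = np.searchsorted(times, times, side="left")
    return times[hi <= lo]


@dataclass
class AlignedSet:
    """Event-locked snippets on a shared relative-time grid.

    ``traces`` is (n_events × n_samples) of z-scored ΔF/F₀; ``rel_t`` spans
    exactly [−pre, +post]. Events whose window is not fully covered, or whose
    pre-event baseline is degenerate, are excluded (``n_excluded``).
    """

    rel_t: np.ndarray
    traces: np.ndarray
    event_times: np.ndarray
    group_keys: np.ndarray  # mouse_id per kept event
    window: tuple[float, float]
    baseline: tuple[float, float]
    n_excluded: int = 0

    def __len__(self) -> int:
        return len(self.event_times)

    def mean(self) -> np.ndarray:
        self._require_events("mean")
        return self.traces.mean(axis=0)

    def sem(self) -> np.ndarray:
        """SEM over pooled events (all pokes from all mice)."""
        self._require_events("sem")
        n = len(self)
        if n < 2:
            return np.full(self.traces.shape[1], np.nan)
        return self.traces.std(axis=0, ddof=1) / math.sqrt(n)

    def _require_events(self, what: str) -> None:
        if len(self) == 0:
            raise ValidationError(
                f"cannot compute {what}: no events survived alignment "
                "(windows incomplete or baselines degenerate)"
            )


def align_to_events(
    trace: NormalizedTrace,
    event_times: np.ndarray,
    *,
    pre_s: float = 45.0,
    post_s: float = 100.0,
    baseline: tuple[float, float] = (-45.0, -1.0),
    mouse_id: str | None = None,
) -> AlignedSet:
    """Extract event-locked snippets and re-normalize each independently.

    Each snippet is converted to ΔF/F₀ and then z-scored against its own
    pre-event baseline window (default 45 s to 1 s before the event, half-
    open). Events not fully covered by the recording, or with a zero-variance
    or zero-mean baseline, are excluded with a logged count.
    """
    if pre_s <= 0 or post_s <= 0:
        raise ValidationError("pre and post must be > 0")
    t = trace.t
    if len(t) < 2:
        raise ValidationError("trace too short to align")
    dt = float(np.median(np.diff(t)))
    n_pre = int(round(pre_s / dt))
    n_post = int(round(post_s / dt))
    rel_t = np.arange(-n_pre, n_post + 1) * dt
    b_mask = (rel_t > baseline[0]) & (rel_t <= baseline[1])
    if b_mask.sum() < 2:
        raise ValidationError("pre-event baseline window contains < 2 samples")

    rows, kept_times, keys = [], [], []
    n_excluded = 0
    if mouse_id is None:
        mouse_id = trace.meta.mouse_id if trace.meta is not None else "unknown"
    for e in np.asarray(event_times, dtype=float):
        j = int(np.searchsorted(t, e))
        if j >= len(t):
            i0 = len(t) - 1
        elif j > 0 and e - t[j - 1] <= t[j] - e:
            i0 = j - 1
        else:
            i0 = j
        lo, hi = i0 - n_pre, i0 + n_post
        if lo < 0 or hi >= len(t):
            n_excluded += 1
            continue
        snip = trace.y[lo : hi + 1]
        f0 = float(np.mean(snip[b_mask]))
        if f0 == 0.0:
            n_excluded += 1
            continue
        dff = (snip - f0) / f0
        m = float(np.mean(dff[b_mask]))
        s = float(np.std(dff[b_mask], ddof=1))
        if s == 0.0 or not np.isfinite(s):
            n_excluded += 1
            continue
        rows.append((dff - m) / s)
        kept_times.append(e)
        keys.append(mouse_id)
    if n_excluded:
        logger.warning("align_to_events: excluded %d of %d event(s)", n_excluded,
                       len(np.atleast_1d(event_times)))
    traces = np.vstack(rows) if rows else np.empty((0, len(rel_t)))
    return AlignedSet(
        rel_t=rel_t,
        traces=traces,
        event_times=np.asarray(kept_times, dtype=float),
        group_keys=np.asarray(keys, dtype=object),
        window=(pre_s, post_s),
        baseline=baseline,
        n_excluded=n_excluded,
    )


def pool_and_average(
    per_mouse: dict[str, list],
) -> tuple[dict[str, np.ndarray | float], np.ndarray | float, np.ndarray | float | None]:
    """Two-stage averaging: mean over trials within mouse, then across mice.

    Returns ``(per_mouse_means, group_mean, group_sem)``; the SEM uses
    n = number of mice and is ``None`` for a single mouse. Mice with zero
    trials are dropped with a warning. Trial order never matters.
    """
    means: dict[str, np.ndarray | float] = {}
    for mouse, trials in per_mouse.items():
        if len(trials) == 0:
            logger.warning("pool_and_average: mouse %s has no trials; dropped", mouse)
            continue
        means[mouse] = np.mean(np.asarray(trials, dtype=float), axis=0)
    if not means:
        raise ValidationError("no mice with trials to average")
    stacked = np.asarray(list(means.values()), dtype=float)
    group_mean = stacked.mean(axis=0)
    n = len(means)
    group_sem = None if n < 2 else stacked.std(axis=0, ddof=1) / math.sqrt(n)
    if np.ndim(group_mean) == 0:
        group_mean = float(group_mean)
        group_sem = None if group_sem is None else float(group_sem)
    return means, group_mean, group_sem


def poke_rate(
    events: EventLog | np.ndarray,
    *,
    window_min: float = 30.0,
    session_span: tuple[float, float] | None = None,
    grid_dt_s: float = 60.0,
    centered: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window poke rate (pokes/min), combining both ports.

    ``rate(t)`` counts pokes in a centered (default) or trailing window and
    divides by the minutes of that window actually covered by the session, so
    edges are normalized by the truncated overlap. Returns ``(t_grid, rate)``.
    """
    if window_min <= 0:
        raise ValidationError(f"window must be > 0; got {window_min}")
    times = events.poke_times() if isinstance(events, EventLog) else np.asarray(events, float)
    times = np.sort(times)
    if session_span is None:
        if len(times) == 0:
            raise ValidationError("empty poke list needs an explicit session_span")
        session_span = (float(times[0]), float(times[-1]))
    t0, t1 = session_span
    grid = np.arange(t0, t1 + grid_dt_s / 2, grid_dt_s)
    w = window_min * 60.0
    if centered:
        lo, hi = grid - w / 2.0, grid + w / 2.0
    else:
        lo, hi = grid - w, grid.copy()
    lo_c, hi_c = np.clip(lo, t0, t1), np.clip(hi, t0, t1)
    counts = np.searchsorted(times, hi_c, side="right") - np.searchsorted(
        times, lo_c, side="left"
    )
    covered_min = (hi_c - lo_c) / 60.0
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(covered_min > 0, counts / covered_min, 0.0)
    return grid, rate


@dataclass
class DecileSplit:
    """Pokes binned by cumulative percentage of the fast period into deciles."""

    decile_index: np.ndarray  # 1..10 per filtered poke, time order
    mean_traces: dict[int, np.ndarray]  # decile -> mean aligned trace
    rel_t: np.ndarray
    presented_deciles: tuple[int, ...] = (1, 4, 7, 10)


def decile_assignments(n: int) -> np.ndarray:
    """Decile of poke i of N: ``ceil((100·i/N)/10)`` clipped to [1, 10]."""
    if n < 1:
        raise ValidationError("decile split needs at least one poke")
    i = np.arange(1, n + 1)
    return np.clip(np.ceil(100.0 * i / n / 10.0).astype(int), 1, 10)


def decile_split(aligned: AlignedSet) -> DecileSplit:
    """Split aligned (refractory-filtered, fast-period) pokes into deciles.

    Pokes are taken in time order; poke i of N has cumulative percentage
    100·i/N and decile ⌈(100·i/N)/10⌉. Four equally spaced deciles
    {1, 4, 7, 10} are flagged for presentation.
    """
    n = len(aligned)
    if n == 0:
        raise ValidationError("decile split needs at least one poke")
    order = np.argsort(aligned.event_times, kind="stable")
    dec = decile_assignments(n)
    assign = np.empty(n, dtype=int)
    assign[order] = dec
    mean_traces = {
        d: aligned.traces[assign == d].mean(axis=0) for d in np.unique(assign)
    }
    return DecileSplit(
        decile_index=assign, mean_traces=mean_traces, rel_t=aligned.rel_t
    )


#: Feeding-phase windows relative to (drop, contact, bite), all half-open (s].
PHASE_NAMES = ("pre_drop", "pre_contact", "pre_bite", "bite")


def phase_means(
    trace: NormalizedTrace,
    drop_s: float,
    contact_s: float,
    bite_s: float,
) -> dict[str, float | None]:
    """Mean ΔF/F₀ in the named feeding-phase windows of one trial.

    pre-drop: 30–20 s before pellet delivery (avoiding pre-drop cues such as
    a hand over the cage); pre-contact: drop to 1 s before contact; pre-bite:
    contact to 1 s before bite; bite: the 10 s following the first bite.
    Empty windows are reported as ``None``, not zero.
    """
    if not drop_s <= contact_s <= bite_s:
        raise ValidationError(
            "events must be ordered pellet_drop <= contact <= first_bite; got "
            f"drop={drop_s}, contact={contact_s}, bite={bite_s}"
        )
    windows = {
        "pre_drop": (drop_s - 30.0, drop_s - 20.0),
        "pre_contact": (drop_s, contact_s - 1.0),
        "pre_bite": (contact_s, bite_s - 1.0),
        "bite": (bite_s, bite_s + 10.0),
    }
    out: dict[str, float | None] = {}
    for name, (t0, t1) in windows.items():
        if t1 <= t0:
            out[name] = None
            continue
        mask = trace.window_mask(t0, t1)
        out[name] = float(np.mean(trace.y[mask])) if mask.any() else None
    return out


def phase_means_from_log(trace: NormalizedTrace, events: EventLog) -> dict[str, float | None]:
    """Feeding-phase means using the first drop/contact/bite of an event log."""
    def first(label: str) -> float:
        ts = events.times(label)
        if len(ts) == 0:
            raise ValidationError(f"event log has no '{label}' event")
        return float(ts[0])

    return phase_means(trace, first("pellet_drop"), first("contact"), first("first_bite"))
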