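"""State-transition metrics: threshold-crossing τ, window summaries, contrasts.

τ is defined as the earliest time at which the baseline-subtracted signal
first reaches a fixed fraction (default 63.8%) of its extremum within a
search window:

* food-evoked falls: search −30 s to +5 min around pellet presentation,
  baseline-relative minimum, τ in seconds from the presentation;
* fasting-evoked rises: search ZT11–ZT18, baseline = mean signal ZT11–ZT12,
  τ in hours reported relative to fast onset (ZT12 by default).

Because both the extremum and the threshold are measured relative to the
baseline, the estimate is invariant to affine rescaling of the trace, so it
is indifferent to whether it is fed ΔF/F₀ or zΔF/F₀.

τ is reported at the sample resolution of the supplied (smoothed) trace; no
sub-sample interpolation is attempted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .io import SessionMeta, ValidationError, seconds_of_zt
from .preprocess import NormalizedTrace

logger = logging.getLogger(__name__)

HOURS = 3600.0

#: Printed threshold fraction. Close to, but deliberately not, 1 − 1/e ≈ 0.632.
DEFAULT_THRESHOLD_FRACTION = 0.638

#: Default fall search window relative to food presentation, seconds.
FALL_SEARCH_S = (-30.0, 300.0)
#: Default rise search and baseline windows, ZT hours.
RISE_SEARCH_ZT = (11.0, 18.0)
RISE_BASELINE_ZT = (11.0, 12.0)


@dataclass
class TauEstimate:
    """A threshold-crossing time-constant estimate.

    ``tau`` is in seconds for falls and hours for rises, relative to the
    window's reference event (food presentation / fast onset). ``valid`` is
    False when the extremum has the wrong sign — no fall (or rise) is present
    and no spurious time is returned.
    """

    tau: float
    direction: Literal["fall", "rise"]
    valid: bool
    threshold_fraction: float
    extremum_value: float
    extremum_time: float  # same units/reference as tau
    baseline_value: float
    search_window: tuple[float, float]


def estimate_tau(
    trace: NormalizedTrace,
    direction: Literal["fall", "rise"],
    search_window: tuple[float, float],
    baseline_window: tuple[float, float],
    *,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
    reference_time: float | None = None,
    time_scale: float = 1.0,
) -> TauEstimate:
    """Earliest time the baseline-subtracted trace reaches the threshold.

    All windows are half-open ``(start, end]`` in recording seconds. Let
    ``b`` be the baseline-window mean and ``x* `` the extremum of
    ``y − b`` over the search window (minimum for falls, maximum for rises);
    τ is the earliest search-window sample at which ``y − b`` first reaches
    ``threshold_fraction · x*`` in the direction of ``x*``, reported relative
    to ``reference_time`` (default: search-window start) and divided by
    ``time_scale`` (3600 to report hours).
    """
    if not 0.0 < threshold_fraction < 1.0:
        raise ValidationError(
            f"threshold_fraction must be in (0, 1); got {threshold_fraction}"
        )
    t, y = trace.t, trace.y
    t0, t1 = search_window
    b0, b1 = baseline_window
    if not (b0 < b1 and t0 < t1):
        raise ValidationError("windows must have start < end")
    b_mask = (t > b0) & (t <= b1)
    s_mask = (t > t0) & (t <= t1)
    if not b_mask.any():
        raise ValidationError("baseline window contains no samples")
    if not s_mask.any():
        raise ValidationError("search window contains no samples")
    if reference_time is None:
        reference_time = t0

    b = float(np.mean(y[b_mask]))
    x = y[s_mask] - b
    ts = t[s_mask]
    if direction == "fall":
        i_ext = int(np.argmin(x))
        ext = float(x[i_ext])
        ok = ext < 0
        crossed = x <= threshold_fraction * ext
    elif direction == "rise":
        i_ext = int(np.argmax(x))
        ext = float(x[i_ext])
        ok = ext > 0
        crossed = x >= threshold_fraction * ext
    else:
        raise ValidationError(f"direction must be 'fall' or 'rise'; got {direction!r}")

    ext_time = (float(ts[i_ext]) - reference_time) / time_scale
    if not ok:
        logger.warning("estimate_tau: no %s present in the search window", direction)
        return TauEstimate(
            tau=math.nan, direction=direction, valid=False,
            threshold_fraction=threshold_fraction, extremum_value=ext,
            extremum_time=ext_time, baseline_value=b,
            search_window=search_window,
        )
    i_cross = int(np.argmax(crossed))  # earliest True
    tau = (float(ts[i_cross]) - reference_time) / time_scale
    return TauEstimate(
        tau=tau, direction=direction, valid=True,
        threshold_fraction=threshold_fraction, extremum_value=ext,
        extremum_time=ext_time, baseline_value=b, search_window=search_window,
    )


def fall_tau(
    trace: NormalizedTrace,
    presentation_time_s: float,
    *,
    baseline_window: tuple[float, float] | None = None,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
) -> TauEstimate:
    """Food-response τ (seconds from pellet presentation).

    Searches −30 s to +5 min around the presentation. The pre-stimulus
    baseline defaults to the ΔF/F₀ baseline window, 3 min to 10 s before the
    drop (an explicit choice; see the methods note).
    """
    if baseline_window is None:
        baseline_window = (presentation_time_s - 180.0, presentation_time_s - 10.0)
    search = (
        presentation_time_s + FALL_SEARCH_S[0],
        presentation_time_s + FALL_SEARCH_S[1],
    )
    return estimate_tau(
        trace, "fall", search, baseline_window,
        threshold_fraction=threshold_fraction,
        reference_time=presentation_time_s,
    )


def rise_tau(
    trace: NormalizedTrace,
    *,
    meta: SessionMeta | None = None,
    search_zt: tuple[float, float] = RISE_SEARCH_ZT,
    baseline_zt: tuple[float, float] = RISE_BASELINE_ZT,
    onset_zt: float = 12.0,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
) -> TauEstimate:
    """Fasting-response τ (hours, relative to fast onset at ZT12).

    Searches ZT11–ZT18 against the ZT11–ZT12 baseline. The baseline anchors
    the clock at ZT11, but τ is reported from the fast onset.
    """
    meta = meta or trace.meta
    if meta is None:
        raise ValidationError("rise_tau needs SessionMeta to resolve ZT windows")
    t0 = seconds_of_zt(search_zt[0], meta)
    t1 = t0 + ((search_zt[1] - search_zt[0]) % 24.0) * HOURS
    b0 = seconds_of_zt(baseline_zt[0], meta)
    b1 = b0 + ((baseline_zt[1] - baseline_zt[0]) % 24.0) * HOURS
    if t1 > trace.t[-1]:
        raise ValidationError(
            f"rise search window ends at {t1 / HOURS:.2f} h but the trace ends "
            f"at {trace.t[-1] / HOURS:.2f} h"
        )
    ref = seconds_of_zt(onset_zt, meta)
    return estimate_tau(
        trace, "rise", (t0, t1), (b0, b1),
        threshold_fraction=threshold_fraction,
        reference_time=ref, time_scale=HOURS,
    )


def tau_cross_to_time_constant(
    tau_cross: float,
    *,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
    smoothing_window: float = 0.0,
) -> float:
    """Convert a threshold-crossing time to an exponential time constant.

    For a saturating exponential, the crossing occurs at
    ``T·ln(1/(1 − f))`` (≈ 1.016·T at f = 0.638). A trailing-mean filter of
    width ``w`` additionally delays the crossing by its group delay ≈ w/2,
    which is subtracted first when ``smoothing_window`` (same units as
    ``tau_cross``) is given.
    """
    factor = math.log(1.0 / (1.0 - threshold_fraction))
    return (tau_cross - smoothing_window / 2.0) / factor


# ---------------------------------------------------------------------------
# Window summaries


def window_means(
    trace: NormalizedTrace, windows: dict[str, tuple[float, float]]
) -> dict[str, float | None]:
    """Mean trace value over named half-open (t0, t1] windows in seconds.

    Windows outside the recording are reported as ``None`` with a warning.
    """
    out: dict[str, float | None] = {}
    for name, (t0, t1) in windows.items():
        mask = trace.window_mask(t0, t1)
        if not mask.any():
            logger.warning("window_means: window '%s' outside the recording", name)
            out[name] = None
        else:
            out[name] = float(np.mean(trace.y[mask]))
    return out


def pellet_windows(drop_s: float) -> dict[str, tuple[float, float]]:
    """The pre/post windows around a pellet drop: 3 min before/after, 5 min after."""
    return {
        "pre3": (drop_s - 180.0, drop_s),
        "post3": (drop_s, drop_s + 180.0),
        "post5": (drop_s, drop_s + 300.0),
    }


def hourly_zt_bins(
    trace: NormalizedTrace,
    *,
    meta: SessionMeta | None = None,
    zt_start: float = 11.0,
    zt_end: float = 16.0,
) -> dict[str, float | None]:
    """Mean trace value in 1-hour ZT bins, default [ZT11,12) … [ZT15,16)."""
    meta = meta or trace.meta
    if meta is None:
        raise ValidationError("hourly_zt_bins needs SessionMeta")
    n_bins = int(round((zt_end - zt_start) % 24.0)) or 24
    windows = {}
    for k in range(n_bins):
        z = zt_start + k
        t0 = seconds_of_zt(z % 24.0, meta)
        windows[f"zt{z % 24:g}"] = (t0, t0 + HOURS)
    return window_means(trace, windows)


def condition_contrast(
    values_a: dict[str, float],
    values_b: dict[str, float],
) -> tuple[dict[str, float], float, float | None]:
    """Per-mouse paired differences (b − a), with group mean ± SEM over mice.

    Mice present in only one condition are dropped with a warning.
    """
    paired = sorted(set(values_a) & set(values_b))
    unpaired = sorted(set(values_a) ^ set(values_b))
    if unpaired:
        logger.warning("condition_contrast: dropping unpaired mice %s", unpaired)
    if not paired:
        raise ValidationError("no mice present in both conditions")
    diffs = {m: float(values_b[m]) - float(values_a[m]) for m in paired}
    arr = np.array(list(diffs.values()))
    mean = float(arr.mean())
    sem = None if len(arr) < 2 else float(arr.std(ddof=1) / math.sqrt(len(arr)))
    return diffs, mean, sem


def holm_sidak_adjust(p_values) -> np.ndarray:
    """Step-down Holm–Šidák adjusted p-values, in the original order.

    Sorted ascending, the i-th adjusted value is
    ``max_{j<=i} (1 − (1 − p_(j))^(m − j + 1))`` (1-indexed), clipped to 1.
    Adjusted values are monotone along the sorted order and never below the
    raw p-values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValidationError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    k = m - np.arange(m)  # m, m-1, ..., 1
    stepwise = 1.0 - np.power(1.0 - sorted_p, k)
    adjusted_sorted = np.minimum(np.maximum.accumulate(stepwise), 1.0)
    out = np.empty(m)
    out[order] = adjusted_sorted
    return out
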