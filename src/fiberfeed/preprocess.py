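"""Normalization of raw photometry into ΔF/F₀ and z-scored traces.

The processing chain mirrors standard dual-channel GCaMP practice:

* short trials (< 1 h): Gaussian-smooth both channels (window = 7 samples,
  sigma = 1 sample), then regress out the isosbestic channel;
* long recordings (≥ 23 h): isosbestic regression first, then ΔF/F₀ against
  an absolute-ZT baseline, a 30-minute trailing mean to suppress fast
  fluctuations, and finally a z-score against the same ZT baseline.

Motion correction predicts the calcium-dependent (465 nm-evoked) signal from
the calcium-independent (405 nm-evoked) signal by ordinary least squares over
the whole recording, subtracts the prediction, and adds back the mean 465 nm
signal — so motion shared by both channels cancels while the trace mean is
preserved exactly.

All windows are half-open ``(start, end]`` in recording seconds; ZT-specified
windows are resolved through :mod:`fiberfeed.io`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

from .io import RawRecording, SessionMeta, ValidationError, zt_window_to_seconds

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BaselineSpec:
    """A baseline window, in recording seconds, seconds relative to an event,
    or absolute ZT hours.

    ``units`` is one of ``"seconds"`` (absolute recording seconds),
    ``"relative"`` (seconds relative to a reference event), or ``"zt"``
    (Zeitgeber hours; may wrap midnight).
    """

    start: float
    end: float
    units: Literal["seconds", "relative", "zt"] = "seconds"

    def resolve(
        self,
        *,
        meta: SessionMeta | None = None,
        duration_s: float | None = None,
        event_time: float | None = None,
    ) -> tuple[float, float]:
        """Resolve to an absolute half-open window (t0, t1] in seconds."""
        if self.units == "seconds":
            t0, t1 = self.start, self.end
        elif self.units == "relative":
            if event_time is None:
                raise ValidationError("relative baseline needs an event_time")
            t0, t1 = event_time + self.start, event_time + self.end
        else:
            if meta is None or duration_s is None:
                raise ValidationError("ZT baseline needs meta and duration")
            return zt_window_to_seconds((self.start, self.end), meta, duration_s)
        if not t0 < t1:
            raise ValidationError(f"baseline window has start >= end: ({t0}, {t1})")
        return t0, t1


#: Default ΔF/F₀ / z baseline for short pellet-drop trials: 3 min to 10 s
#: before the drop.
TRIAL_BASELINE = BaselineSpec(-180.0, -10.0, units="relative")
#: Default baseline for day-long recordings.
LONGTERM_BASELINE = BaselineSpec(6.0, 9.0, units="zt")
#: Baseline used instead when fasting starts at ZT6.
LONGTERM_BASELINE_ZT6_FAST = BaselineSpec(3.0, 6.0, units="zt")


@dataclass
class NormalizedTrace:
    """A single-channel trace with its normalization provenance.

    ``kind`` advances only along corrected → dff → z.
    """

    t: np.ndarray
    y: np.ndarray
    kind: Literal["corrected", "dff", "z"]
    baseline: BaselineSpec | None = None
    smoothing: str | None = None
    meta: SessionMeta | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if len(self.t) != len(self.y):
            raise ValidationError("t and y must have equal length")

    def __len__(self) -> int:
        return len(self.t)

    def window_mask(self, t0: float, t1: float) -> np.ndarray:
        """Boolean mask of samples in the half-open window (t0, t1]."""
        return (self.t > t0) & (self.t <= t1)


def _window_mask(t: np.ndarray, t0: float, t1: float) -> np.ndarray:
    return (t > t0) & (t <= t1)


def gaussian_smooth(y: np.ndarray, window: int = 7, sigma: float = 1.0) -> np.ndarray:
    """Smooth with a truncated discrete Gaussian kernel.

    The kernel spans exactly ``window`` samples (odd), renormalized to sum to
    one; at the edges the weights are renormalized over the available samples
    (no padding), so a constant input is returned unchanged everywhere.
    """
    y = np.asarray(y, dtype=float)
    if window < 1 or window % 2 == 0:
        raise ValidationError(f"window must be odd and >= 1; got {window}")
    if sigma <= 0:
        raise ValidationError(f"sigma must be > 0; got {sigma}")
    if window > len(y):
        raise ValidationError(f"window ({window}) longer than trace ({len(y)})")
    half = window // 2
    k = np.exp(-0.5 * (np.arange(-half, half + 1) / sigma) ** 2)
    k /= k.sum()
    num = np.convolve(y, k, mode="same")
    den = np.convolve(np.ones_like(y), k, mode="same")
    return num / den


def motion_correct(rec: RawRecording, *, presmooth: bool = False) -> NormalizedTrace:
    """Remove motion shared by the two channels via isosbestic regression.

    ``corrected = f_ca − (â + b̂·f_iso) + mean(f_ca)`` with (â, b̂) from a
    single ordinary-least-squares fit over the whole recording. A
    zero-variance isosbestic channel falls back to an intercept-only fit
    (output equals ``f_ca``) with a logged warning.

    With ``presmooth=True`` both channels are Gaussian-filtered
    (window=7, sigma=1) before the fit, the convention for short trials.
    """
    if len(rec) < 3:
        raise ValidationError("motion correction needs a recording of length >= 3")
    f_ca, f_iso = rec.f_ca, rec.f_iso
    smoothing = None
    if presmooth:
        f_ca = gaussian_smooth(f_ca)
        f_iso = gaussian_smooth(f_iso)
        smoothing = "gaussian(window=7,sigma=1)"
    var_iso = float(np.var(f_iso))
    if var_iso == 0.0:
        logger.warning(
            "isosbestic channel has zero variance; skipping regression "
            "(output equals the calcium channel)"
        )
        corrected = f_ca.copy()
    else:
        slope = float(np.cov(f_ca, f_iso, ddof=0)[0, 1]) / var_iso
        intercept = float(np.mean(f_ca) - slope * np.mean(f_iso))
        corrected = f_ca - (intercept + slope * f_iso) + np.mean(f_ca)
    return NormalizedTrace(
        t=rec.t, y=corrected, kind="corrected", smoothing=smoothing, meta=rec.meta
    )


def compute_dff(
    trace: NormalizedTrace,
    baseline: BaselineSpec,
    *,
    event_time: float | None = None,
) -> NormalizedTrace:
    """ΔF/F₀ = (F − F₀)/F₀ with F₀ the mean over the baseline window."""
    t0, t1 = baseline.resolve(
        meta=trace.meta, duration_s=float(trace.t[-1]), event_time=event_time
    )
    mask = _window_mask(trace.t, t0, t1)
    if mask.sum() < 2:
        raise ValidationError(
            f"baseline window ({t0:.1f}, {t1:.1f}] s contains "
            f"{int(mask.sum())} sample(s); need >= 2"
        )
    f0 = float(np.mean(trace.y[mask]))
    if f0 == 0.0:
        raise ValidationError("baseline mean F0 is zero; cannot form dF/F0")
    return NormalizedTrace(
        t=trace.t,
        y=(trace.y - f0) / f0,
        kind="dff",
        baseline=baseline,
        smoothing=trace.smoothing,
        meta=trace.meta,
    )


def compute_zscore(
    trace: NormalizedTrace,
    baseline: BaselineSpec,
    *,
    event_time: float | None = None,
    ddof: int = 1,
) -> NormalizedTrace:
    """z = (F − M)/S with M, S the baseline-window mean and SD of the trace.

    The SD uses the n−1 (sample) denominator by default; set ``ddof=0`` for
    the population convention.
    """
    t0, t1 = baseline.resolve(
        meta=trace.meta, duration_s=float(trace.t[-1]), event_time=event_time
    )
    mask = _window_mask(trace.t, t0, t1)
    if mask.sum() < 2:
        raise ValidationError(
            f"baseline window ({t0:.1f}, {t1:.1f}] s contains "
            f"{int(mask.sum())} sample(s); need >= 2"
        )
    m = float(np.mean(trace.y[mask]))
    s = float(np.std(trace.y[mask], ddof=ddof))
    if s == 0.0:
        raise ValidationError(
            "degenerate baseline: standard deviation over the baseline window is zero"
        )
    return NormalizedTrace(
        t=trace.t,
        y=(trace.y - m) / s,
        kind="z",
        baseline=baseline,
        smoothing=trace.smoothing,
        meta=trace.meta,
    )


def trailing_mean(
    y: np.ndarray, t: np.ndarray, window_s: float = 30.0 * 60.0
) -> np.ndarray:
    """Rolling mean over the trailing window ``(t[i] − window, t[i]]``.

    Early samples with incomplete history use the shrinking available window,
    so output is defined from the first sample on.
    """
    y = np.asarray(y, dtype=float)
    t = np.asarray(t, dtype=float)
    if window_s <= 0:
        raise ValidationError(f"window must be > 0; got {window_s}")
    csum = np.concatenate(([0.0], np.cumsum(y)))
    idx = np.arange(len(y))
    j0 = np.searchsorted(t, t - window_s, side="right")
    n = idx - j0 + 1
    return (csum[idx + 1] - csum[j0]) / n


def preprocess_trial(
    rec: RawRecording,
    event_time: float,
    *,
    baseline: BaselineSpec = TRIAL_BASELINE,
) -> NormalizedTrace:
    """Short-trial chain: Gaussian-smooth both channels, motion-correct,
    ΔF/F₀ then z against the pre-event baseline (3 min to 10 s pre-drop)."""
    corrected = motion_correct(rec, presmooth=True)
    dff = compute_dff(corrected, baseline, event_time=event_time)
    return compute_zscore(dff, baseline, event_time=event_time)


def preprocess_longterm(
    rec: RawRecording,
    *,
    baseline: BaselineSpec = LONGTERM_BASELINE,
    smooth_window_s: float = 30.0 * 60.0,
    return_dff: bool = False,
) -> NormalizedTrace:
    """Long-recording chain: motion-correct, ΔF/F₀ against the ZT baseline,
    30-min trailing mean, then z against the same baseline on the filtered
    signal.

    With ``return_dff=True`` the (unfiltered) ΔF/F₀ trace is returned instead
    of the z-scored filtered trace.
    """
    corrected = motion_correct(rec, presmooth=False)
    dff = compute_dff(corrected, baseline)
    if return_dff:
        return dff
    smoothed = replace(
        dff,
        y=trailing_mean(dff.y, dff.t, smooth_window_s),
        smoothing=f"trailing_mean({smooth_window_s / 60:.0f}min)",
    )
    return compute_zscore(smoothed, baseline)
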