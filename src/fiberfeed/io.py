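"""Reading, writing and time-base handling for photometry recordings and event logs.

Canonical interchange format is CSV (UTF-8, header row, '.' decimal):

* recordings: columns ``t_s, f_ca, f_iso`` — seconds since recording start,
  calcium-dependent (465 nm-evoked) and calcium-independent (405 nm-evoked,
  isosbestic) fluorescence in arbitrary units;
* event logs: columns ``t_s, label, value`` with labels from a closed vocabulary.

Zeitgeber time (ZT) is hours since lights-on; ZT12 is lights-off in a 12:12
cycle. A recording is anchored to ZT by ``SessionMeta.recording_start_zt``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Closed vocabulary of behavioral event labels.
EVENT_LABELS = frozenset(
    {
        "poke_left",
        "poke_right",
        "pellet_drop",
        "pellet_retrieval",
        "food_in",
        "food_out",
        "water_in",
        "contact",
        "first_bite",
        "injection",
    }
)

#: Labels counted as nose pokes (both ports are combined downstream).
POKE_LABELS = ("poke_left", "poke_right")

HOURS = 3600.0


class FormatError(ValueError):
    """A file did not match the expected tabular schema."""


class ValidationError(ValueError):
    """Data violated an invariant (non-monotone time, bad label, ...)."""


@dataclass(frozen=True)
class SessionMeta:
    """Session-level metadata anchoring a recording to the light cycle.

    Parameters
    ----------
    mouse_id : str
        Animal identifier.
    condition : str
        Free condition label, e.g. ``ad_lib``, ``fast``, ``vehicle``, ``cno``,
        ``fed``, ``fasted``, ``water_deprived``.
    recording_start_zt : float
        Zeitgeber time (hours in [0, 24)) at the first sample.
    lights_on_clock : str | None
        Local clock time of lights-on, kept for provenance only.
    acquisition_rate_label : str
        Nominal time-division-multiplexed acquisition rate ("10 Hz" or "20 Hz").
    """

    mouse_id: str = "unknown"
    condition: str = "ad_lib"
    recording_start_zt: float = 6.0
    lights_on_clock: str | None = None
    acquisition_rate_label: str = "10 Hz"

    def __post_init__(self) -> None:
        if not 0.0 <= self.recording_start_zt < 24.0:
            raise ValidationError(
                f"recording_start_zt must be in [0, 24); got {self.recording_start_zt}"
            )


@dataclass
class RawRecording:
    """Two-channel photometry trace on a common time base.

    ``t`` is seconds since recording start and must be strictly increasing;
    ``f_ca`` and ``f_iso`` are the 465 nm- and 405 nm-evoked fluorescence.
    """

    t: np.ndarray
    f_ca: np.ndarray
    f_iso: np.ndarray
    sample_rate: float
    meta: SessionMeta = field(default_factory=SessionMeta)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.f_ca = np.asarray(self.f_ca, dtype=float)
        self.f_iso = np.asarray(self.f_iso, dtype=float)
        n = len(self.t)
        if n == 0:
            raise ValidationError("recording is empty")
        if len(self.f_ca) != n or len(self.f_iso) != n:
            raise ValidationError("t, f_ca, f_iso must have equal length")
        if n > 1 and not np.all(np.diff(self.t) > 0):
            raise ValidationError("time vector must be strictly increasing")
        if not (np.all(np.isfinite(self.f_ca)) and np.all(np.isfinite(self.f_iso))):
            raise ValidationError("non-finite fluorescence after loading")
        if self.sample_rate <= 0:
            raise ValidationError(f"sample_rate must be > 0; got {self.sample_rate}")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        """Recording span in seconds."""
        return float(self.t[-1] - self.t[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_s": self.t, "f_ca": self.f_ca, "f_iso": self.f_iso})


@dataclass
class EventLog:
    """Ordered, labeled behavioral events on the recording time base."""

    frame: pd.DataFrame  # columns: t_s (float), label (str), value (object)

    def __post_init__(self) -> None:
        df = self.frame
        for col in ("t_s", "label"):
            if col not in df.columns:
                raise FormatError(f"event log missing required column '{col}'")
        if "value" not in df.columns:
            df = df.assign(value=None)
        bad = sorted(set(df["label"]) - EVENT_LABELS)
        if bad:
            raise ValidationError(
                f"unknown event label(s) {bad}; allowed: {sorted(EVENT_LABELS)}"
            )
        df = df.sort_values("t_s", kind="stable").reset_index(drop=True)
        self.frame = df[["t_s", "label", "value"]]

    def __len__(self) -> int:
        return len(self.frame)

    def times(self, labels: str | Iterable[str]) -> np.ndarray:
        """Event times (s) for one label or any of several labels."""
        if isinstance(labels, str):
            labels = (labels,)
        mask = self.frame["label"].isin(tuple(labels))
        return self.frame.loc[mask, "t_s"].to_numpy(dtype=float)

    def poke_times(self) -> np.ndarray:
        """Nose-poke times, combining both ports."""
        return self.times(POKE_LABELS)

    @classmethod
    def from_rows(cls, rows: Sequence[tuple]) -> "EventLog":
        """Build from ``(t_s, label)`` or ``(t_s, label, value)`` tuples."""
        recs = [(r[0], r[1], r[2] if len(r) > 2 else None) for r in rows]
        return cls(pd.DataFrame(recs, columns=["t_s", "label", "value"]))


# ---------------------------------------------------------------------------
# CSV codecs


def load_recording(
    path: str | Path,
    *,
    meta: SessionMeta | None = None,
    sample_rate: float | None = None,
) -> RawRecording:
    """Load a recording CSV (columns ``t_s, f_ca, f_iso``).

    Rows with non-finite fluorescence are dropped (with a logged count) rather
    than interpolated. The sample rate is inferred from the median time step
    when not given.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    for col in ("t_s", "f_ca", "f_iso"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    finite = np.isfinite(df["f_ca"]) & np.isfinite(df["f_iso"]) & np.isfinite(df["t_s"])
    n_dropped = int((~finite).sum())
    if n_dropped:
        logger.warning("%s: dropped %d row(s) with non-finite values", path, n_dropped)
        df = df[finite]
    t = df["t_s"].to_numpy(dtype=float)
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise ValidationError(f"{path}: time column is not strictly increasing")
    if sample_rate is None:
        sample_rate = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 1.0
    return RawRecording(
        t=t,
        f_ca=df["f_ca"].to_numpy(dtype=float),
        f_iso=df["f_iso"].to_numpy(dtype=float),
        sample_rate=sample_rate,
        meta=meta or SessionMeta(),
    )


def save_recording(rec: RawRecording, path: str | Path) -> None:
    """Write a recording to its canonical CSV form."""
    rec.to_frame().to_csv(Path(path), index=False)


def load_events(path: str | Path) -> EventLog:
    """Load an event-log CSV (columns ``t_s, label[, value]``).

    Labels outside the closed vocabulary are rejected; rows are stably sorted
    by time.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    return EventLog(df)


def save_events(log: EventLog, path: str | Path) -> None:
    log.frame.to_csv(Path(path), index=False)


# ---------------------------------------------------------------------------
# Zeitgeber-time conversion


def zt_of_seconds(t_s: np.ndarray | float, meta: SessionMeta) -> np.ndarray | float:
    """ZT hours at recording second(s) ``t_s``: ``(start_zt + t/3600) mod 24``."""
    return (meta.recording_start_zt + np.asarray(t_s, dtype=float) / HOURS) % 24.0


def seconds_of_zt(zt: float, meta: SessionMeta) -> float:
    """Recording second of the first occurrence of ``zt`` at/after the start."""
    return ((zt - meta.recording_start_zt) % 24.0) * HOURS


def zt_window_to_seconds(
    window: tuple[float, float],
    meta: SessionMeta,
    duration_s: float,
    *,
    clip: bool = True,
) -> tuple[float, float]:
    """Resolve a ZT window to recording seconds, handling midnight wrap.

    A window ``(start, end)`` with ``end <= start`` wraps midnight (e.g. the
    ZT12–ZT2 fast window spans 14 h). The window resolves to its first
    occurrence at or after recording start; an error is raised if it lies
    entirely outside the recording.
    """
    z0, z1 = window
    t0 = seconds_of_zt(z0, meta)
    span = ((z1 - z0) % 24.0) * HOURS
    if span == 0.0:
        span = 24.0 * HOURS
    t1 = t0 + span
    if t0 >= duration_s:
        raise ValidationError(
            f"ZT window {window} starts at t={t0 / HOURS:.2f} h, "
            f"outside the {duration_s / HOURS:.2f} h recording"
        )
    if clip and t1 > duration_s:
        t1 = duration_s
    return t0, t1
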