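"""End-to-end orchestration: simulate → preprocess → analyze → report.

A run is described by a :class:`RunConfig` (YAML/JSON-friendly); outputs are
CSV tables plus a ``manifest.json`` recording the package version, the seed,
a hash of the canonical config, and per-stage row counts. Runs are
deterministic given (inputs, seed): the manifest carries no timestamps, so
two runs of the same config produce byte-identical outputs.

All of the analysis constants (45-s refractory, 30-min windows, the 0.638
threshold, Gaussian window=7/sigma=1) are surfaced as config keys with the
standard values as defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import (
    EventLog,
    RawRecording,
    ValidationError,
    load_events,
    load_recording,
    zt_window_to_seconds,
)
from .preprocess import (
    LONGTERM_BASELINE,
    TRIAL_BASELINE,
    BaselineSpec,
    preprocess_longterm,
    preprocess_trial,
)
from .events import align_to_events, decile_split, poke_rate, refractory_filter
from .metrics import (
    DEFAULT_THRESHOLD_FRACTION,
    fall_tau,
    hourly_zt_bins,
    pellet_windows,
    rise_tau,
    window_means,
)
from .synthetic import write_fixture_suite

logger = logging.getLogger(__name__)

MODES = ("simulate", "food_response", "longterm", "operant", "contrast")


@dataclass
class RunConfig:
    """Configuration for one pipeline run (schema version 1)."""

    mode: str
    out_dir: str
    seed: int = 0
    # input discovery: a fixture-suite style directory of session folders,
    # each holding recording.csv + events.csv
    input_dir: str | None = None
    # or explicit single-session inputs
    recording: str | None = None
    events: str | None = None
    # contrast mode: two tau-report CSVs
    report_a: str | None = None
    report_b: str | None = None
    # simulate mode
    n_mice: int = 2
    sim_duration_h: float = 13.0
    sim_sample_rate: float = 5.0
    # analysis constants (standard values as defaults)
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION
    refractory_s: float = 45.0
    poke_pre_s: float = 45.0
    poke_post_s: float = 100.0
    rate_window_min: float = 30.0
    smooth_window_min: float = 30.0
    fast_window_zt: tuple[float, float] = (12.0, 2.0)
    schema_version: int = 1

    def validate(self) -> None:
        if self.mode not in MODES:
            raise ValidationError(f"mode must be one of {MODES}; got {self.mode!r}")
        needs = {
            "food_response": ("input_dir", "recording"),
            "longterm": ("input_dir", "recording"),
            "operant": ("input_dir", "events"),
        }
        if self.mode in needs and all(getattr(self, k) is None for k in needs[self.mode]):
            raise ValidationError(
                f"mode '{self.mode}' needs one of {needs[self.mode]} set"
            )
        if self.mode == "contrast" and (self.report_a is None or self.report_b is None):
            raise ValidationError("contrast mode needs report_a and report_b")

    def canonical_json(self) -> str:
        d = dataclasses.asdict(self)
        d["fast_window_zt"] = list(d["fast_window_zt"])
        return json.dumps(d, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "fast_window_zt" in d:
            d["fast_window_zt"] = tuple(d["fast_window_zt"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _session_dirs(cfg: RunConfig) -> list[tuple[str, Path | None, Path | None]]:
    """Yield (session_name, recording_path, events_path) for the run inputs."""
    out: list[tuple[str, Path | None, Path | None]] = []
    if cfg.input_dir is not None:
        root = Path(cfg.input_dir)
        if not root.is_dir():
            raise ValidationError(f"input_dir does not exist: {root}")
        for sdir in sorted(p for p in root.iterdir() if p.is_dir()):
            rec = sdir / "recording.csv"
            ev = sdir / "events.csv"
            out.append(
                (sdir.name, rec if rec.exists() else None, ev if ev.exists() else None)
            )
    else:
        rec = Path(cfg.recording) if cfg.recording else None
        ev = Path(cfg.events) if cfg.events else None
        name = rec.stem if rec is not None else (ev.stem if ev else "session")
        out.append((name, rec, ev))
    if not out:
        raise ValidationError(f"no session directories found under {cfg.input_dir}")
    return out


def _require_file(path: Path | None, what: str, session: str) -> Path:
    if path is None or not path.exists():
        raise ValidationError(f"session '{session}': missing {what} file ({path})")
    return path


def _load_session(name: str, rec_path: Path | None, ev_path: Path | None, *, need_events: bool):
    rec = load_recording(_require_file(rec_path, "recording", name))
    meta = rec.meta
    # recover meta from the ground-truth sidecar when present
    sidecar = rec_path.with_name("truth.json")
    if sidecar.exists():
        truth = json.loads(sidecar.read_text())
        condition = {
            "ad_lib": "ad_lib", "fast": "fast", "food_presentation_trial": "fasted",
        }.get(truth.get("schedule"), meta.condition)
        meta = dataclasses.replace(
            meta,
            mouse_id=rec_path.parent.name.split("_")[0],
            condition=condition,
            recording_start_zt=float(truth.get("start_zt", meta.recording_start_zt)),
        )
        rec = RawRecording(rec.t, rec.f_ca, rec.f_iso, rec.sample_rate, meta)
    ev = None
    if ev_path is not None and ev_path.exists():
        ev = load_events(ev_path)
    elif need_events:
        raise ValidationError(f"session '{name}': missing events file ({ev_path})")
    return rec, ev


# ---------------------------------------------------------------------------
# stages


def _stage_food_response(cfg: RunConfig, out: Path) -> dict[str, int]:
    from .events import phase_means_from_log

    rows, phase_rows = [], []
    for name, rec_path, ev_path in _session_dirs(cfg):
        if rec_path is None:
            continue
        rec, ev = _load_session(name, rec_path, ev_path, need_events=True)
        if rec.duration > 2 * 3600.0:
            logger.info("session %s: longer than a short trial; skipped", name)
            continue
        drops = ev.times("pellet_drop")
        if len(drops) == 0:
            logger.warning("session %s: no pellet_drop event; skipped", name)
            continue
        drop = float(drops[0])
        z = preprocess_trial(rec, drop)
        est = fall_tau(z, drop, threshold_fraction=cfg.threshold_fraction)
        wm = window_means(z, pellet_windows(drop))
        rows.append(
            {
                "session": name,
                "mouse_id": rec.meta.mouse_id,
                "condition": rec.meta.condition,
                "tau_s": est.tau,
                "valid": est.valid,
                "extremum_z": est.extremum_value,
                **{f"mean_{k}": v for k, v in wm.items()},
            }
        )
        # feeding phases are summarized on dF/F0 (not z)
        from .preprocess import compute_dff, motion_correct

        dff_trace = compute_dff(motion_correct(rec, presmooth=True), TRIAL_BASELINE,
                                event_time=drop)
        try:
            pm = phase_means_from_log(dff_trace, ev)
            phase_rows.append({"session": name, "mouse_id": rec.meta.mouse_id, **pm})
        except ValidationError:
            pass
    if not rows:
        raise ValidationError("food_response: no usable sessions")
    tau_df = pd.DataFrame(rows).sort_values("session")
    tau_df.to_csv(out / "food_response_tau.csv", index=False)
    counts = {"food_response_tau": len(tau_df)}
    if phase_rows:
        pdf = pd.DataFrame(phase_rows).sort_values("session")
        pdf.to_csv(out / "feeding_phase_means.csv", index=False)
        counts["feeding_phase_means"] = len(pdf)
    return counts


def _stage_longterm(cfg: RunConfig, out: Path) -> dict[str, int]:
    rows, bin_rows = [], []
    for name, rec_path, ev_path in _session_dirs(cfg):
        if rec_path is None:
            continue
        rec, _ = _load_session(name, rec_path, ev_path, need_events=False)
        if rec.duration < 2 * 3600.0:
            logger.info("session %s: too short for long-term analysis; skipped", name)
            continue
        z = preprocess_longterm(rec, smooth_window_s=cfg.smooth_window_min * 60.0)
        bins = hourly_zt_bins(z)
        bin_rows.append(
            {"session": name, "mouse_id": rec.meta.mouse_id,
             "condition": rec.meta.condition, **bins}
        )
        if rec.meta.condition == "fast":
            try:
                est = rise_tau(z, threshold_fraction=cfg.threshold_fraction)
            except ValidationError as err:
                logger.warning("session %s: rise tau unavailable (%s)", name, err)
                continue
            rows.append(
                {
                    "session": name,
                    "mouse_id": rec.meta.mouse_id,
                    "condition": rec.meta.condition,
                    "tau_h": est.tau,
                    "valid": est.valid,
                    "extremum_z": est.extremum_value,
                }
            )
    if not bin_rows:
        raise ValidationError("longterm: no usable sessions")
    pd.DataFrame(bin_rows).sort_values("session").to_csv(
        out / "hourly_bins.csv", index=False
    )
    counts = {"hourly_bins": len(bin_rows)}
    if rows:
        pd.DataFrame(rows).sort_values("session").to_csv(
            out / "rise_tau.csv", index=False
        )
        counts["rise_tau"] = len(rows)
    return counts


def _stage_operant(cfg: RunConfig, out: Path) -> dict[str, int]:
    rate_rows, aligned_rows, decile_rows = [], [], []
    for name, rec_path, ev_path in _session_dirs(cfg):
        if ev_path is None:
            continue
        ev = load_events(ev_path)
        rec = None
        if rec_path is not None and rec_path.exists():
            rec, _ = _load_session(name, rec_path, ev_path, need_events=False)
        pokes = ev.poke_times()
        if len(pokes) == 0:
            logger.warning("session %s: no pokes; skipped", name)
            continue
        span = (0.0, float(pokes.max()) if rec is None else float(rec.t[-1]))
        grid, rate = poke_rate(ev, window_min=cfg.rate_window_min, session_span=span)
        for g, r in zip(grid, rate):
            rate_rows.append({"session": name, "t_s": g, "pokes_per_min": r})
        if rec is None:
            continue
        meta = rec.meta
        try:
            f0, f1 = zt_window_to_seconds(cfg.fast_window_zt, meta, float(rec.t[-1]))
        except ValidationError:
            continue
        fast_pokes = pokes[(pokes > f0) & (pokes <= f1)]
        kept = refractory_filter(fast_pokes, cfg.refractory_s)
        from .preprocess import motion_correct

        corrected = motion_correct(rec, presmooth=True)
        aligned = align_to_events(
            corrected, kept, pre_s=cfg.poke_pre_s, post_s=cfg.poke_post_s,
            mouse_id=meta.mouse_id,
        )
        if len(aligned) == 0:
            continue
        mean = aligned.mean()
        for rt, zv in zip(aligned.rel_t, mean):
            aligned_rows.append(
                {"session": name, "mouse_id": meta.mouse_id, "rel_t": rt, "z": zv}
            )
        if len(aligned) >= 10:
            split = decile_split(aligned)
            for d in split.presented_deciles:
                if d not in split.mean_traces:
                    continue
                for rt, zv in zip(split.rel_t, split.mean_traces[d]):
                    decile_rows.append(
                        {"session": name, "decile": d, "rel_t": rt, "z": zv}
                    )
    if not rate_rows:
        raise ValidationError("operant: no usable sessions")
    counts = {}
    pd.DataFrame(rate_rows).to_csv(out / "poke_rate.csv", index=False)
    counts["poke_rate"] = len(rate_rows)
    if aligned_rows:
        pd.DataFrame(aligned_rows).to_csv(out / "poke_aligned.csv", index=False)
        counts["poke_aligned"] = len(aligned_rows)
    if decile_rows:
        pd.DataFrame(decile_rows).to_csv(out / "poke_deciles.csv", index=False)
        counts["poke_deciles"] = len(decile_rows)
    return counts


def _stage_contrast(cfg: RunConfig, out: Path) -> dict[str, int]:
    from .metrics import condition_contrast

    def read_taus(path: str) -> dict[str, float]:
        p = Path(path)
        if not p.exists():
            raise ValidationError(f"contrast: missing report file {p}")
        df = pd.read_csv(p)
        col = "tau_h" if "tau_h" in df.columns else "tau_s"
        df = df[df.get("valid", True) == True]  # noqa: E712
        return df.groupby("mouse_id")[col].mean().to_dict()

    a = read_taus(cfg.report_a)
    b = read_taus(cfg.report_b)
    diffs, mean, sem = condition_contrast(a, b)
    df = pd.DataFrame(
        [{"mouse_id": m, "delta_tau": d} for m, d in sorted(diffs.items())]
    )
    df.to_csv(out / "contrast.csv", index=False)
    summary = pd.DataFrame([{"mean_delta_tau": mean, "sem_delta_tau": sem,
                             "n_mice": len(diffs)}])
    summary.to_csv(out / "contrast_summary.csv", index=False)
    return {"contrast": len(df)}


def run_pipeline(config: RunConfig) -> Path:
    """Execute one pipeline run; returns the output directory.

    Any stage failure aborts with the stage name and the offending input in
    the error message. Outputs are deterministic given (inputs, seed).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    try:
        if config.mode == "simulate":
            written = write_fixture_suite(
                out / "sessions", config.seed, n_mice=config.n_mice,
                long_duration_h=config.sim_duration_h,
                long_sample_rate=config.sim_sample_rate,
            )
            counts["sessions"] = len(written)
        elif config.mode == "food_response":
            counts.update(_stage_food_response(config, out))
        elif config.mode == "longterm":
            counts.update(_stage_longterm(config, out))
        elif config.mode == "operant":
            counts.update(_stage_operant(config, out))
        elif config.mode == "contrast":
            counts.update(_stage_contrast(config, out))
    except (ValidationError, FileNotFoundError) as err:
        raise ValidationError(f"stage '{config.mode}' failed: {err}") from err

    manifest = {
        "package": "fiberfeed",
        "version": __version__,
        "seed": config.seed,
        "config": json.loads(config.canonical_json()),
        "config_hash": config.config_hash(),
        "row_counts": counts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
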