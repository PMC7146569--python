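"""Recording readers/writers, configuration files, and the pipeline driver.

Recordings travel as columnar CSV (t, ppg, ax, ay, az), NPZ archives, or the
per-subject PPG-DaLia pickle layout (wrist blood-volume-pulse channel, wrist
3-axis accelerometer, ground-truth HR on a 2-second grid).  All timestamps
are seconds; samples are indexed 0-based internally.
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .conditioning import ConditioningConfig, LimiterBounds
from .evaluate import EvaluationResult, mae
from .hr import HREstimate, HRParams, PipelineConfig, sliding_hr
from .motion import AccelSequence, MotionParams, resample_accel
from .synth import SynthRecording

__all__ = [
    "Recording",
    "read_recording",
    "write_recording",
    "recording_from_synth",
    "write_estimates_csv",
    "read_estimates_csv",
    "load_config",
    "save_config",
    "run_pipeline",
]

logger = logging.getLogger("tdhr")

# Gravity-to-counts scale of the PPG-DaLia wrist accelerometer channel
# (values there are already in g after the published conversion; raw-count
# layouts declare their own scale in the manifest).
_DALIA_PPG_FS = 64.0
_DALIA_ACC_FS = 32.0


class FormatError(ValueError):
    """Unknown or malformed recording container."""


class MissingChannelError(ValueError):
    """A required channel is absent from the container."""


@dataclass
class Recording:
    """A PPG + accelerometer recording on a common clock."""

    ppg: np.ndarray
    fs: float
    acc: AccelSequence | None = None
    truth_hr_t: np.ndarray | None = None
    truth_hr_bpm: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ppg = np.asarray(self.ppg, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.acc is not None and len(self.acc) != len(self.ppg):
            raise ValueError("accelerometer not aligned to PPG")


def recording_from_synth(rec: SynthRecording, meta: dict | None = None) -> Recording:
    return Recording(
        ppg=rec.ppg.astype(float), fs=rec.fs, acc=rec.acc,
        truth_hr_t=rec.truth_hr_t, truth_hr_bpm=rec.truth_hr_bpm,
        meta=dict(meta or {}, source="synthetic"),
    )


def _read_csv(path: Path, fs: float | None) -> Recording:
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    if "ppg" not in df.columns:
        raise MissingChannelError(f"{path}: no 'ppg' column")
    if fs is None:
        if "t" not in df.columns or len(df) < 2:
            raise FormatError(f"{path}: need a 't' column (or explicit fs)")
        fs = 1.0 / float(np.median(np.diff(df["t"].to_numpy())))
    acc = None
    if {"ax", "ay", "az"} <= set(df.columns):
        acc = AccelSequence(
            gx=df["ax"].to_numpy(float),
            gy=df["ay"].to_numpy(float),
            gz=df["az"].to_numpy(float),
        )
    elif {"ax", "ay", "az"} & set(df.columns):
        raise MissingChannelError(f"{path}: partial accelerometer columns")
    return Recording(ppg=df["ppg"].to_numpy(float), fs=fs, acc=acc,
                     meta={"source": str(path)})


def _read_npz(path: Path) -> Recording:
    data = np.load(path, allow_pickle=False)
    if "ppg" not in data:
        raise MissingChannelError(f"{path}: no 'ppg' array")
    fs = float(data["fs"]) if "fs" in data else 32.0
    acc = None
    if all(k in data for k in ("ax", "ay", "az")):
        fr = float(data["accel_full_range"]) if "accel_full_range" in data else 2.0
        acc = AccelSequence(gx=data["ax"], gy=data["ay"], gz=data["az"], full_range=fr)
    truth_t = data["truth_hr_t"] if "truth_hr_t" in data else None
    truth_bpm = data["truth_hr_bpm"] if "truth_hr_bpm" in data else None
    return Recording(ppg=data["ppg"].astype(float), fs=fs, acc=acc,
                     truth_hr_t=truth_t, truth_hr_bpm=truth_bpm,
                     meta={"source": str(path)})


def _read_dalia(path: Path, target_fs: float = 32.0) -> Recording:
    """Map a PPG-DaLia per-subject pickle onto the common model.

    Layout: ``signal.wrist.BVP`` at 64 Hz, ``signal.wrist.ACC`` (3 columns,
    32 Hz, g), ``label`` = ground-truth HR every 2 s.  The BVP channel is
    decimated and the accelerometer held onto the target timebase.
    """
    with open(path, "rb") as fh:
        raw: dict[str, Any] = pickle.load(fh, encoding="latin1")
    try:
        wrist = raw["signal"]["wrist"]
        bvp = np.asarray(wrist["BVP"], dtype=float).ravel()
        acc_arr = np.asarray(wrist["ACC"], dtype=float)
    except KeyError as exc:
        raise MissingChannelError(f"{path}: missing wrist channel {exc}") from exc
    step = int(round(_DALIA_PPG_FS / target_fs))
    ppg = bvp[::step]
    acc = AccelSequence(gx=acc_arr[:, 0], gy=acc_arr[:, 1], gz=acc_arr[:, 2])
    acc = resample_accel(acc, _DALIA_ACC_FS, target_fs, len(ppg))
    truth_t = truth_bpm = None
    if "label" in raw:
        truth_bpm = np.asarray(raw["label"], dtype=float).ravel()
        # labels cover 8 s windows shifted by 2 s; stamp at each window end
        truth_t = 8.0 + 2.0 * np.arange(truth_bpm.size)
    return Recording(ppg=ppg, fs=target_fs, acc=acc,
                     truth_hr_t=truth_t, truth_hr_bpm=truth_bpm,
                     meta={"source": str(path), "subject": path.stem})


def read_recording(path: str | Path, format: str | None = None,
                   fs: float | None = None) -> Recording:
    """Load a recording; format inferred from the suffix when not given."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = {".csv": "csv", ".npz": "npz", ".pkl": "dalia"}.get(path.suffix)
    if format == "csv":
        return _read_csv(path, fs)
    if format == "npz":
        return _read_npz(path)
    if format == "dalia":
        return _read_dalia(path)
    raise FormatError(f"unknown recording format {format!r} for {path}")


def write_recording(rec: Recording, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = {".csv": "csv", ".npz": "npz"}.get(path.suffix)
    t = np.arange(len(rec.ppg)) / rec.fs
    if format == "csv":
        cols = {"t": t, "ppg": rec.ppg}
        if rec.acc is not None:
            cols.update(ax=rec.acc.gx, ay=rec.acc.gy, az=rec.acc.gz)
        pd.DataFrame(cols).to_csv(path, index=False)
    elif format == "npz":
        arrays: dict[str, np.ndarray] = {"ppg": rec.ppg, "fs": np.asarray(rec.fs)}
        if rec.acc is not None:
            arrays.update(ax=rec.acc.gx, ay=rec.acc.gy, az=rec.acc.gz,
                          accel_full_range=np.asarray(rec.acc.full_range))
        if rec.truth_hr_t is not None:
            arrays.update(truth_hr_t=rec.truth_hr_t, truth_hr_bpm=rec.truth_hr_bpm)
        np.savez(path, **arrays)
    else:
        raise FormatError(f"unknown output format {format!r}")


def write_estimates_csv(estimates: list[HREstimate], path: str | Path) -> None:
    pd.DataFrame(
        {
            "t_s": [e.t for e in estimates],
            "bpm": [e.bpm for e in estimates],
            "valid": [int(e.valid) for e in estimates],
            "n_peaks": [e.n_peaks for e in estimates],
            "n_valid_periods": [e.n_valid_periods for e in estimates],
            "reason": [e.reason for e in estimates],
        }
    ).to_csv(path, index=False)


def read_estimates_csv(path: str | Path) -> list[HREstimate]:
    df = pd.read_csv(path, keep_default_na=False)
    return [
        HREstimate(t=float(r.t_s), bpm=float(r.bpm), valid=bool(r.valid),
                   n_peaks=int(r.n_peaks), n_valid_periods=int(r.n_valid_periods),
                   reason=str(r.reason))
        for r in df.itertuples()
    ]


def load_config(path: str | Path) -> PipelineConfig:
    """Build a pipeline configuration from a YAML file.

    Every algorithm constant is a named key with its standard value as the
    default: fs, passband, limiter bounds, lambda_max, H, Ts, BPM_min, N,
    shift.  Missing keys keep defaults; unknown keys are rejected.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {
        "fs", "passband_low", "passband_high", "limiter_low", "limiter_high",
        "lambda_max", "flat_peak_rule", "limiter_auto", "h", "ts_ms", "g_norm",
        "spike_mode", "bpm_min", "n", "shift_s",
    }
    unknown = set(data) - known
    if unknown:
        raise FormatError(f"unknown config keys: {sorted(unknown)}")
    fs = float(data.get("fs", 32.0))
    cond = ConditioningConfig(
        fs=fs,
        passband_low=float(data.get("passband_low", 0.5)),
        passband_high=float(data.get("passband_high", 2.5)),
        limiter=LimiterBounds(
            float(data.get("limiter_low", -150.0)),
            float(data.get("limiter_high", 150.0)),
        ),
    )
    motion = MotionParams(
        g_norm=(float(data["g_norm"]) if "g_norm" in data else None),
        h=float(data.get("h", 0.0025)),
        ts_ms=float(data.get("ts_ms", 500.0)),
        spike_mode=str(data.get("spike_mode", "remove-short")),
    )
    hrp = HRParams(
        fs=fs,
        n=int(data.get("n", 1024)),
        bpm_min=float(data.get("bpm_min", 40.0)),
        shift_s=float(data.get("shift_s", 2.0)),
    )
    return PipelineConfig(
        conditioning=cond, motion=motion, hr=hrp,
        lambda_max=int(data.get("lambda_max", 17)),
        enable_flat_peak_rule=bool(data.get("flat_peak_rule", True)),
        limiter_auto=bool(data.get("limiter_auto", False)),
    )


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    data = {
        "fs": cfg.hr.fs,
        "passband_low": cfg.conditioning.passband_low,
        "passband_high": cfg.conditioning.passband_high,
        "limiter_low": cfg.conditioning.limiter.lower,
        "limiter_high": cfg.conditioning.limiter.upper,
        "lambda_max": cfg.lambda_max,
        "flat_peak_rule": cfg.enable_flat_peak_rule,
        "limiter_auto": cfg.limiter_auto,
        "h": cfg.motion.h,
        "ts_ms": cfg.motion.ts_ms,
        "spike_mode": cfg.motion.spike_mode,
        "bpm_min": cfg.hr.bpm_min,
        "n": cfg.hr.n,
        "shift_s": cfg.hr.shift_s,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def run_pipeline(
    rec: Recording, cfg: PipelineConfig | None = None, mode: str = "valid-only"
) -> tuple[list[HREstimate], EvaluationResult | None]:
    """Full dataflow: conditioning, sliding HR, optional scoring.

    The evaluation is computed only when the recording carries a reference
    HR series.  Fully deterministic: two runs on the same inputs and
    configuration produce identical outputs.
    """
    cfg = cfg or PipelineConfig()
    if cfg.hr.fs != rec.fs:
        cfg = replace(cfg, hr=replace(cfg.hr, fs=rec.fs))
    estimates = sliding_hr(rec.ppg, rec.acc, cfg)
    result = None
    if estimates and rec.truth_hr_t is not None and rec.truth_hr_bpm is not None:
        result = mae(estimates, rec.truth_hr_t, rec.truth_hr_bpm, mode=mode)
    return estimates, result
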