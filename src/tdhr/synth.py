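"""Synthetic wrist PPG + accelerometer recordings with known ground truth.

The generator emulates the raw signal class the pipeline is built for: a
weak quasi-periodic pulse train (amplitude a few tens of counts) riding on a
large baseline (about 11,100 counts at 14-bit resolution), with random-walk
baseline wander, white sensor noise, and optional motion-artifact bursts
that hit the PPG channel and the accelerometer simultaneously.  Beat times
are the ground truth; a reference HR series on a 2-second grid is derived
from them for the evaluator.

It does not model optics or hemodynamics: pulse morphology is a fixed
asymmetric bump (fast systolic rise, slow decay), so green tests establish
that the pipeline recovers beat timing from signals of realistic amplitude,
bandwidth and disturbance structure — not that it handles every real-world
morphology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .motion import AccelSequence

__all__ = ["ArtifactBurst", "SynthConfig", "SynthRecording", "generate"]

ADC_MAX = 2**14 - 1  # 14-bit converter

# Pulse template: log-normal bump, mode (systolic rise) at 0.15 s and decay
# tail about 0.35 s for a 1 s beat; scaled with the instantaneous period.
_TEMPLATE_RISE_FRAC = 0.15
_TEMPLATE_SHAPE = 0.45


@dataclass(frozen=True)
class ArtifactBurst:
    """A motion event: simultaneous PPG transient and accelerometer burst."""

    start_s: float
    duration_s: float
    ppg_magnitude: float = 3000.0  # counts
    accel_magnitude: float = 0.5   # g


@dataclass(frozen=True)
class SynthConfig:
    """Stated world of the generator.

    ``hr`` may be a constant bpm, a callable t -> bpm, or a piecewise-
    constant list of (start_s, bpm) segments; rates must stay in [40, 180].
    Defaults mirror a wrist recording: baseline 11,100 counts, pulse
    amplitude 40 counts, 1 count of white noise and a gentle random-walk
    drift, 2 % beat-to-beat jitter.
    """

    fs: float = 32.0
    duration_s: float = 60.0
    hr: float | Callable[[float], float] | Sequence[tuple[float, float]] = 75.0
    baseline: float = 11100.0
    pulse_amplitude: float = 40.0
    noise_sd: float = 1.0
    drift_sd: float = 0.5
    jitter_frac: float = 0.02
    artifact_bursts: tuple[ArtifactBurst, ...] = ()
    accel_noise_sd: float = 0.002  # g, per axis
    accel_full_range: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration_s <= 0 or self.pulse_amplitude <= 0:
            raise ValueError("fs, duration and pulse amplitude must be positive")
        for b in self.artifact_bursts:
            if not (0 <= b.start_s and b.start_s + b.duration_s <= self.duration_s):
                raise ValueError("artifact burst outside the recording")

    def hr_at(self, t: float) -> float:
        if callable(self.hr):
            bpm = float(self.hr(t))
        elif isinstance(self.hr, (int, float)):
            bpm = float(self.hr)
        else:
            bpm = float(self.hr[0][1])
            for start, value in self.hr:
                if t >= start:
                    bpm = float(value)
        if not (40.0 <= bpm <= 180.0):
            raise ValueError(f"heart rate {bpm} bpm outside the supported [40, 180]")
        return bpm


@dataclass
class SynthRecording:
    """Generated recording plus its ground truth."""

    ppg: np.ndarray            # integer counts in [0, 16383]
    acc: AccelSequence
    fs: float
    truth_hr_t: np.ndarray     # 2-second grid, s
    truth_hr_bpm: np.ndarray
    truth_peaks: np.ndarray    # beat times, s

    def __len__(self) -> int:
        return len(self.ppg)


def _tukey(n: int, alpha: float) -> np.ndarray:
    """Tapered-cosine envelope (flat top, cosine ramps of alpha/2 each side)."""
    from scipy.signal import windows

    return windows.tukey(n, alpha=alpha)


def _pulse_template(phase: np.ndarray) -> np.ndarray:
    """Unimodal asymmetric bump on phase in (0, 1], normalised to max 1."""
    out = np.zeros_like(phase)
    pos = phase > 0
    mu = np.log(_TEMPLATE_RISE_FRAC) + _TEMPLATE_SHAPE**2
    z = (np.log(phase[pos]) - mu) / _TEMPLATE_SHAPE
    out[pos] = np.exp(-0.5 * z * z)
    return out


def generate(cfg: SynthConfig) -> SynthRecording:
    """Generate one recording, deterministically per seed."""
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.fs))
    t = np.arange(n) / cfg.fs

    # Beat times: integrate the HR trajectory with per-beat jitter.
    beats = []
    tb = 0.0
    while tb < cfg.duration_s:
        beats.append(tb)
        period = 60.0 / cfg.hr_at(tb)
        if cfg.jitter_frac > 0:
            period *= 1.0 + cfg.jitter_frac * rng.standard_normal()
        tb += max(period, 60.0 / 220.0)
    truth_peaks = np.asarray(beats)

    # Pulse train: each beat contributes one template bump over its period.
    ppg = np.zeros(n, dtype=float)
    bounds = np.concatenate([truth_peaks, [cfg.duration_s + 1.0]])
    for b, (t0, t1) in enumerate(zip(bounds[:-1], bounds[1:])):
        i0 = int(np.ceil(t0 * cfg.fs))
        i1 = min(int(np.ceil(t1 * cfg.fs)), n)
        if i0 >= i1:
            continue
        phase = (t[i0:i1] - t0) / (t1 - t0)
        ppg[i0:i1] += cfg.pulse_amplitude * _pulse_template(phase)

    ppg += cfg.baseline
    if cfg.drift_sd > 0:
        ppg += np.cumsum(rng.normal(0.0, cfg.drift_sd, size=n))
    if cfg.noise_sd > 0:
        ppg += rng.normal(0.0, cfg.noise_sd, size=n)

    # Accelerometer at rest: gravity on Z plus sensor noise.
    gx = rng.normal(0.0, cfg.accel_noise_sd, size=n)
    gy = rng.normal(0.0, cfg.accel_noise_sd, size=n)
    gz = 1.0 + rng.normal(0.0, cfg.accel_noise_sd, size=n)

    for burst in cfg.artifact_bursts:
        i0 = int(round(burst.start_s * cfg.fs))
        i1 = min(int(round((burst.start_s + burst.duration_s) * cfg.fs)), n)
        if i0 >= i1:
            continue
        tt = t[i0:i1] - burst.start_s
        envelope = _tukey(i1 - i0, alpha=0.2)  # fast onset, short tapers
        wobble = 0.6 * np.sin(2 * np.pi * 1.7 * tt) + 0.4 * np.sin(2 * np.pi * 3.1 * tt)
        ppg[i0:i1] += burst.ppg_magnitude * envelope * wobble
        # jerky broadband shake: smoothed white noise, unit-ish amplitude
        for axis in (gx, gy, gz):
            raw = rng.standard_normal(i1 - i0 + 8)
            kernel = np.hanning(9)
            shake = np.convolve(raw, kernel / kernel.sum(), mode="valid")
            shake = shake / max(np.abs(shake).max(), 1e-9)
            axis[i0:i1] += burst.accel_magnitude * envelope * shake

    ppg = np.clip(np.round(ppg), 0, ADC_MAX).astype(np.int64)
    fr = cfg.accel_full_range
    acc = AccelSequence(
        gx=np.clip(gx, -fr, fr), gy=np.clip(gy, -fr, fr), gz=np.clip(gz, -fr, fr),
        full_range=fr,
    )

    # Reference HR on the 2 s grid: rate implied by the beats nearest each
    # grid point (mean instantaneous rate over a centred 4 s neighbourhood).
    grid = np.arange(2.0, cfg.duration_s + 1e-9, 2.0)
    inst_t = 0.5 * (truth_peaks[1:] + truth_peaks[:-1])
    inst_bpm = 60.0 / np.diff(truth_peaks)
    truth_bpm = np.empty_like(grid)
    for i, g in enumerate(grid):
        near = np.abs(inst_t - g) <= 2.0
        truth_bpm[i] = inst_bpm[near].mean() if near.any() else np.interp(g, inst_t, inst_bpm)
    return SynthRecording(
        ppg=ppg, acc=acc, fs=cfg.fs,
        truth_hr_t=grid, truth_hr_bpm=truth_bpm, truth_peaks=truth_peaks,
    )
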