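"""Accelerometer-based motion masking.

Wrist motion displaces the optical sensor and perturbs tissue blood volume,
corrupting the PPG waveform.  The 3-axis accelerometer is differenced into a
normalised movement indicator d in [0, 1], thresholded into a binary flag
sequence, debounced in time, and used to discard inter-peak periods that
overlap flagged samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "AccelSequence",
    "MotionParams",
    "MotionMask",
    "movement_indicator",
    "threshold_and_despike",
    "exclude_periods",
    "resample_accel",
]

DEFAULT_FULL_RANGE_G = 2.0  # accelerometer configured for +/-2 g
DEFAULT_H = 0.0025          # movement threshold on d, for the +/-2 g range
DEFAULT_TS_MS = 500.0       # spike duration for the time filter


@dataclass
class AccelSequence:
    """Synchronized 3-axis acceleration, one sample per PPG sample.

    Values are in g; ``full_range`` is the configured measuring range
    (+/-full_range g), which fixes the normalisation of the movement
    indicator.
    """

    gx: np.ndarray
    gy: np.ndarray
    gz: np.ndarray
    full_range: float = DEFAULT_FULL_RANGE_G

    def __post_init__(self) -> None:
        self.gx = np.asarray(self.gx, dtype=float)
        self.gy = np.asarray(self.gy, dtype=float)
        self.gz = np.asarray(self.gz, dtype=float)
        if not (len(self.gx) == len(self.gy) == len(self.gz)):
            raise ValueError("accelerometer axes must have equal lengths")
        if self.full_range <= 0:
            raise ValueError("full_range must be positive")

    def __len__(self) -> int:
        return len(self.gx)


@dataclass(frozen=True)
class MotionParams:
    """Normalisation, threshold and time-filter settings.

    ``g_norm`` scales the differenced acceleration norm into [0, 1]; when
    None it is derived from the accelerometer full range as the largest
    possible single-step change, a rail-to-rail jump on all three axes at
    once: 2 * full_range * sqrt(3).  ``h`` is the movement threshold on the
    indicator and ``ts_ms`` the duration of the time filter; the defaults
    (0.0025 and 500 ms) are tuned for the +/-2 g range.

    ``spike_mode`` selects the time-filter direction: "remove-short" (the
    default) zeroes movement runs strictly shorter than ``ts_ms`` — a
    debounce that ignores single jolts; "remove-long" zeroes runs strictly
    longer than ``ts_ms`` instead.
    """

    g_norm: float | None = None
    h: float = DEFAULT_H
    ts_ms: float = DEFAULT_TS_MS
    spike_mode: str = "remove-short"

    def __post_init__(self) -> None:
        if self.g_norm is not None and self.g_norm <= 0:
            raise ValueError("g_norm must be positive")
        if not (0.0 < self.h < 1.0):
            raise ValueError("threshold h must lie in (0, 1)")
        if self.ts_ms < 0:
            raise ValueError("ts_ms must be >= 0")
        if self.spike_mode not in ("remove-short", "remove-long"):
            raise ValueError("spike_mode must be 'remove-short' or 'remove-long'")

    def effective_g(self, full_range: float) -> float:
        if self.g_norm is not None:
            return self.g_norm
        return 2.0 * full_range * math.sqrt(3.0)


@dataclass(frozen=True)
class MotionMask:
    """Per-sample movement indicator and binary flag after time filtering."""

    d: np.ndarray
    v: np.ndarray

    def __len__(self) -> int:
        return len(self.v)


def movement_indicator(acc: AccelSequence, params: MotionParams | None = None) -> np.ndarray:
    """Normalised magnitude of the first-differenced acceleration.

    d_i = sqrt(dgx^2 + dgy^2 + dgz^2) / G with d_0 = 0 by convention; with
    the default G the indicator is bounded by 1 for any in-range trace.
    """
    params = params or MotionParams()
    if len(acc) < 2:
        raise ValueError("need at least 2 accelerometer samples")
    g = params.effective_g(acc.full_range)
    d = np.zeros(len(acc), dtype=float)
    d[1:] = np.sqrt(
        np.diff(acc.gx) ** 2 + np.diff(acc.gy) ** 2 + np.diff(acc.gz) ** 2
    ) / g
    return d


def _run_bounds(v: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) bounds of runs of ones."""
    padded = np.concatenate([[0], v.astype(np.int8), [0]])
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    stops = np.flatnonzero(edges == -1)
    return list(zip(starts, stops))


def threshold_and_despike(
    d: np.ndarray, params: MotionParams | None = None, fs: float = 32.0
) -> MotionMask:
    """Threshold the indicator and time-filter the binary flag.

    V_i = 1 where d_i > h; then, in the default debounce mode, runs of ones
    strictly shorter than ts_ms are cleared (a single jolt does not mark the
    window as motion-corrupted).
    """
    params = params or MotionParams()
    d = np.asarray(d, dtype=float)
    v = (d > params.h).astype(np.uint8)
    min_run = params.ts_ms * 1e-3 * fs
    for start, stop in _run_bounds(v):
        length = stop - start
        if params.spike_mode == "remove-short":
            if length < min_run:
                v[start:stop] = 0
        else:  # remove-long: the literal text reading, kept behind the switch
            if length > min_run:
                v[start:stop] = 0
    return MotionMask(d=d, v=v)


def exclude_periods(peaks, mask: MotionMask) -> np.ndarray:
    """Inter-peak periods free of flagged samples.

    For each consecutive peak pair (p, q) the period q - p is kept iff no
    sample index in [ceil(p), floor(q)] is flagged; half-sample peak
    positions round inward.  Returns the kept periods in samples.
    """
    positions = np.asarray(getattr(peaks, "peaks", peaks), dtype=float)
    v = np.asarray(mask.v)
    if positions.size < 2:
        return np.empty(0, dtype=float)
    kept = []
    for p, q in zip(positions[:-1], positions[1:]):
        lo = int(math.ceil(p))
        hi = int(math.floor(q))
        lo = max(lo, 0)
        hi = min(hi, len(v) - 1)
        if lo > hi or not v[lo : hi + 1].any():
            kept.append(q - p)
    return np.asarray(kept, dtype=float)


def resample_accel(acc: AccelSequence, acc_fs: float, fs: float, n_out: int) -> AccelSequence:
    """Nearest-sample-hold resampling of the accelerometer onto the PPG timebase."""
    if acc_fs <= 0 or fs <= 0:
        raise ValueError("sampling rates must be positive")
    t_out = np.arange(n_out) / fs
    idx = np.clip(np.round(t_out * acc_fs).astype(int), 0, len(acc) - 1)
    return AccelSequence(
        gx=acc.gx[idx], gy=acc.gy[idx], gz=acc.gz[idx], full_range=acc.full_range
    )
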