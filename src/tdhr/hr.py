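"""Heart-rate estimation from detected peaks, and the sliding-window driver.

One estimate is produced per analysis window: the heart rate is the inverse
of the median inter-peak period, using only periods untouched by the motion
mask.  A window is invalid when the peak detector's quality gate failed,
when too few movement-free peaks remain to support the configured minimum
measurable rate, or when the resulting rate is implausible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .ampd import AmpdParams, PeakDetectionResult, detect_peaks
from .conditioning import ConditioningConfig, condition_signal, warmup_samples
from .motion import (
    AccelSequence,
    MotionMask,
    MotionParams,
    exclude_periods,
    movement_indicator,
    threshold_and_despike,
)

__all__ = [
    "HRParams",
    "HREstimate",
    "PipelineConfig",
    "min_peaks_required",
    "estimate_hr",
    "sliding_hr",
    "hold_last_valid",
]

logger = logging.getLogger("tdhr")

BPM_PLAUSIBLE_MAX = 220.0  # estimates above this are doubled-peak pathologies


@dataclass(frozen=True)
class HRParams:
    """Window geometry and validity thresholds for HR estimation."""

    fs: float = 32.0
    n: int = 1024
    bpm_min: float = 40.0
    shift_s: float = 2.0
    # count the minimum-peaks requirement after motion exclusion (default)
    # or before it
    require_peaks_after_exclusion: bool = True

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.n < 2 or self.bpm_min < 0 or self.shift_s <= 0:
            raise ValueError("invalid HR parameters")


@dataclass(frozen=True)
class HREstimate:
    """One window's result.  ``bpm`` is NaN when ``valid`` is False.

    ``reason`` classifies invalidity: 'gate' (too-noisy window), 'motion'
    (all periods motion-affected), 'sparse' (too few peaks), 'implausible'
    (rate outside the measurable range), or '' when valid.
    """

    t: float
    bpm: float
    valid: bool
    n_peaks: int
    n_valid_periods: int
    reason: str = ""


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to run raw PPG + accelerometer into an HR trace."""

    conditioning: ConditioningConfig = field(default_factory=ConditioningConfig)
    motion: MotionParams = field(default_factory=MotionParams)
    hr: HRParams = field(default_factory=HRParams)
    lambda_max: int = 17
    enable_flat_peak_rule: bool = True
    # derive limiter bounds from a calm leading stretch instead of the fixed
    # +/-150 defaults
    limiter_auto: bool = False

    def ampd_params(self) -> AmpdParams:
        return AmpdParams(
            n=self.hr.n,
            lambda_max=self.lambda_max,
            enable_flat_peak_rule=self.enable_flat_peak_rule,
        )


def min_peaks_required(params: HRParams) -> int:
    """Minimum peak count P for a valid window: floor(N * BPM_min / (60 fs)).

    A window of N samples at the slowest measurable rate still contains P
    beats; fewer detected peaks than that means the window cannot support a
    trustworthy estimate.
    """
    return int(math.floor(params.n * params.bpm_min / (60.0 * params.fs)))


def estimate_hr(
    peaks: PeakDetectionResult, mask: MotionMask, params: HRParams, t: float = 0.0
) -> HREstimate:
    """Median inter-beat estimate for one window.

    bpm = 60 fs / median(movement-free inter-peak periods in samples); the
    median of an even count is the mean of the two central values.
    """
    if not peaks.valid:
        return HREstimate(t=t, bpm=float("nan"), valid=False,
                          n_peaks=0, n_valid_periods=0, reason="gate")
    positions = peaks.peaks
    v = np.asarray(mask.v)
    idx = np.clip(np.round(positions).astype(int), 0, max(len(v) - 1, 0))
    free = positions[v[idx] == 0] if len(v) else positions
    n_counted = len(free) if params.require_peaks_after_exclusion else len(positions)
    periods = exclude_periods(positions, mask)
    p_required = min_peaks_required(params)
    if n_counted < p_required or n_counted < 2:
        return HREstimate(t=t, bpm=float("nan"), valid=False,
                          n_peaks=len(positions), n_valid_periods=len(periods),
                          reason="sparse")
    if len(periods) == 0:
        return HREstimate(t=t, bpm=float("nan"), valid=False,
                          n_peaks=len(positions), n_valid_periods=0, reason="motion")
    bpm = 60.0 * params.fs / float(np.median(periods))
    if not (params.bpm_min <= bpm <= min(BPM_PLAUSIBLE_MAX, 60.0 * params.fs / 2.0)):
        return HREstimate(t=t, bpm=float("nan"), valid=False,
                          n_peaks=len(positions), n_valid_periods=len(periods),
                          reason="implausible")
    return HREstimate(t=t, bpm=bpm, valid=True,
                      n_peaks=len(positions), n_valid_periods=len(periods))


def sliding_hr(
    ppg: np.ndarray,
    acc: AccelSequence | None,
    cfg: PipelineConfig | None = None,
) -> list[HREstimate]:
    """Condition the stream once and estimate HR on sliding windows.

    Windows of N samples advance by shift_s seconds; each estimate is
    timestamped at its window's trailing edge.  Peaks falling inside the
    filter warm-up transient at the very start of the stream are discarded.
    An empty list is returned for streams shorter than one window.
    """
    cfg = cfg or PipelineConfig()
    hrp = cfg.hr
    x = np.asarray(ppg, dtype=float)
    if x.size < hrp.n:
        logger.warning("stream of %d samples shorter than window N=%d", x.size, hrp.n)
        return []
    cond_cfg = cfg.conditioning
    if cfg.limiter_auto:
        from .conditioning import calibrate_limiter
        from dataclasses import replace as _replace

        calm = x[: min(x.size, int(30 * hrp.fs))]
        cond_cfg = _replace(cond_cfg, limiter=calibrate_limiter(calm, cond_cfg))
    conditioned = condition_signal(x, cond_cfg)
    if acc is not None:
        if len(acc) != x.size:
            raise ValueError("accelerometer not aligned to the PPG stream")
        d = movement_indicator(acc, cfg.motion)
        mask_full = threshold_and_despike(d, cfg.motion, fs=hrp.fs)
    else:
        mask_full = MotionMask(d=np.zeros(x.size), v=np.zeros(x.size, dtype=np.uint8))
    warmup = warmup_samples(cfg.conditioning)
    params = cfg.ampd_params()
    step = int(round(hrp.shift_s * hrp.fs))
    estimates: list[HREstimate] = []
    for start in range(0, x.size - hrp.n + 1, step):
        stop = start + hrp.n
        window = conditioned[start:stop]
        res = detect_peaks(window, params)
        if start < warmup and res.valid:
            keep = res.peaks + start >= warmup
            res = PeakDetectionResult(
                peaks=res.peaks[keep], lam=res.lam, valid=res.valid,
                column_sums=res.column_sums, gamma=res.gamma,
            )
        mask = MotionMask(d=mask_full.d[start:stop], v=mask_full.v[start:stop])
        est = estimate_hr(res, mask, hrp, t=stop / hrp.fs)
        logger.debug(
            "window t=%.1fs lam=%d peaks=%d valid=%s reason=%s",
            est.t, res.lam, res.n_peaks, est.valid, est.reason or "-",
        )
        estimates.append(est)
    return estimates


def hold_last_valid(estimates: list[HREstimate]) -> list[HREstimate]:
    """Substitute the last valid rate for invalid windows (reporting mode)."""
    out: list[HREstimate] = []
    last: float | None = None
    for e in estimates:
        if e.valid:
            last = e.bpm
            out.append(e)
        elif last is not None:
            out.append(HREstimate(t=e.t, bpm=last, valid=True,
                                  n_peaks=e.n_peaks,
                                  n_valid_periods=e.n_valid_periods,
                                  reason="held"))
        else:
            out.append(e)
    return out
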