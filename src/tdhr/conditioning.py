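"""Two-stage band-pass conditioning of the raw PPG signal.

Stage one is a single second-order band-pass section whose recursion output
is clamped by an internal limiter; stage two is a fourth-order band-pass
realised as two plain biquads.  The limiter is the nonlinear element: the
*clamped* value is stored back into the filter state, so a large transient
(a baseline jump from wrist motion) cannot charge the recursion and ring for
seconds the way it would in a linear chain.  The conditioned signal is
zero-mean and band-limited to the heart-rate band, which is what the
multiscale peak detector downstream requires.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

__all__ = [
    "BiquadCoefficients",
    "LimiterBounds",
    "ConditioningConfig",
    "BiquadState",
    "biquad_step",
    "limited_biquad_step",
    "design_bandpass",
    "condition_signal",
    "calibrate_limiter",
    "warmup_samples",
]

# Default analogue band shared by both stages, Hz.
DEFAULT_PASSBAND = (0.5, 2.5)
DEFAULT_FS = 32.0
# Default limiter bounds in filter-output units (counts after stage 1).
DEFAULT_LIMITER = (-150.0, 150.0)


@dataclass(frozen=True)
class BiquadCoefficients:
    """One second-order recursive section, direct form I.

    ``y_i = (b0*x_i + b1*x_{i-1} + b2*x_{i-2} - a1*y_{i-1} - a2*y_{i-2}) / a0``

    The feedback coefficient ``a0`` is kept explicitly (it normalises the
    recursion); sections produced by :func:`design_bandpass` have ``a0 = 1``.
    """

    b0: float
    b1: float = 0.0
    b2: float = 0.0
    a0: float = 1.0
    a1: float = 0.0
    a2: float = 0.0

    def __post_init__(self) -> None:
        if self.a0 == 0.0:
            raise ValueError("a0 must be nonzero")
        if not all(
            math.isfinite(c)
            for c in (self.b0, self.b1, self.b2, self.a0, self.a1, self.a2)
        ):
            raise ValueError("biquad coefficients must be finite")

    def normalized(self) -> "BiquadCoefficients":
        """Return an equivalent section with ``a0 = 1``."""
        a0 = self.a0
        if a0 == 1.0:
            return self
        return BiquadCoefficients(
            self.b0 / a0, self.b1 / a0, self.b2 / a0, 1.0, self.a1 / a0, self.a2 / a0
        )

    def is_stable(self) -> bool:
        """Both poles strictly inside the unit circle."""
        poles = np.roots([self.a0, self.a1, self.a2])
        return bool(np.all(np.abs(poles) < 1.0))

    def as_sos_row(self) -> np.ndarray:
        c = self.normalized()
        return np.array([c.b0, c.b1, c.b2, 1.0, c.a1, c.a2], dtype=float)

    @classmethod
    def from_sos_row(cls, row: np.ndarray) -> "BiquadCoefficients":
        b0, b1, b2, a0, a1, a2 = (float(v) for v in row)
        return cls(b0, b1, b2, a0, a1, a2)


@dataclass(frozen=True)
class LimiterBounds:
    """Clamp interval for the stage-1 recursion output.

    The conditioned signal is zero-mean, so the interval must bracket zero.
    Good bounds sit at roughly 100-150 % of the useful pulse amplitude after
    stage 1: the pulse passes untouched while motion transients are cut.
    """

    lower: float = DEFAULT_LIMITER[0]
    upper: float = DEFAULT_LIMITER[1]

    def __post_init__(self) -> None:
        if not (self.lower < 0.0 < self.upper):
            raise ValueError("limiter bounds must satisfy lower < 0 < upper")


@dataclass(frozen=True)
class ConditioningConfig:
    """Full description of the two-stage conditioning chain."""

    fs: float = DEFAULT_FS
    passband_low: float = DEFAULT_PASSBAND[0]
    passband_high: float = DEFAULT_PASSBAND[1]
    stage1: BiquadCoefficients = None  # type: ignore[assignment]
    limiter: LimiterBounds = field(default_factory=LimiterBounds)
    stage2: tuple[BiquadCoefficients, BiquadCoefficients] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not (0.0 < self.passband_low < self.passband_high < self.fs / 2.0):
            raise ValueError("need 0 < passband_low < passband_high < fs/2")
        if self.stage1 is None:
            (s1,) = design_bandpass(self.fs, self.passband_low, self.passband_high, 2)
            object.__setattr__(self, "stage1", s1)
        if self.stage2 is None:
            s2 = design_bandpass(self.fs, self.passband_low, self.passband_high, 4)
            object.__setattr__(self, "stage2", tuple(s2))

    def with_limiter(self, lower: float, upper: float) -> "ConditioningConfig":
        return replace(self, limiter=LimiterBounds(lower, upper))


class BiquadState:
    """Direct-form-I delay line: two past inputs and two past outputs."""

    __slots__ = ("x1", "x2", "y1", "y2")

    def __init__(self) -> None:
        self.x1 = self.x2 = 0.0
        self.y1 = self.y2 = 0.0


def biquad_step(state: BiquadState, x_i: float, coeffs: BiquadCoefficients) -> float:
    """Advance one plain biquad sample and return the output."""
    if not math.isfinite(x_i):
        raise ValueError(f"non-finite input sample {x_i!r}: corrupt stream")
    c = coeffs
    y = (
        c.b0 * x_i + c.b1 * state.x1 + c.b2 * state.x2 - c.a1 * state.y1 - c.a2 * state.y2
    ) / c.a0
    state.x2, state.x1 = state.x1, x_i
    state.y2, state.y1 = state.y1, y
    return y


def limited_biquad_step(
    state: BiquadState,
    x_i: float,
    coeffs: BiquadCoefficients,
    bounds: LimiterBounds,
) -> float:
    """Advance one limited-biquad sample.

    The candidate output is computed by the plain recursion, clamped to
    ``[lower, upper]``, and the clamped value is what enters the output
    delay line.  Clamping the stored state (rather than post-hoc clipping
    of the emitted samples) is what gives the fast recovery after a large
    input transient.
    """
    if not math.isfinite(x_i):
        raise ValueError(f"non-finite input sample {x_i!r}: corrupt stream")
    c = coeffs
    y_c = (
        c.b0 * x_i + c.b1 * state.x1 + c.b2 * state.x2 - c.a1 * state.y1 - c.a2 * state.y2
    ) / c.a0
    y = min(max(y_c, bounds.lower), bounds.upper)
    state.x2, state.x1 = state.x1, x_i
    state.y2, state.y1 = state.y1, y
    return y


def design_bandpass(fs: float, low: float, high: float, order: int) -> list[BiquadCoefficients]:
    """Design a Butterworth band-pass as a cascade of biquad sections.

    ``order`` is the overall filter order: 2 gives one section, 4 gives two.
    Band edges are the -3 dB points (bilinear transform).
    """
    if not (0.0 < low < high < fs / 2.0):
        raise ValueError(f"infeasible band ({low}, {high}) Hz at fs={fs} Hz")
    if order not in (2, 4):
        raise ValueError("order must be 2 or 4")
    sos = signal.butter(order // 2, [low, high], btype="bandpass", fs=fs, output="sos")
    sections = [BiquadCoefficients.from_sos_row(row) for row in sos]
    for sec in sections:
        if not sec.is_stable():  # pragma: no cover - Butterworth is always stable
            raise ValueError("designed section is unstable")
    return sections


def _run_limited_biquad(
    x: np.ndarray, coeffs: BiquadCoefficients, bounds: LimiterBounds
) -> np.ndarray:
    """Stream the whole array through the limited biquad (scalar loop).

    The clamp feeds back into the recursion, so this cannot be expressed as
    a linear filter call; signals here are short (tens of Hz) and the loop
    is cheap.
    """
    c = coeffs.normalized()
    b0, b1, b2, a1, a2 = c.b0, c.b1, c.b2, c.a1, c.a2
    lo, hi = bounds.lower, bounds.upper
    y = np.empty(len(x), dtype=float)
    x1 = x2 = y1 = y2 = 0.0
    for i, xi in enumerate(x):
        y_c = b0 * xi + b1 * x1 + b2 * x2 - a1 * y1 - a2 * y2
        yi = hi if y_c > hi else (lo if y_c < lo else y_c)
        x2, x1 = x1, xi
        y2, y1 = y1, yi
        y[i] = yi
    return y


def condition_signal(
    raw: np.ndarray,
    cfg: ConditioningConfig | None = None,
    *,
    use_limiter: bool = True,
) -> np.ndarray:
    """Run the full conditioning chain: limited stage 1, then stage 2.

    Returns a float array of the same length as ``raw``.  ``use_limiter=False``
    runs the identical linear chain without the clamp, for side-by-side
    comparison of transient recovery.
    """
    cfg = cfg or ConditioningConfig()
    x = np.asarray(raw, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D sample sequence")
    if x.size < 3:
        raise ValueError("need at least 3 samples to filter")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite samples in input: corrupt stream")
    # the unlimited variant runs the same direct-form-I loop with the clamp
    # disabled, so the two chains are bit-identical whenever the limiter
    # never engages
    bounds = cfg.limiter if use_limiter else LimiterBounds(-math.inf, math.inf)
    y = _run_limited_biquad(x, cfg.stage1, bounds)
    sos2 = np.vstack([sec.as_sos_row() for sec in cfg.stage2])
    return signal.sosfilt(sos2, y)


def calibrate_limiter(
    raw: np.ndarray, cfg: ConditioningConfig, *, factor: float = 1.25
) -> LimiterBounds:
    """Estimate limiter bounds from a calm calibration stretch.

    Bounds are set to ``±factor`` times a robust amplitude estimate of the
    *unlimited* stage-1 output: the median absolute per-cycle extreme
    (upper bound from crests, lower from troughs).  ``factor`` defaults to
    1.25, inside the recommended 100-150 % of the useful-signal amplitude.
    """
    x = np.asarray(raw, dtype=float)
    sos1 = cfg.stage1.as_sos_row()[None, :]
    y = signal.sosfilt(sos1, x)
    y = y[warmup_samples(cfg):]
    if y.size < 8:
        raise ValueError("calibration window too short")
    # Per-cycle extremes approximated over one-second chunks.
    chunk = max(2, int(round(cfg.fs)))
    n_chunks = y.size // chunk
    blocks = y[: n_chunks * chunk].reshape(n_chunks, chunk)
    hi = float(np.median(blocks.max(axis=1)))
    lo = float(np.median(blocks.min(axis=1)))
    if not (lo < 0.0 < hi):
        raise ValueError("calibration window has no oscillatory content")
    return LimiterBounds(factor * lo, factor * hi)


def warmup_samples(cfg: ConditioningConfig) -> int:
    """Start-up transient length: samples to ignore before trusting peaks.

    The chain starts from zero state; two periods of the slowest passband
    component cover the visible transient.
    """
    return int(math.ceil(2.0 * cfg.fs / cfg.passband_low))
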