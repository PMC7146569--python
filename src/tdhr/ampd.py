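"""Multiscale peak detection on the conditioned PPG window.

Implements the memory-reduced binary variant of automatic multiscale peak
detection (AMPD).  The local-maxima scalogram (LMS) is stored as 1-bit
values and truncated to ``lambda_max`` rows; the scale selection uses the
row-sum vector gamma, peaks are read off the column sums, and a window whose
best scale sits on the truncation boundary is declared too noisy.  A "flat
peak" rescue rule recovers crests sampled as two equal values, which strict
local-maximum tests miss on weak wrist signals.

The original real-valued AMPD (full scalogram, random fill values,
column-wise standard deviation) is also provided; it is the reference the
binary variant is validated against and is not used in the pipeline.

Index conventions: the defining comparisons are written for a 1-based window
x_1..x_N with cell (k, i) populated for i = k+2 .. N-k+1 from the test
x_{i-1} > x_{i-k-1} and x_{i-1} > x_{i+k-1}.  In 0-based array terms the
cell for sample j is populated for j = k .. N-k-1 and tests
x[j] > x[j-k] and x[j] > x[j+k]; cells outside that range take the
"otherwise" value (1 for the binary variant).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AmpdParams",
    "BinaryLMS",
    "GammaVector",
    "PeakDetectionResult",
    "compute_binary_lms",
    "compute_gamma",
    "quality_gate",
    "column_sums",
    "flat_peak_positions",
    "detect_peaks",
    "detect_peaks_original_ampd",
]

DEFAULT_LAMBDA_MAX = 17  # scales stored; larger minimising scale => too noisy


@dataclass(frozen=True)
class AmpdParams:
    """Window length and truncation bound for the binary detector."""

    n: int
    lambda_max: int = DEFAULT_LAMBDA_MAX
    enable_flat_peak_rule: bool = True

    def __post_init__(self) -> None:
        if self.lambda_max < 1:
            raise ValueError("lambda_max must be >= 1")
        if self.n < 2 * (self.lambda_max + 2):
            raise ValueError(
                f"window of {self.n} samples too short for lambda_max={self.lambda_max}"
            )


@dataclass(frozen=True)
class BinaryLMS:
    """Truncated 1-bit local-maxima scalogram.

    ``bits[k-1, j]`` is 0 iff sample j is greater than both samples at
    distance k; rows run over scales k = 1..lambda_max, columns over the
    window.  Out-of-range cells hold the "otherwise" value 1.
    """

    bits: np.ndarray

    @property
    def lambda_max(self) -> int:
        return self.bits.shape[0]

    @property
    def n(self) -> int:
        return self.bits.shape[1]


@dataclass(frozen=True)
class GammaVector:
    """Row sums of the scalogram and the selected scale.

    ``lam`` is the smallest scale k (1-based) minimising gamma; it tracks the
    dominant inter-peak half-period of the window.
    """

    gamma: np.ndarray
    lam: int


@dataclass(frozen=True)
class PeakDetectionResult:
    """Detected peak positions for one window.

    Positions are in sample units, 0-based; flat peaks sit on half-sample
    midpoints.  ``valid`` is False when the scale-selection quality gate
    failed, in which case ``peaks`` is empty.
    """

    peaks: np.ndarray
    lam: int
    valid: bool
    column_sums: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    gamma: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    @property
    def n_peaks(self) -> int:
        return int(len(self.peaks))


def compute_binary_lms(x: np.ndarray, params: AmpdParams) -> BinaryLMS:
    """Build the truncated binary scalogram for one window."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size != params.n:
        raise ValueError(f"expected a window of exactly {params.n} samples")
    n, kmax = params.n, params.lambda_max
    bits = np.ones((kmax, n), dtype=np.uint8)
    for k in range(1, kmax + 1):
        j = np.arange(k, n - k)  # columns with both comparison samples in range
        if j.size == 0:
            continue
        is_max = (x[j] > x[j - k]) & (x[j] > x[j + k])
        bits[k - 1, j] = (~is_max).astype(np.uint8)
    return BinaryLMS(bits)


def compute_gamma(lms: BinaryLMS) -> GammaVector:
    """Row sums and the minimising scale (smallest index on ties)."""
    gamma = lms.bits.sum(axis=1, dtype=np.int64)
    lam = int(np.argmin(gamma)) + 1
    return GammaVector(gamma=gamma, lam=lam)


def quality_gate(gamma: GammaVector, params: AmpdParams) -> bool:
    """True when the selected scale is certified below the truncation bound.

    Only ``lambda_max`` rows of the scalogram exist, so a minimising scale
    beyond the bound is observable only as the minimum sitting exactly on
    the last stored row; such windows are declared too noisy for use.
    """
    return gamma.lam < params.lambda_max


def column_sums(lms: BinaryLMS, lam: int) -> np.ndarray:
    """Sum the first ``lam`` scalogram rows per column."""
    if not (1 <= lam <= lms.lambda_max):
        raise ValueError(f"lam={lam} outside stored scales 1..{lms.lambda_max}")
    return lms.bits[:lam].sum(axis=0, dtype=np.int64)


def flat_peak_positions(s: np.ndarray) -> np.ndarray:
    """Midpoint positions of flat two-sample crests.

    A crest realised as two equal samples fails the strict local-maximum
    test at scale 1 but passes at every larger scale, leaving the signature
    s[j-2] > 1, s[j-1] = 1, s[j] = 1, s[j+1] > 1 in the column sums; the
    peak is placed at the midpoint of the two equal samples, half a sample
    below j.
    """
    s = np.asarray(s)
    if s.size < 4:
        return np.empty(0, dtype=float)
    j = np.arange(2, s.size - 1)
    hit = (s[j - 2] > 1) & (s[j - 1] == 1) & (s[j] == 1) & (s[j + 1] > 1)
    return j[hit] - 0.5


def detect_peaks(x: np.ndarray, params: AmpdParams) -> PeakDetectionResult:
    """Run the full binary-AMPD pipeline on one conditioned window.

    Integer peaks are the columns whose sum over the first lam rows is zero;
    flat-peak midpoints are merged in, dropping any midpoint within one
    sample of an integer peak.  An invalid window (gate failure) returns no
    peaks.  The input must already be detrended/zero-mean — the band-pass
    conditioning chain guarantees this.
    """
    lms = compute_binary_lms(x, params)
    gv = compute_gamma(lms)
    ok = quality_gate(gv, params)
    s = column_sums(lms, gv.lam)
    if not ok:
        return PeakDetectionResult(
            peaks=np.empty(0, dtype=float), lam=gv.lam, valid=False,
            column_sums=s, gamma=gv.gamma,
        )
    int_peaks = np.flatnonzero(s == 0).astype(float)
    if params.enable_flat_peak_rule:
        flats = flat_peak_positions(s)
        if flats.size and int_peaks.size:
            # a midpoint within one sample of an integer peak duplicates it
            d = np.min(np.abs(flats[:, None] - int_peaks[None, :]), axis=1)
            flats = flats[d > 1.0]
        peaks = np.sort(np.concatenate([int_peaks, flats]))
    else:
        peaks = int_peaks
    return PeakDetectionResult(
        peaks=peaks, lam=gv.lam, valid=True, column_sums=s, gamma=gv.gamma
    )


def detect_peaks_original_ampd(x: np.ndarray, rng_seed: int = 0) -> PeakDetectionResult:
    """Reference detector: the original real-valued AMPD.

    Builds the full scalogram of L = ceil(N/2) - 1 rows with cell value 0 at
    scale-k local maxima and r + 1 elsewhere (r uniform on [0, 1], seeded),
    selects lam as the global minimiser of the row sums, and reads peaks off
    the columns whose standard deviation over the first lam rows is zero.
    With continuous random fill, a zero column deviation occurs exactly when
    the column is all zeros; for lam = 1 (where the sample deviation is
    undefined) the zero-cell criterion is applied directly.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    L = int(np.ceil(n / 2)) - 1
    if L < 1:
        raise ValueError("window too short for the original detector")
    rng = np.random.default_rng(rng_seed)
    m = rng.uniform(0.0, 1.0, size=(L, n)) + 1.0
    for k in range(1, L + 1):
        j = np.arange(k, n - k)
        if j.size == 0:
            continue
        is_max = (x[j] > x[j - k]) & (x[j] > x[j + k])
        m[k - 1, j[is_max]] = 0.0
    gamma = m.sum(axis=1)
    lam = int(np.argmin(gamma)) + 1
    top = m[:lam]
    if lam == 1:
        is_peak = top[0] == 0.0
    else:
        is_peak = top.std(axis=0, ddof=1) == 0.0
    peaks = np.flatnonzero(is_peak).astype(float)
    return PeakDetectionResult(
        peaks=peaks, lam=lam, valid=True,
        column_sums=(top == 0.0).sum(axis=0), gamma=gamma,
    )
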