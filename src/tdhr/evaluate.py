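"""Scoring an HR trace against a reference series.

The metric is the mean absolute error in bpm over evaluation windows on a
common 2-second grid, reported either with hold-last substitution for
invalid windows or over valid windows only (in which case the fraction of
valid windows is reported alongside).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hr import HREstimate, hold_last_valid

__all__ = ["EvaluationResult", "mae", "mae_series", "aggregate"]


@dataclass(frozen=True)
class EvaluationResult:
    """MAE in bpm, fraction of valid windows, window count and raw errors."""

    mae: float
    valid_fraction: float
    n_windows: int
    per_window_errors: np.ndarray


def mae_series(est: np.ndarray, ref: np.ndarray) -> float:
    """Plain MAE between two aligned bpm series."""
    est = np.asarray(est, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if est.shape != ref.shape:
        raise ValueError("estimate and reference series differ in length")
    return float(np.mean(np.abs(est - ref)))


def mae(
    estimates: list[HREstimate],
    ref_t: np.ndarray,
    ref_bpm: np.ndarray,
    mode: str = "hold-last",
    max_gap_s: float = 1.0,
) -> EvaluationResult:
    """Score estimates against a reference HR series.

    Each estimate is matched to the reference sample nearest its timestamp
    (within ``max_gap_s``; unmatched estimates are not scored).  Mode
    "hold-last" substitutes the last valid rate for invalid windows and
    averages over all matched windows; mode "valid-only" averages over valid
    windows only.  ``valid_fraction`` always reports the fraction of matched
    windows carrying a genuinely valid estimate.
    """
    if mode not in ("hold-last", "valid-only"):
        raise ValueError("mode must be 'hold-last' or 'valid-only'")
    ref_t = np.asarray(ref_t, dtype=float)
    ref_bpm = np.asarray(ref_bpm, dtype=float)
    if ref_t.shape != ref_bpm.shape:
        raise ValueError("reference times and values differ in length")
    if ref_t.size == 0:
        raise ValueError("empty reference series")
    scored = hold_last_valid(estimates) if mode == "hold-last" else estimates
    errors = []
    n_matched = 0
    n_valid = 0
    for orig, e in zip(estimates, scored):
        i = int(np.argmin(np.abs(ref_t - e.t)))
        if abs(ref_t[i] - e.t) > max_gap_s:
            continue
        n_matched += 1
        if orig.valid:
            n_valid += 1
        if e.valid:
            errors.append(abs(e.bpm - ref_bpm[i]))
    errors = np.asarray(errors, dtype=float)
    value = float(errors.mean()) if errors.size else float("nan")
    frac = n_valid / n_matched if n_matched else 0.0
    return EvaluationResult(
        mae=value, valid_fraction=frac, n_windows=n_matched, per_window_errors=errors
    )


def aggregate(results: list[EvaluationResult]) -> dict:
    """Across-recording summary: mean and SD of per-recording MAE and the
    mean valid fraction (the usual per-subject roll-up)."""
    maes = np.asarray([r.mae for r in results], dtype=float)
    fracs = np.asarray([r.valid_fraction for r in results], dtype=float)
    return {
        "mae_mean": float(np.nanmean(maes)),
        "mae_sd": float(np.nanstd(maes, ddof=1)) if maes.size > 1 else 0.0,
        "valid_fraction_mean": float(fracs.mean()),
        "n_recordings": len(results),
    }
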