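"""Start-stop dye-leakage time courses and dose-response (EC50) fitting.

Transient permeabilizers produce a burst of dye release that levels off
within tens of minutes; a second peptide addition triggers a new,
smaller burst.  This module converts raw plate-reader fluorescence to
fractional leakage using buffer (negative) and detergent (positive)
control levels, estimates the initial rate of each burst from a short
window after the addition, and fits the cooperative dose-response

    y = 1 - 1 / (1 + (x / EC50)**p)

where ``p`` is a cooperativity coefficient and the half-maximal
effective dose satisfies ``y(EC50) = 1/2`` for any ``p``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "LeakageTrace",
    "DoseResponse",
    "fractional_leakage",
    "burst_rate",
    "rate_fold_change",
    "dose_response_curve",
    "fit_dose_response",
    "rates_with_sem",
]


@dataclass
class LeakageTrace:
    """One well's fluorescence time course with its control levels.

    ``f0`` is the buffer (no peptide) baseline, ``fmax`` the full-release
    level from detergent (Triton X-100) solubilization.  ``addition_times``
    lists the times (minutes) at which peptide was added.
    """

    time_min: np.ndarray
    fluorescence: np.ndarray
    f0: float
    fmax: float
    addition_times: Sequence[float] = field(default_factory=lambda: (0.0,))
    label: str = ""

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.time_min.shape != self.fluorescence.shape or self.time_min.ndim != 1:
            raise ValueError("time and fluorescence must be 1-D and equal length")
        if np.any(np.diff(self.time_min) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.fmax <= self.f0:
            raise ValueError("fmax (positive control) must exceed f0 (baseline)")

    def fractional(self) -> np.ndarray:
        return fractional_leakage(self.fluorescence, self.f0, self.fmax)


def fractional_leakage(f, f0: float, fmax: float):
    """Normalize fluorescence to the [0, 1] fractional-leakage scale.

    Values outside the control range are clipped, with a warning so
    miscalibrated controls are noticed.
    """
    if fmax <= f0:
        raise ValueError("fmax must exceed f0")
    f = np.asarray(f, dtype=float)
    frac = (f - f0) / (fmax - f0)
    if np.any((frac < -1e-12) | (frac > 1 + 1e-12)):
        warnings.warn(
            "fluorescence outside the control range; fractional leakage clipped",
            stacklevel=2,
        )
    out = np.clip(frac, 0.0, 1.0)
    return out if out.ndim else float(out)


def burst_rate(
    trace: LeakageTrace, addition_index: int = 0, window_s: float = 10.0
) -> float:
    """Initial leakage rate (min^-1) after one peptide addition.

    Ordinary least-squares slope of fractional leakage versus time over
    the first ``window_s`` seconds of readings following the addition --
    a linear fit rather than finite differences, for noise robustness.
    """
    t_add = trace.addition_times[addition_index]
    t = trace.time_min
    mask = (t >= t_add) & (t <= t_add + window_s / 60.0)
    if mask.sum() < 2:
        raise ValueError(
            f"need at least 2 samples within {window_s} s of the addition"
        )
    frac = trace.fractional()[mask]
    slope = np.polyfit(t[mask], frac, 1)[0]
    return float(slope)


def rate_fold_change(rate_a: float, rate_b: float) -> float:
    """Ratio of two burst rates, reported to one decimal place."""
    if rate_b <= 0:
        raise ValueError("reference rate must be positive")
    return round(rate_a / rate_b, 1)


def rates_with_sem(rates: Sequence[float]) -> tuple[float, float]:
    """Mean and standard error of replicate burst rates."""
    r = np.asarray(rates, dtype=float)
    if r.size == 0:
        raise ValueError("no rates supplied")
    sem = float(r.std(ddof=1) / np.sqrt(r.size)) if r.size > 1 else np.nan
    return float(r.mean()), sem


def dose_response_curve(x, ec50: float, p: float):
    """Cooperative dose-response ``y = 1 - 1/(1 + (x/ec50)**p)``."""
    x = np.asarray(x, dtype=float)
    out = 1.0 - 1.0 / (1.0 + (x / ec50) ** p)
    return out if out.ndim else float(out)


@dataclass
class DoseResponse:
    """Fitted dose-response: data, EC50, cooperativity, and fit status."""

    x: np.ndarray
    y: np.ndarray
    ec50: float
    p: float
    success: bool
    message: str = ""

    def predict(self, x):
        return dose_response_curve(x, self.ec50, self.p)


def fit_dose_response(x, y, p0: Optional[tuple[float, float]] = None) -> DoseResponse:
    """Least-squares fit of the cooperative dose-response curve.

    Requires at least 3 points with responses in [0, 1] and positive
    doses.  A degenerate (constant) response or optimizer failure is
    reported through ``success=False`` with the best available
    parameters, never silently.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points to fit EC50 and p")
    if np.any(x <= 0):
        raise ValueError("doses must be positive")
    if np.any((y < 0) | (y > 1)):
        raise ValueError("responses must lie in [0, 1]")
    if np.ptp(y) < 1e-12:
        return DoseResponse(
            x=x, y=y, ec50=np.nan, p=np.nan, success=False,
            message="constant response; EC50 undefined",
        )
    if p0 is None:
        p0 = (float(np.median(x)), 1.0)
    try:
        popt, _ = curve_fit(
            dose_response_curve, x, y, p0=p0,
            bounds=([1e-12, 1e-3], [np.inf, np.inf]), maxfev=20000,
        )
    except RuntimeError as exc:
        return DoseResponse(
            x=x, y=y, ec50=p0[0], p=p0[1], success=False, message=str(exc)
        )
    return DoseResponse(
        x=x, y=y, ec50=float(popt[0]), p=float(popt[1]), success=True
    )
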