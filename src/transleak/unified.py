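"""Unified per-vesicle leakage model for fluorescence requenching.

Idealized graded and all-or-none leakage are two extremes of a single
mechanism.  This module models the spectrum between them with two
concentration-response functions of the normalized peptide dose
``cp`` in [0, 1]:

* ``Pleak(cp)`` -- the probability that a vesicle leaks at all, and
* ``fout(cp)`` -- the fractional extent to which a leaking vesicle
  releases its contents.

Each is a saturating sigmoid (steepness ``C1``, midpoint ``C2``) or a
constant.  A vesicle's internal quenching follows the graded relation of
:mod:`transleak.quench` applied per vesicle; the measured bulk ``Qin`` is
the remaining-dye-weighted average over leaking and intact
subpopulations.  With ``Pleak == 1`` the model reduces exactly to ideal
graded leakage; with ``fout == 1`` it reduces exactly to ideal
all-or-none (flat ``Qin``).  When both responses vary with ``cp`` the
predicted ``Qin(fout)`` is nonmonotonic: graded-like rise at low dose,
all-or-none flattening and fall at high dose ("mixed" behavior).

The default sigmoid is a smoothstep (cubic Hermite) that reaches 0 and 1
at ``C2 -/+ 3/C1`` with midpoint slope ``C1/4``.  A bounded-support form
is required for the mixed regime: with strictly interior sigmoids of
equal steepness the remnant-dye share of leaking vesicles tends to a
constant, so the bulk ``Qin`` is provably monotone and the observed
all-or-none tail at high dose can never be reproduced.  The plain
logistic is available as ``kind="logistic"`` for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .quench import QuenchParams, qin_graded, quench_factor

__all__ = [
    "SigmoidResponse",
    "UnifiedParams",
    "ConcentrationGrid",
    "RequenchCurve",
    "response",
    "vesicle_outcomes",
    "bulk_observables",
    "predict_curve",
    "classify_behavior",
    "chi_squared",
    "fit_unified",
    "fit_ideal_graded",
    "FitResult",
    "IdealGradedFit",
]

_KINDS = ("smoothstep", "logistic", "constant")


@dataclass(frozen=True)
class SigmoidResponse:
    """A concentration-response curve on the normalized dose axis.

    ``kind`` selects the functional form:

    ``smoothstep``
        ``3 t^2 - 2 t^3`` with ``t = clip((cp - c2) * c1 / 6 + 1/2, 0, 1)``;
        reaches exactly 0 and 1 at ``c2 -/+ 3 / c1``, midpoint slope
        ``c1 / 4`` (matching the logistic of the same steepness).
    ``logistic``
        ``1 / (1 + exp(-c1 * (cp - c2)))``.
    ``constant``
        ``value`` for every ``cp`` (the ideal-model limits).
    """

    kind: str = "smoothstep"
    c1: float = 10.0
    c2: float = 0.5
    value: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}")
        if self.kind == "constant":
            if not 0.0 <= self.value <= 1.0:
                raise ValueError("constant response value must lie in [0, 1]")
        else:
            if self.c1 <= 0:
                raise ValueError("steepness c1 must be positive")
            if not 0.0 <= self.c2 <= 1.0:
                raise ValueError("midpoint c2 must lie in [0, 1]")

    def __call__(self, cp):
        return response(cp, self)

    @classmethod
    def constant(cls, value: float) -> "SigmoidResponse":
        return cls(kind="constant", value=value)


def response(cp, r: SigmoidResponse):
    """Evaluate a :class:`SigmoidResponse` at dose(s) ``cp`` in [0, 1]."""
    cp = np.asarray(cp, dtype=float)
    if np.any((cp < 0) | (cp > 1)):
        raise ValueError("normalized peptide concentration cp must lie in [0, 1]")
    if r.kind == "constant":
        out = np.full_like(cp, r.value, dtype=float)
    elif r.kind == "logistic":
        out = 1.0 / (1.0 + np.exp(-r.c1 * (cp - r.c2)))
    else:
        t = np.clip((cp - r.c2) * r.c1 / 6.0 + 0.5, 0.0, 1.0)
        out = t * t * (3.0 - 2.0 * t)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class UnifiedParams:
    """Full parameter set: the two responses plus quencher chemistry."""

    pleak: SigmoidResponse
    foutv: SigmoidResponse
    quench: QuenchParams = field(default_factory=QuenchParams)

    @classmethod
    def ideal_graded(
        cls, foutv: SigmoidResponse, quench: QuenchParams = QuenchParams()
    ) -> "UnifiedParams":
        """Every vesicle leaks (``Pleak = 1``); extent varies with dose."""
        return cls(SigmoidResponse.constant(1.0), foutv, quench)

    @classmethod
    def ideal_all_or_none(
        cls, pleak: SigmoidResponse, quench: QuenchParams = QuenchParams()
    ) -> "UnifiedParams":
        """Leaking vesicles empty completely (``fout = 1``)."""
        return cls(pleak, SigmoidResponse.constant(1.0), quench)


@dataclass(frozen=True)
class ConcentrationGrid:
    """Strictly increasing normalized peptide concentrations in [0, 1]."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size == 0:
            raise ValueError("concentration grid must be a nonempty 1-D array")
        if np.any((v < 0) | (v > 1)):
            raise ValueError("cp values must lie in [0, 1]")
        if np.any(np.diff(v) <= 0):
            raise ValueError("cp values must be strictly increasing")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class RequenchCurve:
    """Ordered requenching observations: (fout_bulk, qin_bulk[, sd]).

    ``cp`` carries the dose at which each point was generated or
    measured; ``degenerate`` marks points where every vesicle emptied
    completely (no dye left to report ``Qin``; the value is set to 1 by
    convention and flagged).
    """

    fout: np.ndarray
    qin: np.ndarray
    sd: Optional[np.ndarray] = None
    cp: Optional[np.ndarray] = None
    source: str = "model"
    degenerate: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.fout = np.asarray(self.fout, dtype=float)
        self.qin = np.asarray(self.qin, dtype=float)
        if self.fout.shape != self.qin.shape or self.fout.ndim != 1:
            raise ValueError("fout and qin must be 1-D arrays of equal length")
        if np.any((self.fout < 0) | (self.fout > 1)):
            raise ValueError("fout values must lie in [0, 1]")
        if np.any((self.qin <= 0) | (self.qin > 1)):
            raise ValueError("qin values must lie in (0, 1]")
        for name in ("sd", "cp"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != self.fout.shape:
                    raise ValueError(f"{name} must match the number of points")
                setattr(self, name, arr)
        if self.sd is not None and np.any(self.sd < 0):
            raise ValueError("sd values must be nonnegative")
        if self.degenerate is None:
            self.degenerate = np.zeros(self.fout.shape, dtype=bool)
        else:
            self.degenerate = np.asarray(self.degenerate, dtype=bool)
        if self.source not in ("model", "experiment"):
            raise ValueError("source must be 'model' or 'experiment'")

    def __len__(self) -> int:
        return len(self.fout)

    def to_frame(self):
        import pandas as pd

        data = {"fout": self.fout, "qin": self.qin}
        if self.cp is not None:
            data = {"cp": self.cp, **data}
        if self.sd is not None:
            data["qin_sd"] = self.sd
        data["degenerate"] = self.degenerate
        return pd.DataFrame(data)


def vesicle_outcomes(cp, params: UnifiedParams):
    """Per-vesicle leak probability and leak extent at dose(s) ``cp``."""
    return response(cp, params.pleak), response(cp, params.foutv)


def bulk_observables(cp, params: UnifiedParams):
    """Population-averaged requenching observables at dose(s) ``cp``.

    The bulk fractional release is ``fout_bulk = Pleak * fout_v``.  The
    bulk internal quenching averages the per-vesicle ``Qin`` weighted by
    the dye each subpopulation retains:

    ``qin_bulk = [P (1 - f) Qg(f) + (1 - P) Qg(0)] / [P (1 - f) + (1 - P)]``

    where ``Qg`` is the graded relation.  When ``Pleak = 1`` and
    ``fout_v = 1`` no dye remains anywhere; the point is flagged
    degenerate and ``qin_bulk`` is set to 1 (the limit in which the only
    subpopulation has shed all of its quencher).

    Returns
    -------
    (fout_bulk, qin_bulk, degenerate) : tuple of ndarray
    """
    p, f = vesicle_outcomes(cp, params)
    p = np.atleast_1d(np.asarray(p, dtype=float))
    f = np.atleast_1d(np.asarray(f, dtype=float))
    p, f = np.broadcast_arrays(p, f)
    w_leak = p * (1.0 - f)
    w_intact = 1.0 - p
    den = w_leak + w_intact
    degenerate = den <= 1e-14
    qg = qin_graded(f, params.quench)
    q0 = quench_factor(params.quench.dpx0, params.quench)
    safe = np.where(degenerate, 1.0, den)
    qin = (w_leak * qg + w_intact * q0) / safe
    # pure subpopulations are exact limits, not weighted averages
    qin = np.where(w_intact == 0.0, qg, qin)
    qin = np.where(w_leak == 0.0, q0, qin)
    qin = np.where(degenerate, 1.0, qin)
    fout = p * f
    scalar = np.ndim(cp) == 0
    if scalar:
        return float(fout[0]), float(qin[0]), bool(degenerate[0])
    return fout, qin, degenerate


def predict_curve(grid, params: UnifiedParams) -> RequenchCurve:
    """Model requenching curve over a concentration grid."""
    if not isinstance(grid, ConcentrationGrid):
        grid = ConcentrationGrid(np.asarray(grid, dtype=float))
    fout, qin, degenerate = bulk_observables(grid.values, params)
    return RequenchCurve(
        fout=fout, qin=qin, cp=grid.values.copy(), source="model", degenerate=degenerate
    )


def classify_behavior(
    curve: RequenchCurve, flat_tol: float = 0.02, rise_tol: float = 0.05
) -> str:
    """Label a requenching curve ``graded``, ``all_or_none`` or ``mixed``.

    Operates on ``Qin`` ordered by increasing ``fout`` (degenerate
    points excluded):

    * total variation of ``Qin`` within ``flat_tol`` -> ``all_or_none``;
    * nondecreasing (no drop exceeding ``flat_tol``) with total rise of
      at least ``rise_tol`` -> ``graded``;
    * a rise of at least ``rise_tol`` followed by a drop exceeding
      ``flat_tol`` -> ``mixed``.
    """
    keep = ~curve.degenerate
    fout = curve.fout[keep]
    qin = curve.qin[keep]
    if len(qin) < 4:
        raise ValueError("classification requires at least 4 non-degenerate points")
    order = np.argsort(fout, kind="stable")
    q = qin[order]
    if q.max() - q.min() <= flat_tol:
        return "all_or_none"
    cummax = np.maximum.accumulate(q)
    max_drop = float(np.max(cummax - q))
    i_peak = int(np.argmax(q))
    rise_to_peak = float(q[i_peak] - q[: i_peak + 1].min())
    if max_drop <= flat_tol:
        if q[-1] - q[0] >= rise_tol:
            return "graded"
        return "all_or_none"
    if rise_to_peak >= rise_tol:
        return "mixed"
    return "all_or_none"


def chi_squared(model: RequenchCurve, data: RequenchCurve, n_params: int) -> float:
    """Reduced chi-squared of a model curve against requenching data.

    The model ``Qin`` is linearly interpolated at the data's ``fout``
    values; residuals are weighted by the data's per-point standard
    deviations and the sum is divided by ``N - n_params``.
    """
    if data.sd is None or np.any(data.sd <= 0):
        raise ValueError("data must carry positive sd for every point")
    n = len(data)
    if n <= n_params:
        raise ValueError("need more data points than fitted parameters")
    order = np.argsort(model.fout, kind="stable")
    pred = np.interp(data.fout, model.fout[order], model.qin[order])
    resid = (data.qin - pred) / data.sd
    return float(np.sum(resid**2) / (n - n_params))


@dataclass
class FitResult:
    """Outcome of a unified-model fit."""

    params: UnifiedParams
    chi2: float
    dof: int
    success: bool
    nfev: int
    message: str

    @property
    def theta(self) -> np.ndarray:
        return np.array(
            [
                self.params.pleak.c1,
                self.params.pleak.c2,
                self.params.foutv.c1,
                self.params.foutv.c2,
            ]
        )


_DEFAULT_STARTS: Sequence[tuple[float, float, float, float]] = (
    (5.0, 0.3, 5.0, 0.5),
    (5.0, 0.5, 5.0, 0.5),
    (5.0, 0.5, 5.0, 0.7),
    (5.0, 0.7, 5.0, 0.5),
    (5.0, 0.4, 5.0, 0.7),
)


def _curve_from_theta(theta, quench: QuenchParams, kind: str) -> UnifiedParams:
    c1p, c2p, c1f, c2f = theta
    return UnifiedParams(
        SigmoidResponse(kind, c1=c1p, c2=c2p),
        SigmoidResponse(kind, c1=c1f, c2=c2f),
        quench,
    )


def fit_unified(
    data: RequenchCurve,
    init: Optional[UnifiedParams] = None,
    bounds: tuple = ((0.5, 0.0, 0.5, 0.0), (100.0, 1.0, 100.0, 1.0)),
    quench: Optional[QuenchParams] = None,
    fout_sd: float = 0.005,
    kind: str = "smoothstep",
) -> FitResult:
    """Fit the four sigmoid parameters to a requenching dataset.

    ``data`` must carry ``cp`` along with ``(fout, qin, sd)``.  The fit
    minimizes sd-weighted ``Qin`` residuals jointly with ``fout``
    residuals (weight ``fout_sd``, since the release fraction is
    measured essentially exactly relative to ``Qin``).  Quench
    parameters are held fixed (pass ``quench`` to override the ones on
    ``init``).  Bounded least squares is run from five deterministic
    starting points plus ``init``; the best converged solution wins.
    The reported statistic is the reduced chi-squared of the ``Qin``
    residuals with four fitted parameters.
    """
    if data.cp is None:
        raise ValueError("fit_unified requires the cp column on the data")
    if data.sd is None or np.any(data.sd <= 0):
        raise ValueError("fit_unified requires positive sd for every point")
    if len(data) <= 4:
        raise ValueError("need more than 4 points to fit 4 parameters")
    if quench is None:
        quench = init.quench if init is not None else QuenchParams()

    cp = data.cp
    keep = ~data.degenerate
    cp, fout, qin, sd = cp[keep], data.fout[keep], data.qin[keep], data.sd[keep]

    def residuals(theta):
        params = _curve_from_theta(theta, quench, kind)
        fm, qm, _ = bulk_observables(cp, params)
        return np.concatenate([(qm - qin) / sd, (fm - fout) / fout_sd])

    starts = list(_DEFAULT_STARTS)
    if init is not None:
        starts.insert(
            0, (init.pleak.c1, init.pleak.c2, init.foutv.c1, init.foutv.c2)
        )
    best = None
    nfev = 0
    for start in starts:
        sol = least_squares(residuals, start, bounds=bounds, x_scale=[10, 0.2, 10, 0.2])
        nfev += sol.nfev
        if best is None or sol.cost < best.cost:
            best = sol
    params = _curve_from_theta(best.x, quench, kind)
    fm, qm, _ = bulk_observables(cp, params)
    dof = len(qin) - 4
    chi2 = float(np.sum(((qm - qin) / sd) ** 2) / dof)
    return FitResult(
        params=params,
        chi2=chi2,
        dof=dof,
        success=bool(best.success),
        nfev=nfev,
        message=best.message,
    )


@dataclass
class IdealGradedFit:
    """Outcome of an ideal-graded fit: entrapped DPX and release-rate ratio."""

    dpx0: float
    alpha: float
    chi2: float
    success: bool
    at_bound: bool
    message: str


def fit_ideal_graded(
    data: RequenchCurve,
    k_static: float = QuenchParams().k_static,
    k_dynamic: float = QuenchParams().k_dynamic,
    alpha_bounds: tuple[float, float] = (0.05, 20.0),
    dpx0_bounds: tuple[float, float] = (1e-7, 1.0),
) -> IdealGradedFit:
    """Fit ``(dpx0, alpha)`` of the ideal graded relation to a curve.

    Minimizes sd-weighted residuals of
    ``Qin = quench_factor(dpx0 * (1 - fout)**alpha)`` with ``dpx0``
    optimized on a log scale.  A solution pinned at a parameter bound is
    flagged ``at_bound`` (typical when all-or-none data are forced
    through the graded relation).
    """
    if len(data) < 3:
        raise ValueError("need at least 3 points to fit 2 parameters")
    if data.sd is None or np.any(data.sd <= 0):
        raise ValueError("fit_ideal_graded requires positive sd for every point")
    fout, qin, sd = data.fout, data.qin, data.sd

    def residuals(theta):
        log_dpx0, alpha = theta
        qp = QuenchParams(
            k_static=k_static, k_dynamic=k_dynamic, dpx0=10.0**log_dpx0, alpha=alpha
        )
        return (qin_graded(fout, qp) - qin) / sd

    lo = (np.log10(dpx0_bounds[0]), alpha_bounds[0])
    hi = (np.log10(dpx0_bounds[1]), alpha_bounds[1])
    best = None
    for log_d0 in (-4.0, -3.0, -2.0, -1.0):
        for a0 in (0.5, 1.5, 4.0):
            sol = least_squares(residuals, (log_d0, a0), bounds=(lo, hi))
            if best is None or sol.cost < best.cost:
                best = sol
    dpx0 = float(10.0 ** best.x[0])
    alpha = float(best.x[1])
    dof = len(data) - 2
    chi2 = float(np.sum(residuals(best.x) ** 2) / dof) if dof > 0 else np.nan
    eps = 1e-6
    at_bound = bool(
        alpha <= alpha_bounds[0] * (1 + eps)
        or alpha >= alpha_bounds[1] * (1 - eps)
        or best.x[0] <= lo[0] + eps
        or best.x[0] >= hi[0] - eps
    )
    return IdealGradedFit(
        dpx0=dpx0,
        alpha=alpha,
        chi2=chi2,
        success=bool(best.success),
        at_bound=at_bound,
        message=best.message,
    )
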