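"""Synthetic-data generators emulating the assays the package analyzes.

Each generator reproduces the statistical structure the corresponding
analysis assumes, so that every pipeline stage can be exercised and
calibrated without measured data:

* requenching tables -- bulk (fout, Qin) points from a generating
  :class:`~transleak.unified.UnifiedParams`, with Gaussian noise on
  ``Qin`` whose standard deviation grows with bulk leakage (in the
  experiment, fewer dye-containing vesicles remain at high dose, so the
  ``Qin`` error bars widen);
* explicit vesicle populations -- the brute-force Monte-Carlo oracle
  behind the analytic bulk averages;
* start-stop leakage time courses -- piecewise saturating-exponential
  bursts with buffer and detergent control traces;
* pore free-energy profiles -- landscapes with a controlled global
  minimum, water-wire shoulder, metastable plateau and local dip, whose
  generating feature locations are returned as ground truth.

Every generator is deterministic under a fixed seed; one root seed per
invocation spawns child streams per replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .kinetics import LeakageTrace
from .landscape import FreeEnergyProfile
from .quench import QuenchParams, qin_graded
from .unified import (
    ConcentrationGrid,
    RequenchCurve,
    SigmoidResponse,
    UnifiedParams,
    bulk_observables,
    vesicle_outcomes,
)

__all__ = [
    "SynthSpec",
    "PmfShape",
    "TraceKinetics",
    "VesiclePopulation",
    "gen_requench_dataset",
    "gen_vesicle_population",
    "gen_leakage_traces",
    "gen_pmf",
    "default_mixed_params",
    "default_graded_params",
]


def default_mixed_params(quench: QuenchParams = QuenchParams()) -> UnifiedParams:
    """Generating parameters for mixed (graded-then-all-or-none) leakage."""
    return UnifiedParams(
        pleak=SigmoidResponse(c1=10.0, c2=0.7),
        foutv=SigmoidResponse(c1=10.0, c2=0.6),
        quench=quench,
    )


def default_graded_params(quench: QuenchParams = QuenchParams()) -> UnifiedParams:
    """Generating parameters for graded-dominated leakage."""
    return UnifiedParams(
        pleak=SigmoidResponse(c1=3.0, c2=0.4),
        foutv=SigmoidResponse(c1=10.0, c2=0.7),
        quench=quench,
    )


@dataclass(frozen=True)
class TraceKinetics:
    """Two-burst start-stop kinetics: rates (min^-1), amplitudes, additions.

    Defaults emulate a strong permeabilizer at low L/P: a first burst at
    0.27 min^-1 that levels within the hour, and a second, smaller burst
    after re-addition of peptide an hour later.
    """

    rates_per_min: Sequence[float] = (0.27, 0.14)
    amplitudes: Sequence[float] = (0.5, 0.25)
    addition_times_min: Sequence[float] = (0.0, 60.0)
    duration_min: float = 120.0
    dt_s: float = 1.0
    f0: float = 100.0
    fmax: float = 1000.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if len(self.rates_per_min) != len(self.addition_times_min) or len(
            self.amplitudes
        ) != len(self.addition_times_min):
            raise ValueError("rates, amplitudes and addition times must align")
        if len(self.addition_times_min) < 1:
            raise ValueError("need at least one addition")
        if sum(self.amplitudes) > 1.0 + 1e-12:
            raise ValueError("burst amplitudes must sum to at most 1")


@dataclass(frozen=True)
class PmfShape:
    """Shape parameters of a synthetic pore free-energy landscape.

    The slope dF/dxi is built analytically -- a saturating rise out of
    the global minimum, a Gaussian slope dip at the shoulder, and
    piecewise-linear descent/ascent around the plateau chosen so the
    slope magnitude crosses ``plateau_slope_tol`` exactly at the
    requested window edges -- then integrated to F(xi).  Keeping the
    slope linear near those crossings makes the edges robust to the
    moving-average smoothing used in detection.
    """

    xi_start: float = 0.05
    xi_stop: float = 2.93
    n_points: int = 145
    min_xi: float = 0.25
    shoulder_xi: float = 0.87
    shoulder_amp: float = 19.0
    shoulder_width: float = 0.06
    rise_rate: float = 100.0
    slope_cap: float = 20.0
    plateau: Optional[tuple[float, float]] = (1.11, 1.83)
    plateau_slope_tol: float = 1.5
    dip_xi: Optional[float] = 1.51
    dip_depth: float = 0.2
    dip_width: float = 0.10
    edge_rate: float = 25.0
    join_rate_left: float = 150.0
    join_rate_right: float = 60.0
    knee: float = 0.1
    tail_slope: float = 12.0
    noise_sd: float = 0.0


@dataclass(frozen=True)
class SynthSpec:
    """Root specification for all generators: seed, noise, truth."""

    seed: int = 0
    n_replicates: int = 3
    qin_sd_base: float = 0.02
    qin_sd_inflation: float = 1.0
    fout_sd: float = 0.0
    params: UnifiedParams = field(default_factory=default_graded_params)
    kinetics: TraceKinetics = field(default_factory=TraceKinetics)
    pmf: PmfShape = field(default_factory=PmfShape)

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if min(self.qin_sd_base, self.qin_sd_inflation, self.fout_sd) < 0:
            raise ValueError("noise parameters must be nonnegative")


def gen_requench_dataset(spec: SynthSpec, cp_levels) -> RequenchCurve:
    """Simulate a requenching table over the given dose levels.

    At each ``cp`` the true bulk observables are computed analytically,
    then ``n_replicates`` noisy ``Qin`` readings are drawn with
    ``sd = base * (1 + inflation * fout_bulk)`` and averaged.  The
    emitted ``sd`` column is the nominal standard deviation of that
    replicate mean, so chi-squared against the generating model is
    calibrated (mean ~ 1).  ``fout`` is noise-free unless ``fout_sd``
    is set.
    """
    grid = ConcentrationGrid(np.asarray(cp_levels, dtype=float))
    fout, qin_true, degenerate = bulk_observables(grid.values, spec.params)
    rng = np.random.default_rng(spec.seed)
    sd_single = spec.qin_sd_base * (1.0 + spec.qin_sd_inflation * fout)
    reps = qin_true[None, :] + rng.normal(
        0.0, 1.0, size=(spec.n_replicates, len(grid))
    ) * sd_single[None, :]
    qin = reps.mean(axis=0)
    qin = np.clip(qin, 1e-9, 1.0)
    sd_mean = sd_single / np.sqrt(spec.n_replicates)
    if spec.fout_sd > 0:
        fout = np.clip(
            fout + rng.normal(0.0, spec.fout_sd, size=fout.shape), 0.0, 1.0
        )
    return RequenchCurve(
        fout=fout,
        qin=qin,
        sd=sd_mean,
        cp=grid.values.copy(),
        source="experiment",
        degenerate=degenerate,
    )


@dataclass
class VesiclePopulation:
    """Explicit per-vesicle outcomes at one dose, with pooled observables."""

    leaked: np.ndarray
    fout_v: np.ndarray
    pooled_fout: float
    pooled_qin: float
    cp: float
    seed: Optional[int]


def gen_vesicle_population(
    n: int, cp: float, params: UnifiedParams, seed: Optional[int] = None
) -> VesiclePopulation:
    """Brute-force Monte-Carlo population at a single dose.

    Each vesicle leaks with probability ``Pleak(cp)`` (Bernoulli); a
    leaking vesicle releases the fraction ``fout(cp)``.  Pooled
    observables are computed directly from the population -- released
    dye fraction, and remaining-dye-weighted internal quenching -- and
    serve as the sampling oracle for
    :func:`transleak.unified.bulk_observables`.
    """
    if n < 1:
        raise ValueError("need at least one vesicle")
    rng = np.random.default_rng(seed)
    p, f = vesicle_outcomes(cp, params)
    leaked = rng.random(n) < p
    fout_v = np.where(leaked, f, 0.0)
    remaining = 1.0 - fout_v
    qin_v = qin_graded(fout_v, params.quench)
    pooled_fout = float(fout_v.mean())
    dye = remaining.sum()
    if dye <= 0:
        pooled_qin = 1.0  # every vesicle emptied; no dye left to report
    else:
        pooled_qin = float((remaining * qin_v).sum() / dye)
    return VesiclePopulation(
        leaked=leaked,
        fout_v=fout_v,
        pooled_fout=pooled_fout,
        pooled_qin=pooled_qin,
        cp=float(cp),
        seed=seed,
    )


def gen_leakage_traces(spec: SynthSpec) -> dict[str, LeakageTrace]:
    """Simulate a start-stop leakage experiment with its control wells.

    The sample trace is a sum of saturating-exponential bursts, one per
    peptide addition: fractional leakage
    ``sum_j A_j * (1 - exp(-k_j (t - t_j)))`` for ``t >= t_j``.  The
    buffer control sits at ``f0`` and the Triton control at ``fmax``.
    """
    kin = spec.kinetics
    rng = np.random.default_rng(spec.seed)
    t = np.arange(0.0, kin.duration_min + 1e-9, kin.dt_s / 60.0)
    frac = np.zeros_like(t)
    for k, amp, t_add in zip(
        kin.rates_per_min, kin.amplitudes, kin.addition_times_min
    ):
        dt = t - t_add
        frac += np.where(dt >= 0, amp * (1.0 - np.exp(-k * np.maximum(dt, 0))), 0.0)
    span = kin.fmax - kin.f0
    fluor = kin.f0 + frac * span
    if kin.noise_sd > 0:
        fluor = fluor + rng.normal(0.0, kin.noise_sd, size=fluor.shape)
    common = dict(
        time_min=t, f0=kin.f0, fmax=kin.fmax, addition_times=tuple(kin.addition_times_min)
    )
    return {
        "sample": LeakageTrace(fluorescence=fluor, label="sample", **common),
        "buffer": LeakageTrace(
            fluorescence=np.full_like(t, kin.f0), label="buffer", **common
        ),
        "triton": LeakageTrace(
            fluorescence=np.full_like(t, kin.fmax), label="triton", **common
        ),
    }


def _pmf_slope(xi: np.ndarray, shape: PmfShape) -> np.ndarray:
    base = shape.slope_cap * np.tanh(
        shape.rise_rate * (xi - shape.min_xi) / shape.slope_cap
    ) - shape.shoulder_amp * np.exp(
        -((xi - shape.shoulder_xi) ** 2) / (2.0 * shape.shoulder_width**2)
    )
    if shape.plateau is None:
        return base
    lo, hi = shape.plateau
    tol = shape.plateau_slope_tol
    knee_val = tol + shape.edge_rate * shape.knee
    # descent into the plateau: steep join, then a linear segment whose
    # slope magnitude crosses tol exactly at the requested left edge
    line_join_l = knee_val - shape.join_rate_left * (xi - (lo - shape.knee))
    line_edge_l = tol - shape.edge_rate * (xi - lo)
    descent = np.where(xi <= lo - shape.knee, line_join_l, line_edge_l)
    h = np.minimum(base, np.maximum(descent, 0.0))
    # ascent out of the plateau, mirror construction at the right edge
    line_edge_r = tol + shape.edge_rate * (xi - hi)
    line_join_r = knee_val + shape.join_rate_right * (xi - (hi + shape.knee))
    h = h + np.clip(np.maximum(line_edge_r, line_join_r), 0.0, shape.tail_slope)
    if shape.dip_xi is not None:
        # derivative of a negative Gaussian: local minimum exactly at dip_xi
        u = xi - shape.dip_xi
        h = h + shape.dip_depth * u / shape.dip_width**2 * np.exp(
            -(u**2) / (2.0 * shape.dip_width**2)
        )
    return h


def gen_pmf(spec: SynthSpec) -> tuple[FreeEnergyProfile, dict]:
    """Construct a synthetic pore free-energy profile with known features.

    Returns the profile together with the generating ground truth
    (feature locations and the plateau window, or ``None`` where a
    feature was disabled).
    """
    shape = spec.pmf
    xi = np.linspace(shape.xi_start, shape.xi_stop, shape.n_points)
    f = cumulative_trapezoid(_pmf_slope(xi, shape), xi, initial=0.0)
    f -= f.min()
    if shape.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        f = f + rng.normal(0.0, shape.noise_sd, size=f.shape)
    label = "synthetic AS-like" if shape.plateau is not None else "synthetic AR-like"
    profile = FreeEnergyProfile(xi=xi, f=f, label=label)
    truth = {
        "min_xi": shape.min_xi,
        "shoulder_xi": shape.shoulder_xi,
        "plateau": shape.plateau,
        "dip_xi": shape.dip_xi if shape.plateau is not None else None,
        "dip_depth": shape.dip_depth if shape.plateau is not None else None,
        "grid_spacing": float(xi[1] - xi[0]),
        "seed": spec.seed,
    }
    return profile, truth
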