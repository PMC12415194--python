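"""Pore free-energy-landscape post-processing.

Potentials of mean force F(xi) along the extended pore reaction
coordinate characterize pore formation and expansion in a membrane:
xi < 1 indexes pore nucleation (culminating in a membrane-spanning
water wire near xi ~ 0.87), while xi >= 1 indexes expansion, with an
approximate pore radius of ``4.22 A * xi`` (4.22 A being the reference
radius R0 at xi ~ 1).  This module extracts the landscape features that
distinguish stressed from relaxed membranes:

* the global minimum (flat, unperturbed bilayer, typically xi ~ 0.25);
* the water-wire shoulder (a dip in slope near xi ~ 0.87);
* the energy of the small "CPP-like" pore (evaluated near xi ~ 1.18);
* a metastable plateau beyond xi = 1 -- a maximal contiguous stretch
  where the smoothed slope stays within tolerance -- possibly holding a
  shallow local minimum.

Profiles from relaxed (area-symmetric) membranes are convex beyond the
minimum and show neither plateau nor local minimum; features that are
not present are reported as absent, never fabricated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "XI_TO_RADIUS_ANGSTROM",
    "FreeEnergyProfile",
    "LandscapeFeatures",
    "xi_to_radius",
    "radius_to_xi",
    "energy_at",
    "find_features",
    "compare_profiles",
]

#: Reference pore radius R0 in Angstrom: the radius when xi ~ 1.
XI_TO_RADIUS_ANGSTROM = 4.22


def xi_to_radius(xi):
    """Approximate pore radius (A) for reaction coordinate ``xi >= 1``.

    The nucleation regime ``xi < 1`` describes partial defects with no
    defined pore radius; those values map to ``nan`` (undefined-radius
    sentinel) rather than raising, so whole profiles can be converted.
    """
    xi = np.asarray(xi, dtype=float)
    r = np.where(xi >= 1.0, XI_TO_RADIUS_ANGSTROM * xi, np.nan)
    return r if r.ndim else float(r)


def radius_to_xi(r):
    """Inverse conversion; radii below R0 = 4.22 A are out of domain."""
    r = np.asarray(r, dtype=float)
    if np.any(r < XI_TO_RADIUS_ANGSTROM):
        raise ValueError(
            f"radius below the reference radius {XI_TO_RADIUS_ANGSTROM} A "
            "has no reaction-coordinate image"
        )
    xi = r / XI_TO_RADIUS_ANGSTROM
    return xi if xi.ndim else float(xi)


@dataclass
class FreeEnergyProfile:
    """Sampled free-energy profile F(xi) with optional pointwise error."""

    xi: np.ndarray
    f: np.ndarray
    err: Optional[np.ndarray] = None
    label: str = ""
    composition: str = ""

    def __post_init__(self) -> None:
        self.xi = np.asarray(self.xi, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        if self.xi.shape != self.f.shape or self.xi.ndim != 1:
            raise ValueError("xi and f must be 1-D arrays of equal length")
        if np.any(np.diff(self.xi) <= 0):
            raise ValueError("xi must be strictly increasing")
        if not np.all(np.isfinite(self.f)):
            raise ValueError("free energies must be finite")
        if self.err is not None:
            self.err = np.asarray(self.err, dtype=float)
            if self.err.shape != self.xi.shape:
                raise ValueError("err must match the number of samples")
            if np.any(self.err < 0):
                raise ValueError("errors must be nonnegative")

    def __len__(self) -> int:
        return len(self.xi)

    @property
    def spacing(self) -> float:
        return float(np.median(np.diff(self.xi)))


def energy_at(profile: FreeEnergyProfile, xi: float) -> float:
    """Free energy at ``xi``, referenced to the profile's global minimum.

    Linear interpolation between samples; out-of-range ``xi`` raises.
    """
    if not profile.xi[0] <= xi <= profile.xi[-1]:
        raise ValueError(
            f"xi={xi} outside the sampled range "
            f"[{profile.xi[0]}, {profile.xi[-1]}]"
        )
    return float(np.interp(xi, profile.xi, profile.f - profile.f.min()))


@dataclass
class LandscapeFeatures:
    """Extracted landscape features; energies referenced to the global min.

    Absent features (no plateau, no local minimum, insufficient range)
    are ``None``, with an explanatory entry in ``flags``.
    """

    global_min_xi: Optional[float] = None
    shoulder_xi: Optional[float] = None
    shoulder_energy: Optional[float] = None
    cpp_xi: Optional[float] = None
    cpp_energy: Optional[float] = None
    metastable_window: Optional[tuple[float, float]] = None
    metastable_energy: Optional[float] = None
    local_min_xi: Optional[float] = None
    local_min_depth: Optional[float] = None
    flags: list = field(default_factory=list)

    @property
    def metastable_radii(self) -> Optional[tuple[float, float]]:
        """Pore-radius (A) image of the metastable window, when defined."""
        if self.metastable_window is None:
            return None
        lo, hi = self.metastable_window
        return (xi_to_radius(max(lo, 1.0)), xi_to_radius(max(hi, 1.0)))

    def to_dict(self) -> dict:
        return {
            "global_min_xi": self.global_min_xi,
            "shoulder_xi": self.shoulder_xi,
            "shoulder_energy": self.shoulder_energy,
            "cpp_xi": self.cpp_xi,
            "cpp_energy": self.cpp_energy,
            "metastable_window": self.metastable_window,
            "metastable_energy": self.metastable_energy,
            "metastable_radii": self.metastable_radii,
            "local_min_xi": self.local_min_xi,
            "local_min_depth": self.local_min_depth,
            "flags": list(self.flags),
        }


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y.copy()
    pad = window // 2
    padded = np.pad(y, pad, mode="edge")
    return np.convolve(padded, np.ones(window) / window, mode="valid")[: len(y)]


def find_features(
    profile: FreeEnergyProfile,
    smooth_window: int = 5,
    plateau_slope_tol: float = 1.5,
    min_tol: float = 0.1,
    shoulder_center: float = 0.87,
    cpp_center: float = 1.18,
    search_halfwidth: float = 0.15,
) -> LandscapeFeatures:
    """Extract the characteristic features of a pore free-energy profile.

    Parameters
    ----------
    smooth_window : int
        Centered moving-average window (samples) applied before
        derivative-based detection.
    plateau_slope_tol : float
        Maximum |dF/dxi| (kcal/mol per unit xi) for a stretch beyond
        xi = 1 to count as a metastable plateau.
    min_tol : float
        Minimum depth (kcal/mol) below both flanks for an interior
        minimum of the plateau to be flagged as a metastable local
        minimum.
    shoulder_center, cpp_center, search_halfwidth : float
        Search window centers (reaction-coordinate units) for the
        water-wire shoulder and the CPP-like pore evaluation point.

    Notes
    -----
    The shoulder is located as the interior minimum of the smoothed
    first derivative within its search window (a slope dip on the rising
    flank).  The plateau is the longest contiguous run of samples beyond
    xi = 1 whose smoothed slope magnitude stays within tolerance.
    Detection is invariant to adding a constant to F.
    """
    feats = LandscapeFeatures()
    n = len(profile)
    if n < 10:
        feats.flags.append("too few samples for feature extraction")
        return feats
    xi, f = profile.xi, profile.f - profile.f.min()
    if np.ptp(f) < 1e-12:
        feats.flags.append("degenerate constant profile")
        return feats
    fs = _moving_average(f, smooth_window)
    slope = np.gradient(fs, xi)

    feats.global_min_xi = float(xi[np.argmin(fs)])

    if xi[0] > 0.5 or xi[-1] < 2.0:
        feats.flags.append("profile does not span xi in (0.5, 2); partial features")

    # water-wire shoulder: slope dip on the rising flank
    win = (xi >= shoulder_center - search_halfwidth) & (
        xi <= shoulder_center + search_halfwidth
    )
    idx = np.where(win)[0]
    if len(idx) >= 3:
        j = idx[np.argmin(slope[idx])]
        if j not in (idx[0], idx[-1]):  # interior dip only
            feats.shoulder_xi = float(xi[j])
            feats.shoulder_energy = float(f[j])
        else:
            feats.flags.append("no slope dip in the shoulder window")
    else:
        feats.flags.append("shoulder window not covered by samples")

    # CPP-like pore energy at the nominal expansion onset
    if xi[0] <= cpp_center <= xi[-1]:
        feats.cpp_xi = cpp_center
        feats.cpp_energy = energy_at(profile, cpp_center)
    else:
        feats.flags.append("cpp evaluation point outside the sampled range")

    # metastable plateau: longest low-|slope| run beyond xi = 1
    candidates = np.where((xi > 1.0) & (np.abs(slope) <= plateau_slope_tol))[0]
    if len(candidates) >= 3:
        runs = np.split(candidates, np.where(np.diff(candidates) != 1)[0] + 1)
        best = max(runs, key=len)
        if len(best) >= 3:
            feats.metastable_window = (float(xi[best[0]]), float(xi[best[-1]]))
            feats.metastable_energy = float(f[best].mean())
            seg = fs[best]
            j = int(np.argmin(seg))
            if 0 < j < len(seg) - 1:
                depth = min(seg[: j + 1].max(), seg[j:].max()) - seg[j]
                if depth >= min_tol:
                    feats.local_min_xi = float(xi[best[0] + j])
                    feats.local_min_depth = float(depth)
    if feats.metastable_window is None:
        feats.flags.append("no metastable plateau beyond xi = 1")
    return feats


def compare_profiles(
    a: FreeEnergyProfile,
    b: FreeEnergyProfile,
    at_radius: float,
    reference: str = "raw",
) -> tuple[float, Optional[float]]:
    """Free-energy difference ``F_b - F_a`` at a common pore radius.

    ``reference="raw"`` differences the profiles as supplied (so two
    copies offset by a constant report that constant); ``"min"``
    references each profile to its own global minimum first, which is
    the convention for comparing pore energetics across membrane
    states.  The propagated error is the quadrature sum of the
    interpolated pointwise errors when both profiles carry them.
    """
    xi = radius_to_xi(at_radius)
    for prof in (a, b):
        if not prof.xi[0] <= xi <= prof.xi[-1]:
            raise ValueError(
                f"radius {at_radius} A (xi={xi:.3f}) outside the sampled "
                f"range of profile {prof.label or '?'}"
            )
    if reference == "min":
        fa = energy_at(a, xi)
        fb = energy_at(b, xi)
    elif reference == "raw":
        fa = float(np.interp(xi, a.xi, a.f))
        fb = float(np.interp(xi, b.xi, b.f))
    else:
        raise ValueError("reference must be 'raw' or 'min'")
    delta = fb - fa
    err = None
    if a.err is not None and b.err is not None:
        ea = float(np.interp(xi, a.xi, a.err))
        eb = float(np.interp(xi, b.xi, b.err))
        err = math.hypot(ea, eb)
    return delta, err
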