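"""ANTS/DPX quenching arithmetic and the two ideal leakage limits.

In the requenching assay a fluorophore (ANTS) is co-entrapped in vesicles
with a collisional/associative quencher (DPX).  The internal quenching
``Qin`` of the dye that remains inside a vesicle reports how much quencher
is still co-entrapped, which in turn encodes how the vesicle released its
contents:

* *graded* leakage -- every vesicle releases part of its dye **and**
  quencher, so ``Qin`` rises toward 1 as leakage proceeds;
* *all-or-none* leakage -- vesicles are either intact or empty, so the
  surviving population keeps its initial quencher load and ``Qin`` stays
  flat at its initial value.

All concentrations in this module are in **molar**; use :func:`to_molar`
when reading tables quoted in mM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "QuenchParams",
    "to_molar",
    "quench_factor",
    "qin_graded",
    "qin_all_or_none",
]

#: Collisional (dynamic) Stern-Volmer constant for ANTS/DPX, M^-1.
DEFAULT_K_DYNAMIC = 50.0
#: Static (association) quenching constant for ANTS/DPX, M^-1.
DEFAULT_K_STATIC = 490.0


def to_molar(value: float, unit: str = "M") -> float:
    """Convert a concentration tagged ``"M"`` or ``"mM"`` to molar."""
    if unit == "M":
        return float(value)
    if unit == "mM":
        return float(value) * 1e-3
    raise ValueError(f"unknown concentration unit {unit!r}; use 'M' or 'mM'")


@dataclass(frozen=True)
class QuenchParams:
    """Entrapped-quencher chemistry of the ANTS/DPX pair.

    Parameters
    ----------
    k_static : float
        Association (static) quenching constant, M^-1.
    k_dynamic : float
        Collisional (dynamic) quenching constant, M^-1.
    dpx0 : float
        Initially entrapped DPX concentration, molar.
    alpha : float
        Ratio of DPX to ANTS release rates; ``alpha > 1`` means the
        quencher escapes a leaking vesicle faster than the dye.
    """

    k_static: float = DEFAULT_K_STATIC
    k_dynamic: float = DEFAULT_K_DYNAMIC
    dpx0: float = 0.004
    alpha: float = 1.43

    def __post_init__(self) -> None:
        if self.k_static < 0 or self.k_dynamic < 0:
            raise ValueError("quenching constants must be nonnegative")
        if self.dpx0 < 0:
            raise ValueError("dpx0 must be nonnegative")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")


def quench_factor(dpx, params: QuenchParams = QuenchParams()):
    """Fractional fluorescence ``Q`` of ANTS at DPX concentration ``dpx``.

    Combines static and dynamic quenching:

    ``Q = 1 / ((1 + k_dynamic * dpx) * (1 + k_static * dpx))``

    so ``Q = 1`` with no quencher and ``Q`` decreases monotonically as
    DPX accumulates.

    Parameters
    ----------
    dpx : float or array_like
        DPX concentration, molar.  Must be nonnegative.

    Returns
    -------
    float or ndarray
        Quenching value in (0, 1].
    """
    dpx = np.asarray(dpx, dtype=float)
    if np.any(dpx < 0):
        raise ValueError("DPX concentration must be nonnegative")
    q = 1.0 / ((1.0 + params.k_dynamic * dpx) * (1.0 + params.k_static * dpx))
    return q if q.ndim else float(q)


def _check_fraction(fout_v) -> np.ndarray:
    fout_v = np.asarray(fout_v, dtype=float)
    if np.any((fout_v < 0) | (fout_v > 1)):
        raise ValueError("per-vesicle fractional leakage must lie in [0, 1]")
    return fout_v


def qin_graded(fout_v, params: QuenchParams = QuenchParams()):
    """Internal quenching of a vesicle that leaked a fraction ``fout_v``
    of its dye in the graded mode.

    The co-entrapped DPX is released alongside the dye at a relative rate
    ``alpha``, leaving ``dpx0 * (1 - fout_v)**alpha`` inside, so

    ``Qin = quench_factor(dpx0 * (1 - fout_v)**alpha)``.

    ``Qin`` is nondecreasing in ``fout_v`` and equals exactly 1 at
    ``fout_v = 1`` (all quencher gone).
    """
    fout_v = _check_fraction(fout_v)
    remaining = np.where(fout_v >= 1.0, 0.0, (1.0 - fout_v) ** params.alpha)
    q = quench_factor(params.dpx0 * remaining, params)
    q = np.where(fout_v >= 1.0, 1.0, q)
    return q if np.ndim(q) else float(q)


def qin_all_or_none(fout_v, params: QuenchParams = QuenchParams()):
    """Internal quenching under ideal all-or-none leakage.

    Vesicles are either intact or empty; the dye that remains is all in
    intact vesicles whose quencher load never changed, so ``Qin`` is the
    initial value ``quench_factor(dpx0)`` for every bulk leakage level.
    """
    fout_v = _check_fraction(fout_v)
    q0 = quench_factor(params.dpx0, params)
    q = np.full_like(fout_v, q0, dtype=float)
    return q if q.ndim else float(q)
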