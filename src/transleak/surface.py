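"""Peptide-occupancy statistics on a vesicle surface.

A large unilamellar vesicle (LUV) is treated as a collection of
simulation-sized membrane patches.  Even for noninteracting peptides,
random placement leaves some patches nearly empty and others crowded;
this heterogeneity is what lets low- and high-occupancy poration
pathways coexist on a single vesicle.  The module provides the
deterministic geometry chain (lipid, patch, and peptide counts from
vesicle size and lipid-to-peptide ratio), binomial/Poisson occupancy
statistics, and seeded random placement realizations on a grid.

Note on areas: the spherical leaflet area of a 100 nm vesicle is
``pi * d**2 ~ 31,416 nm^2``, whereas the worked value commonly used for
this geometry is 32,500 nm^2 (which makes the lipid count a round
100,000 at 65 A^2 per lipid).  ``leaflet_area_override_nm2`` exists to
reproduce that arithmetic chain exactly; the geometric formula is the
default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

__all__ = [
    "VesicleGeometry",
    "SurfacePlacement",
    "leaflet_area",
    "n_lipids",
    "n_patches",
    "n_peptides",
    "patch_occupancy_stats",
    "prob_low_occupancy",
    "random_placement",
    "surface_report",
]

NM2_TO_A2 = 100.0


@dataclass(frozen=True)
class VesicleGeometry:
    """LUV geometry: diameter (nm), area per lipid (A^2), patch edge (nm)."""

    diameter_nm: float = 100.0
    area_per_lipid_A2: float = 65.0
    patch_edge_nm: float = 10.0
    leaflet_area_override_nm2: Optional[float] = None

    def __post_init__(self) -> None:
        if self.diameter_nm <= 0:
            raise ValueError("vesicle diameter must be positive")
        if self.area_per_lipid_A2 <= 0:
            raise ValueError("area per lipid must be positive")
        if self.patch_edge_nm <= 0:
            raise ValueError("patch edge must be positive")
        area = leaflet_area(self)
        if self.patch_edge_nm**2 > area:
            raise ValueError("patch cannot be larger than the leaflet")


def leaflet_area(geom: VesicleGeometry) -> float:
    """Outer-leaflet surface area in nm^2 (sphere area, or the override)."""
    if geom.leaflet_area_override_nm2 is not None:
        if geom.leaflet_area_override_nm2 <= 0:
            raise ValueError("leaflet area override must be positive")
        return float(geom.leaflet_area_override_nm2)
    return math.pi * geom.diameter_nm**2


def n_lipids(leaflet_area_nm2: float, area_per_lipid_A2: float) -> int:
    """Total lipid count of both leaflets, rounded to the nearest integer."""
    if leaflet_area_nm2 <= 0 or area_per_lipid_A2 <= 0:
        raise ValueError("areas must be positive")
    return round(2.0 * leaflet_area_nm2 * NM2_TO_A2 / area_per_lipid_A2)


def n_patches(leaflet_area_nm2: float, patch_edge_nm: float) -> int:
    """Number of whole square patches tiling the outer leaflet."""
    if leaflet_area_nm2 <= 0 or patch_edge_nm <= 0:
        raise ValueError("inputs must be positive")
    return math.floor(leaflet_area_nm2 / patch_edge_nm**2)


def n_peptides(n_lipids_total: int, lp: float) -> int:
    """Peptides bound to a vesicle at lipid-to-peptide ratio ``lp``."""
    if lp <= 0:
        raise ValueError("L/P ratio must be positive")
    return math.floor(n_lipids_total / lp)


def patch_occupancy_stats(n_pep: int, n_patch: int) -> tuple[float, float]:
    """Binomial mean and variance of peptides per patch.

    Each of ``n_pep`` peptides lands independently in one of ``n_patch``
    patches; per-patch counts are Binomial(n_pep, 1/n_patch) with
    variance ``n_pep * (1/n_patch) * (1 - 1/n_patch)``, close to the
    mean (Poisson limit) whenever the patch count is large.
    """
    if n_patch < 1:
        raise ValueError("need at least one patch")
    if n_pep < 0:
        raise ValueError("peptide count must be nonnegative")
    p = 1.0 / n_patch
    return n_pep * p, n_pep * p * (1.0 - p)


def prob_low_occupancy(k: int, mean: float) -> float:
    """Poisson probability that a patch holds at most ``k`` peptides."""
    if k < 0:
        raise ValueError("k must be nonnegative")
    if mean < 0:
        raise ValueError("mean must be nonnegative")
    if mean == 0:
        return 1.0
    return float(stats.poisson.cdf(k, mean))


@dataclass
class SurfacePlacement:
    """A realized random placement of peptides on a rows x cols grid."""

    counts: np.ndarray
    n_peptides: int
    seed: Optional[int]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D grid")
        if self.counts.sum() != self.n_peptides:
            raise ValueError("per-bin counts must sum to the peptide total")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_long_frame(self):
        """Heat-map-ready long format: one (row, col, count) per bin."""
        import pandas as pd

        rows, cols = np.indices(self.counts.shape)
        return pd.DataFrame(
            {
                "row": rows.ravel(),
                "col": cols.ravel(),
                "count": self.counts.ravel(),
            }
        )


def random_placement(
    n_pep: int, rows: int = 18, cols: int = 18, seed: Optional[int] = None
) -> SurfacePlacement:
    """Drop ``n_pep`` peptides uniformly at random onto a grid of bins."""
    if rows * cols < 1:
        raise ValueError("grid must contain at least one bin")
    if n_pep < 0:
        raise ValueError("peptide count must be nonnegative")
    rng = np.random.default_rng(seed)
    bins = rng.integers(0, rows * cols, size=n_pep)
    counts = np.bincount(bins, minlength=rows * cols).reshape(rows, cols)
    return SurfacePlacement(counts=counts, n_peptides=n_pep, seed=seed)


def surface_report(geom: VesicleGeometry, lp: float) -> dict:
    """The worked-example chain for one vesicle geometry and L/P ratio."""
    area = leaflet_area(geom)
    lipids = n_lipids(area, geom.area_per_lipid_A2)
    patches = n_patches(area, geom.patch_edge_nm)
    peptides = n_peptides(lipids, lp)
    mean, var = patch_occupancy_stats(peptides, patches)
    return {
        "leaflet_area_nm2": area,
        "n_lipids": lipids,
        "n_patches": patches,
        "lp": lp,
        "n_peptides": peptides,
        "mean_per_patch": mean,
        "var_per_patch": var,
        "prob_le_2": prob_low_occupancy(2, mean),
    }
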