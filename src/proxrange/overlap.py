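"""Dyadic utilization-distribution overlap.

Two indices quantify how much two UDs share space:

* Bhattacharyya's affinity, BA = ∫∫ √(UD_a · UD_b) dx dy ∈ [0, 1]
  (0 = disjoint, 1 = identical almost everywhere);
* the UD overlap index, UDOI = A_overlap · ∫∫ UD_a · UD_b dx dy, which is
  1 for two identical uniform distributions and exceeds 1 when both
  individuals concentrate in the same high-use areas.

Both are symmetric.  By default indices are computed *conditionally*: each
UD is truncated to its own q-isopleth (0.95 for home range, 0.50 for core
area) and renormalized first, and A_overlap is the intersection area of
the truncated supports.  Pass ``conditional=False`` for full-UD indices.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io_grid import KinshipTable
from .ud_estimation import HomeRangeEstimate, UDRaster, isopleth

__all__ = [
    "Dyad",
    "OverlapResult",
    "common_raster",
    "conditional_truncate",
    "bhattacharyya",
    "udoi",
    "overlap_indices",
    "build_dyads",
    "site_fidelity_pairs",
]

_NORM_TOL = 1e-4
_ALIGN_TOL = 1e-6


@dataclass(frozen=True)
class Dyad:
    """An unordered pair of individuals (or one individual across periods)."""

    id_a: str
    id_b: str
    batch: str = ""
    relation: str = "non-related"
    kind: str = "space-sharing"

    def __post_init__(self) -> None:
        if self.kind == "space-sharing" and self.id_a == self.id_b:
            raise ValueError("space-sharing dyads need two distinct individuals")

    @property
    def key(self) -> frozenset[str]:
        return frozenset((self.id_a, self.id_b))


@dataclass
class OverlapResult:
    """UDOI and BA for one dyad at one isopleth level."""

    dyad: Dyad
    level: float
    udoi: float
    ba: float
    span: str | None = None  # within-year / between-year, for site fidelity

    def __post_init__(self) -> None:
        if not (0.0 <= self.ba <= 1.0):
            raise ValueError(f"BA must be in [0, 1], got {self.ba}")
        if self.udoi < 0:
            raise ValueError(f"UDOI must be ≥ 0, got {self.udoi}")


def _check_normalized(ud: UDRaster, name: str) -> None:
    mass = ud.total_mass()
    if abs(mass - 1.0) > _NORM_TOL:
        raise ValueError(f"{name} is not normalized (total mass {mass:.6f})")


def _check_aligned(a: UDRaster, b: UDRaster) -> None:
    if a.cell_size != b.cell_size:
        raise ValueError("rasters have different cell sizes")
    if (
        abs(a.origin_x - b.origin_x) > _ALIGN_TOL
        or abs(a.origin_y - b.origin_y) > _ALIGN_TOL
        or a.shape != b.shape
    ):
        raise ValueError("rasters are not aligned; run common_raster first")


def common_raster(ud_a: UDRaster, ud_b: UDRaster) -> tuple[UDRaster, UDRaster]:
    """Embed two UDs on the union extent with a shared origin.

    The rasters must share a cell size and lattice (origins differing by a
    whole number of cells); mass is preserved exactly.
    """
    if ud_a.cell_size != ud_b.cell_size:
        raise ValueError(
            f"mismatched cell sizes: {ud_a.cell_size} vs {ud_b.cell_size}"
        )
    c = ud_a.cell_size
    for axis, (oa, ob) in (("x", (ud_a.origin_x, ud_b.origin_x)),
                           ("y", (ud_a.origin_y, ud_b.origin_y))):
        frac = abs((oa - ob) / c - round((oa - ob) / c))
        if frac > _ALIGN_TOL:
            raise ValueError(
                f"origins misaligned on {axis} by a sub-cell offset; "
                "re-estimate both UDs on a shared origin"
            )
    ox = min(ud_a.origin_x, ud_b.origin_x)
    oy = min(ud_a.origin_y, ud_b.origin_y)

    def _extent(ud: UDRaster) -> tuple[int, int]:
        iy = round((ud.origin_y - oy) / c) + ud.shape[0]
        ix = round((ud.origin_x - ox) / c) + ud.shape[1]
        return iy, ix

    nrow = max(_extent(ud_a)[0], _extent(ud_b)[0])
    ncol = max(_extent(ud_a)[1], _extent(ud_b)[1])

    def _embed(ud: UDRaster) -> UDRaster:
        dens = np.zeros((nrow, ncol))
        r0 = round((ud.origin_y - oy) / c)
        c0 = round((ud.origin_x - ox) / c)
        dens[r0 : r0 + ud.shape[0], c0 : c0 + ud.shape[1]] = ud.density
        return UDRaster(ox, oy, c, dens, ud.bandwidth)

    return _embed(ud_a), _embed(ud_b)


def conditional_truncate(ud: UDRaster, hr: HomeRangeEstimate) -> UDRaster:
    """Zero the density outside an isopleth mask and renormalize."""
    if not hr.cell_mask.any():
        raise ValueError("isopleth mask is empty")
    if hr.cell_mask.shape != ud.density.shape:
        raise ValueError("mask shape does not match raster")
    dens = np.where(hr.cell_mask, ud.density, 0.0)
    mass = dens.sum() * ud.cell_size**2
    if mass <= 0:
        raise ValueError("no density mass inside the mask")
    return UDRaster(ud.origin_x, ud.origin_y, ud.cell_size, dens / mass, ud.bandwidth)


def bhattacharyya(ud_a: UDRaster, ud_b: UDRaster) -> float:
    """Bhattacharyya's affinity of two aligned, normalized UDs."""
    _check_aligned(ud_a, ud_b)
    _check_normalized(ud_a, "ud_a")
    _check_normalized(ud_b, "ud_b")
    val = float(np.sqrt(ud_a.density * ud_b.density).sum() * ud_a.cell_size**2)
    return min(max(val, 0.0), 1.0)


def udoi(ud_a: UDRaster, ud_b: UDRaster) -> float:
    """UD overlap index of two aligned, normalized (truncated) UDs.

    A_overlap is the area where both densities are positive; the integral
    of the product is scaled by it, so identical uniform use scores 1.
    """
    _check_aligned(ud_a, ud_b)
    _check_normalized(ud_a, "ud_a")
    _check_normalized(ud_b, "ud_b")
    both = (ud_a.density > 0) & (ud_b.density > 0)
    area_overlap = float(both.sum()) * ud_a.cell_size**2
    integral = float((ud_a.density * ud_b.density).sum() * ud_a.cell_size**2)
    return area_overlap * integral


def overlap_indices(
    ud_a: UDRaster,
    ud_b: UDRaster,
    level: float = 0.95,
    conditional: bool = True,
) -> tuple[float, float]:
    """(udoi, ba) for two UDs at an isopleth level.

    With ``conditional=True`` (default) each UD is truncated to its own
    level-q isopleth and renormalized before either index is computed.
    """
    a, b = common_raster(ud_a, ud_b)
    if conditional:
        a = conditional_truncate(a, isopleth(a, level))
        b = conditional_truncate(b, isopleth(b, level))
    return udoi(a, b), bhattacharyya(a, b)


def build_dyads(
    individuals_per_batch: Mapping[str, Sequence[str]],
    kinship: KinshipTable | None = None,
) -> list[Dyad]:
    """All unordered pairs within each batch, labeled by kinship.

    Input individuals should already be restricted to those with ≥ 2
    nights of data.  Pairs absent from the kinship table default to
    non-related.
    """
    kinship = kinship or KinshipTable()
    dyads = []
    for batch, ids in individuals_per_batch.items():
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if list(ids).count(i) > 1})
            raise ValueError(f"batch {batch!r}: individual(s) listed twice: {dupes}")
        for id_a, id_b in itertools.combinations(ids, 2):
            dyads.append(
                Dyad(id_a, id_b, batch=batch, relation=kinship.relation(id_a, id_b))
            )
    return dyads


def site_fidelity_pairs(
    uds_by_individual: Mapping[str, Mapping[str, UDRaster]],
    period_years: Mapping[str, int],
    level: float = 0.95,
    conditional: bool = True,
) -> list[OverlapResult]:
    """Self-overlap of individuals monitored in ≥ 2 periods.

    One BA-based result per (individual, period pair), labeled
    ``within-year`` or ``between-year`` from the periods' years.  Periods
    are compared in sorted-key order.
    """
    results = []
    for tag, by_period in uds_by_individual.items():
        periods = sorted(by_period.keys())
        for p1, p2 in itertools.combinations(periods, 2):
            span = (
                "within-year" if period_years[p1] == period_years[p2] else "between-year"
            )
            udoi_val, ba_val = overlap_indices(
                by_period[p1], by_period[p2], level=level, conditional=conditional
            )
            dyad = Dyad(tag, tag, batch=f"{p1}|{p2}", kind="site-fidelity")
            results.append(OverlapResult(dyad, level, udoi_val, ba_val, span=span))
    return results
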