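"""Equivalent atomic number Zeq by Compton-ratio matching.

The equivalent atomic number of a multi-element material at energy E is
the (generally fractional) Z of the pure element whose Compton-to-total
attenuation ratio R = (μ/ρ)_Compton / (μ/ρ)_total equals the material's.
Buildup is driven by multiple Compton scattering, so this ratio — not the
electron density — is the matching variable.  The material's R is
bracketed between the ratios R1, R2 of adjacent elements Z1, Z2 and Zeq
is interpolated logarithmically:

    Zeq = [Z1 (ln R2 − ln R) + Z2 (ln R − ln R1)] / (ln R2 − ln R1)

Zeq is energy dependent: it rises through the photoelectric-dominated
region and settles once Compton scattering dominates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence, Union

from .materials import Material
from .photon_data import AttenuationDataset, compton_ratio

__all__ = [
    "ZeqPoint",
    "ZeqCurve",
    "STANDARD_GRID",
    "ZMIN",
    "ZMAX",
    "bracket_ratio",
    "interpolate_zeq",
    "zeq_curve",
]

logger = logging.getLogger(__name__)

# The 25 standard energies (MeV) of the elemental GP reference library.
STANDARD_GRID: tuple[float, ...] = (
    0.015, 0.02, 0.03, 0.04, 0.05, 0.06, 0.08, 0.1, 0.15, 0.2,
    0.3, 0.4, 0.5, 0.6, 0.8, 1.0, 1.5, 2.0, 3.0, 4.0,
    5.0, 6.0, 8.0, 10.0, 15.0,
)

# Elements available for bracketing.  Ratios outside the spanned range are
# a hard error: the formula interpolates, it does not extrapolate.
ZMIN, ZMAX = 4, 30


class ZeqError(ValueError):
    """Equivalent-atomic-number computation failure."""


@dataclass(frozen=True)
class ZeqPoint:
    """Zeq at one energy with its bracketing elements and ratios."""

    energy: float
    R: float
    Z1: int
    R1: float
    Z2: int
    R2: float
    Zeq: float

    def __post_init__(self) -> None:
        lo, hi = min(self.R1, self.R2), max(self.R1, self.R2)
        if not lo <= self.R <= hi:
            raise ZeqError(f"R={self.R} outside bracket [{lo}, {hi}]")
        if not min(self.Z1, self.Z2) <= self.Zeq <= max(self.Z1, self.Z2):
            raise ZeqError(f"Zeq={self.Zeq} outside [{self.Z1}, {self.Z2}]")


@dataclass(frozen=True)
class ZeqCurve:
    """Zeq of one material over an energy grid (strictly increasing)."""

    material: str
    points: tuple[ZeqPoint, ...]

    def __post_init__(self) -> None:
        e = [p.energy for p in self.points]
        if any(b <= a for a, b in zip(e, e[1:])):
            raise ZeqError("energies not strictly increasing")

    @property
    def energies(self) -> tuple[float, ...]:
        return tuple(p.energy for p in self.points)

    @property
    def values(self) -> tuple[float, ...]:
        return tuple(p.Zeq for p in self.points)


def bracket_ratio(R: float,
                  elemental_ratios: Sequence[tuple[int, float]],
                  ) -> tuple[int, float, int, float]:
    """Adjacent-Z pair (Z1, R1, Z2, R2) whose ratios enclose R.

    ``elemental_ratios`` must be sorted by Z.  An exact match returns a
    degenerate bracket (Z, R, Z, R).  If the ratio sequence is
    non-monotone (possible above ~1 MeV where R is nearly flat in Z) and
    several adjacent pairs enclose R, the pair with the smallest Z1 is
    chosen and the ambiguity is logged.
    """
    if not elemental_ratios:
        raise ZeqError("no elemental ratios supplied")
    zs = [z for z, _ in elemental_ratios]
    if any(b <= a for a, b in zip(zs, zs[1:])):
        raise ZeqError("elemental ratios must be sorted by strictly increasing Z")
    for z, r in elemental_ratios:
        if r == R:
            return z, r, z, r
    enclosing = [
        (z1, r1, z2, r2)
        for (z1, r1), (z2, r2) in zip(elemental_ratios, elemental_ratios[1:])
        if min(r1, r2) <= R <= max(r1, r2)
    ]
    if not enclosing:
        lo = min(r for _, r in elemental_ratios)
        hi = max(r for _, r in elemental_ratios)
        raise ZeqError(
            f"ratio R={R} outside the elemental span [{lo:.6g}, {hi:.6g}]"
        )
    if len(enclosing) > 1:
        logger.warning(
            "non-monotone elemental ratios: %d enclosing pairs for R=%g; "
            "using the one with smallest Z1 (Z=%d)",
            len(enclosing), R, enclosing[0][0],
        )
    return enclosing[0]


def interpolate_zeq(R: float, Z1: int, R1: float, Z2: int, R2: float) -> float:
    """Logarithmic interpolation of Zeq from a ratio bracket.

    Degenerate brackets (Z1 == Z2) return Z1.  The log base cancels;
    natural logs are used.  The result is clipped only by validation:
    for R inside the bracket it lies in [Z1, Z2] by construction.
    """
    if min(R, R1, R2) <= 0:
        raise ZeqError("ratios must be positive")
    if Z1 == Z2:
        return float(Z1)
    if R1 == R2:
        raise ZeqError("degenerate ratios R1 == R2 with distinct elements")
    if not min(R1, R2) <= R <= max(R1, R2):
        raise ZeqError(f"R={R} outside bracket [{R1}, {R2}]")
    if R == R1:   # endpoint identities, exact
        return float(Z1)
    if R == R2:
        return float(Z2)
    lr, lr1, lr2 = math.log(R), math.log(R1), math.log(R2)
    return (Z1 * (lr2 - lr) + Z2 * (lr - lr1)) / (lr2 - lr1)


def zeq_curve(m: Material, ds: AttenuationDataset,
              grid: Sequence[float] = STANDARD_GRID,
              zrange: tuple[int, int] = (ZMIN, ZMAX)) -> ZeqCurve:
    """Zeq of a material at every grid energy.

    At each energy the material ratio is computed by the mixture rule,
    bracketed against the elemental ratios for Z in ``zrange``, and
    interpolated logarithmically.
    """
    zlo, zhi = zrange
    available = [z for z in ds.elements if zlo <= z <= zhi]
    if not available:
        raise ZeqError(f"dataset has no elements in Z range {zrange}")
    points = []
    for e in grid:
        r_mat = compton_ratio(m, ds, e)
        elemental = [(z, compton_ratio(z, ds, e)) for z in available]
        try:
            z1, r1, z2, r2 = bracket_ratio(r_mat, elemental)
        except ZeqError as err:
            raise ZeqError(f"at E={e} MeV: {err}") from err
        zeq = interpolate_zeq(r_mat, z1, r1, z2, r2)
        points.append(ZeqPoint(e, r_mat, z1, r1, z2, r2, zeq))
    return ZeqCurve(m.name, tuple(points))
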