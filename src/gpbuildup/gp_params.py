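"""Elemental GP fitting-parameter libraries and Zeq interpolation.

The geometric-progression (GP) representation describes the buildup
factor of a medium by five parameters per energy: a, b, c, d and Xk,
where b is the buildup factor at 1 mfp and the remaining four shape the
per-mfp dose-multiplication factor K(E, x).  Reference libraries (such
as the ANSI/ANS-6.4.3-1991 standard) tabulate these for pure elements
on a fixed 25-energy grid; a material's parameters are obtained by
interpolating each elemental parameter P logarithmically in Z to the
material's equivalent atomic number:

    P(Zeq) = [P1 (ln Z2 − ln Zeq) + P2 (ln Zeq − ln Z1)] / (ln Z2 − ln Z1)

with Z1 = floor(Zeq), Z2 = ceil(Zeq).  GP parameters are defined only on
the library grid; no energy interpolation is performed.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .materials import Material
from .photon_data import AttenuationDataset
from .zeq import STANDARD_GRID, ZeqCurve, zeq_curve

__all__ = [
    "GPParameterSet",
    "GPLibrary",
    "load_gp_library",
    "interpolate_gp",
    "material_gp_table",
]

PARAM_NAMES = ("a", "b", "c", "d", "Xk")


class GPLibraryError(ValueError):
    """Invalid GP parameter library or query."""


@dataclass(frozen=True)
class GPParameterSet:
    """The five GP fitting parameters at one energy.

    ``b`` is the buildup factor at 1 mfp (≥ 1 for physical data);
    ``Xk`` (mfp) sets the depth scale of the tanh term in K; ``a``,
    ``c`` and ``d`` shape the power-law and saturation behaviour.
    """

    energy: float
    a: float
    b: float
    c: float
    d: float
    Xk: float

    def __post_init__(self) -> None:
        if self.b < 1:
            raise GPLibraryError(f"b={self.b} < 1 at E={self.energy} MeV")
        if self.Xk <= 0:
            raise GPLibraryError(f"Xk={self.Xk} <= 0 at E={self.energy} MeV")

    def astuple(self) -> tuple[float, float, float, float, float]:
        return (self.a, self.b, self.c, self.d, self.Xk)


class GPLibrary:
    """Per-element, per-energy GP parameter records.

    Every element must carry exactly the same energy grid (the standard
    25 energies by default); missing (Z, energy) cells are hard errors.
    """

    def __init__(self, table: pd.DataFrame,
                 grid: Sequence[float] = STANDARD_GRID):
        required = ["Z", "energy_MeV", *PARAM_NAMES]
        missing = [c for c in required if c not in table.columns]
        if missing:
            raise GPLibraryError(f"missing columns: {missing}")
        df = table[required].astype(float).copy()
        df["Z"] = df["Z"].astype(int)
        self.grid = tuple(float(e) for e in grid)
        gset = set(self.grid)
        for z, g in df.groupby("Z"):
            have = set(g["energy_MeV"].astype(float))
            lacking = sorted(gset - have)
            if lacking:
                raise GPLibraryError(
                    f"element Z={z} missing energies {lacking}"
                )
            extra = sorted(have - gset)
            if extra:
                raise GPLibraryError(
                    f"element Z={z} has off-grid energies {extra}"
                )
            if len(g) != len(have):
                raise GPLibraryError(f"duplicate (Z, energy) rows for Z={z}")
        self.table = df.sort_values(["Z", "energy_MeV"],
                                    kind="mergesort").reset_index(drop=True)
        self._by_key = {
            (int(r.Z), float(r.energy_MeV)): GPParameterSet(
                float(r.energy_MeV), r.a, r.b, r.c, r.d, r.Xk)
            for r in self.table.itertuples()
        }

    @property
    def elements(self) -> list[int]:
        return sorted(set(self.table["Z"]))

    def lookup(self, z: int, energy: float) -> GPParameterSet:
        key = (int(z), float(energy))
        try:
            return self._by_key[key]
        except KeyError:
            raise GPLibraryError(
                f"no GP record for Z={z} at E={energy} MeV"
            ) from None

    def to_csv(self) -> str:
        buf = io.StringIO()
        self.table.to_csv(buf, index=False)
        return buf.getvalue()


def load_gp_library(source, grid: Sequence[float] = STANDARD_GRID) -> GPLibrary:
    """Read a GP library CSV (path, file object, or literal text).

    Schema: header ``Z,energy_MeV,a,b,c,d,Xk``; one row per (Z, energy).
    """
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    return GPLibrary(pd.read_csv(source, comment="#"), grid=grid)


def interpolate_gp(zeq: float, energy: float, lib: GPLibrary) -> GPParameterSet:
    """GP parameters at a fractional Zeq by logarithmic Z-interpolation.

    Each of a, b, c, d, Xk is interpolated independently between the
    floor and ceiling elements of Zeq; an integer Zeq returns that
    element's library row exactly.  For Zeq in [Z1, Z2] the weights form
    a convex combination, so every interpolated parameter lies between
    its elemental values.
    """
    z1 = math.floor(zeq)
    z2 = math.ceil(zeq)
    if z1 == z2:
        return lib.lookup(z1, energy)
    p1 = lib.lookup(z1, energy)
    p2 = lib.lookup(z2, energy)
    lz, lz1, lz2 = math.log(zeq), math.log(z1), math.log(z2)
    w2 = (lz - lz1) / (lz2 - lz1)
    w1 = 1.0 - w2
    vals = {
        name: w1 * getattr(p1, name) + w2 * getattr(p2, name)
        for name in PARAM_NAMES
    }
    return GPParameterSet(energy=float(energy), **vals)


def material_gp_table(m: Material, ds: AttenuationDataset, lib: GPLibrary,
                      grid: Sequence[float] | None = None,
                      ) -> tuple[list[GPParameterSet], ZeqCurve]:
    """Material GP parameters over the library grid.

    Composes the Zeq curve (Compton-ratio matching) with the elemental
    parameter interpolation.  Returns the parameter list together with
    the underlying Zeq curve so callers can report both.
    """
    grid = tuple(grid) if grid is not None else lib.grid
    off = [e for e in grid if e not in lib.grid]
    if off:
        raise GPLibraryError(f"energies not on the library grid: {off}")
    curve = zeq_curve(m, ds, grid=grid)
    params = [interpolate_gp(p.Zeq, p.energy, lib) for p in curve.points]
    return params, curve
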