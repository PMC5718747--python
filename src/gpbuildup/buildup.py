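"""Geometric-progression buildup factors B(E, x) and derived summaries.

The GP representation writes the point-isotropic buildup factor at
penetration depth x (in mean free paths, x ≤ 40) as

    B(E, x) = 1 + (b − 1)(K^x − 1)/(K − 1)    for K ≠ 1
    B(E, x) = 1 + (b − 1) x                   for K = 1

    K(E, x) = c x^a + d [tanh(x/Xk − 2) − tanh(−2)] / [1 − tanh(−2)]

K is the per-mfp dose-multiplication factor; b is the buildup factor at
1 mfp.  The K=1 case is the removable singularity of the geometric sum
and is taken whenever |K − 1| < 1e-8.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .gp_params import GPParameterSet

__all__ = [
    "BuildupGrid",
    "PeakEnergy",
    "ComparisonSummary",
    "DEFAULT_DEPTHS",
    "MAX_DEPTH",
    "dose_multiplication_k",
    "buildup_factor",
    "buildup_grid",
    "peak_energy",
    "compare_to_reference",
]

MAX_DEPTH = 40.0          # the GP formula is stated for x <= 40 mfp
K_UNITY_TOL = 1e-8        # |K-1| below this uses the linear branch
TANH_M2 = math.tanh(-2.0)

# Depths (mfp) of the water reference tabulation; the packaged default.
DEFAULT_DEPTHS: tuple[float, ...] = (1, 2, 3, 4, 5, 6, 7, 8,
                                     10, 15, 20, 25, 30, 35, 40)


class BuildupError(ValueError):
    """Invalid buildup-factor evaluation."""


@dataclass(frozen=True)
class PeakEnergy:
    """Grid energy maximizing B at a fixed depth."""

    material: str
    depth: float
    Epeak: float


@dataclass(frozen=True)
class ComparisonSummary:
    """Per-cell absolute percent differences against a reference grid."""

    percent: pd.DataFrame   # index energies, columns depths
    min: float
    max: float
    mean: float


def _check_depth(x: float) -> None:
    if x < 0 or x > MAX_DEPTH:
        raise BuildupError(
            f"depth {x} mfp outside [0, {MAX_DEPTH:g}]; the GP "
            f"representation is not valid beyond {MAX_DEPTH:g} mfp"
        )


def dose_multiplication_k(x: float, p: GPParameterSet) -> float:
    """K(E, x) = c x^a + d [tanh(x/Xk − 2) − tanh(−2)] / [1 − tanh(−2)].

    Defined for 0 < x ≤ 40 (x^a diverges at 0 for a < 0).  A
    non-positive K has no geometric-progression meaning and raises.
    """
    _check_depth(x)
    if x <= 0:
        raise BuildupError("K is undefined at x = 0 (x^a diverges for a < 0)")
    k = p.c * x ** p.a + p.d * (math.tanh(x / p.Xk - 2.0) - TANH_M2) / (
        1.0 - TANH_M2)
    if k <= 0:
        raise BuildupError(
            f"unphysical parameters: K={k:.4g} <= 0 at x={x}, E={p.energy} MeV"
        )
    return k


def buildup_factor(x: float, p: GPParameterSet) -> float:
    """Buildup factor B(E, x) for one GP parameter row.

    x = 0 returns 1 by the algebraic limit without evaluating K; the
    K → 1 removable singularity switches to the linear branch
    1 + (b − 1) x.  At x = 1 the value is b identically.
    """
    _check_depth(x)
    if x == 0:
        return 1.0
    k = dose_multiplication_k(x, p)
    if abs(k - 1.0) < K_UNITY_TOL:
        return 1.0 + (p.b - 1.0) * x
    return 1.0 + (p.b - 1.0) * (k ** x - 1.0) / (k - 1.0)


class BuildupGrid:
    """B(E, x) over an energy grid × depth list for one material.

    The matrix is held as a DataFrame indexed by energy (MeV) with one
    column per depth (mfp); a parallel frame ``K`` holds the
    dose-multiplication factors.
    """

    def __init__(self, material: str, params: Sequence[GPParameterSet],
                 depths: Sequence[float]):
        depths = [float(x) for x in depths]
        if not depths:
            raise BuildupError("no depths requested")
        for x in depths:
            if not 0 < x <= MAX_DEPTH:
                raise BuildupError(f"depth {x} mfp outside (0, {MAX_DEPTH:g}]")
        energies = [p.energy for p in params]
        if len(set(energies)) != len(energies):
            raise BuildupError("duplicate energies in parameter table")
        b = np.empty((len(params), len(depths)))
        k = np.empty_like(b)
        for i, p in enumerate(params):
            for j, x in enumerate(depths):
                k[i, j] = dose_multiplication_k(x, p)
                b[i, j] = buildup_factor(x, p)
        self.material = material
        self.depths = tuple(depths)
        self.B = pd.DataFrame(b, index=pd.Index(energies, name="energy_MeV"),
                              columns=depths)
        self.K = pd.DataFrame(k, index=self.B.index.copy(), columns=depths)

    @classmethod
    def from_frame(cls, material: str, B: pd.DataFrame,
                   K: pd.DataFrame | None = None) -> "BuildupGrid":
        """Wrap an externally tabulated B(E, x) matrix (index energies,
        columns depths in mfp) so it can be compared against computed
        grids."""
        grid = cls.__new__(cls)
        grid.material = material
        grid.B = B.astype(float).copy()
        grid.B.columns = [float(c) for c in grid.B.columns]
        grid.B.index.name = "energy_MeV"
        grid.depths = tuple(grid.B.columns)
        grid.K = K if K is not None else pd.DataFrame(
            np.nan, index=grid.B.index, columns=grid.B.columns)
        return grid

    @property
    def energies(self) -> tuple[float, ...]:
        return tuple(float(e) for e in self.B.index)

    def value(self, energy: float, depth: float) -> float:
        return float(self.B.at[energy, float(depth)])

    def to_long(self) -> pd.DataFrame:
        """Long-format table ``energy_MeV, depth_mfp, K, B``."""
        rows = [
            (e, x, float(self.K.at[e, x]), float(self.B.at[e, x]))
            for e in self.B.index for x in self.B.columns
        ]
        return pd.DataFrame(rows, columns=["energy_MeV", "depth_mfp", "K", "B"])


def buildup_grid(params: Sequence[GPParameterSet],
                 depths: Sequence[float] = DEFAULT_DEPTHS,
                 material: str = "material") -> BuildupGrid:
    """Evaluate the full B(E, x) matrix for a GP parameter table."""
    return BuildupGrid(material, params, depths)


def peak_energy(grid: BuildupGrid, depth: float) -> PeakEnergy:
    """Grid energy with maximal B at ``depth``; ties go to lower energy.

    The buildup spectrum has a broad Compton-regime maximum; this
    reports its location on the evaluation grid.
    """
    depth = float(depth)
    if depth not in grid.B.columns:
        raise BuildupError(f"depth {depth} mfp not a column of the grid")
    col = grid.B[depth]
    best = col.index[int(np.argmax(col.to_numpy()))]  # argmax → first/lowest
    return PeakEnergy(grid.material, depth, float(best))


def compare_to_reference(grid: BuildupGrid,
                         reference: pd.DataFrame) -> ComparisonSummary:
    """Absolute percent difference per cell: 100·|B − B_ref|/B_ref.

    ``reference`` must carry the identical energy index and depth
    columns.  Summary statistics run over all cells in row-major
    (energy, depth) order.
    """
    ref = reference.astype(float)
    if list(ref.index) != list(grid.B.index) or \
            [float(c) for c in ref.columns] != list(grid.B.columns):
        raise BuildupError("reference grid index/columns do not match")
    ref.columns = grid.B.columns
    pct = 100.0 * (grid.B - ref).abs() / ref
    vals = pct.to_numpy().ravel()
    return ComparisonSummary(percent=pct, min=float(vals.min()),
                             max=float(vals.max()), mean=float(vals.mean()))
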