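"""Effective atomic number Zeff and tissue-equivalence screening.

Zeff for total photon interaction is computed by the cross-section-ratio
method: the effective (average) atomic cross section per atom divided by
the effective electronic cross section per electron,

    σ_a = (μ/ρ)_material / (N_A Σ_i w_i/A_i)
    σ_e = (1/N_A) Σ_i f_i (A_i/Z_i) (μ/ρ)_i
    Zeff = σ_a / σ_e

with w_i weight fractions, f_i number (mole) fractions and A_i atomic
masses.  For a pure element this reduces to Z exactly.  Avogadro's
number cancels in the ratio.

A candidate phantom material is tissue-equivalent to an organ over the
energy bands where its Zeff tracks the organ's within a stated
tolerance; :func:`equivalence_bands` reports those bands.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .materials import ATOMIC_MASS, Material
from .photon_data import AttenuationDataset, mixture_coefficient
from .zeq import STANDARD_GRID

__all__ = [
    "ZeffCurve",
    "EquivalenceBand",
    "zeff_curve",
    "equivalence_bands",
]


class ZeffError(ValueError):
    """Effective-atomic-number computation failure."""


@dataclass(frozen=True)
class ZeffCurve:
    """Zeff(E) of one material on an energy grid."""

    material: str
    points: tuple[tuple[float, float], ...]  # (energy MeV, Zeff)

    @property
    def energies(self) -> tuple[float, ...]:
        return tuple(e for e, _ in self.points)

    @property
    def values(self) -> tuple[float, ...]:
        return tuple(z for _, z in self.points)


@dataclass(frozen=True)
class EquivalenceBand:
    """Energy intervals where a substitute's Zeff matches an organ's."""

    organ: str
    substitute: str
    tolerance: float
    intervals: tuple[tuple[float, float], ...]  # [first, last] grid energies


def zeff_curve(m: Material, ds: AttenuationDataset,
               grid: Sequence[float] = STANDARD_GRID) -> ZeffCurve:
    """Zeff(E) by the cross-section-ratio method.

    The mixture coefficient follows the dataset's coherent-scattering
    convention for "total".  The result always lies between the
    material's smallest and largest constituent Z.
    """
    mn = m.normalized()
    for z, _ in mn.constituents:
        if z not in ATOMIC_MASS:
            raise ZeffError(f"no atomic mass tabulated for Z={z}")
    moles_per_g = sum(w / ATOMIC_MASS[z] for z, w in mn.constituents)
    f = mn.number_fractions()
    points = []
    for e in grid:
        mu_mat = mixture_coefficient(mn, ds, "total", e)
        sigma_a = mu_mat / moles_per_g          # per-atom cross section (×N_A)
        sigma_e = sum(                          # per-electron cross section
            f[z] * (ATOMIC_MASS[z] / z) * ds.coefficient(z, "total", e)
            for z, _ in mn.constituents
        )
        if sigma_e <= 0:
            raise ZeffError(f"electronic cross section vanishes at E={e} MeV")
        points.append((float(e), sigma_a / sigma_e))
    return ZeffCurve(m.name, tuple(points))


def equivalence_bands(organ: ZeffCurve, substitute: ZeffCurve,
                      tol: float = 0.05,
                      relative: bool = True) -> EquivalenceBand:
    """Maximal energy bands where |ΔZeff| is within tolerance.

    With ``relative=True`` (default) the criterion is
    |Zeff_sub − Zeff_org| / Zeff_org ≤ tol; with ``relative=False`` the
    absolute difference is compared, making the test symmetric under
    exchanging the two curves.  Bands are maximal runs of consecutive
    grid energies, reported as closed [first, last] intervals.
    """
    if organ.energies != substitute.energies:
        raise ZeffError("curves are not on the same energy grid")
    if tol < 0:
        raise ZeffError("tolerance must be non-negative")
    ok = []
    for (e, zo), (_, zs) in zip(organ.points, substitute.points):
        delta = abs(zs - zo)
        ok.append(delta / zo <= tol if relative else delta <= tol)
    intervals: list[tuple[float, float]] = []
    start = None
    energies = organ.energies
    for i, good in enumerate(ok):
        if good and start is None:
            start = energies[i]
        elif not good and start is not None:
            intervals.append((start, energies[i - 1]))
            start = None
    if start is not None:
        intervals.append((start, energies[-1]))
    return EquivalenceBand(organ.material, substitute.material, tol,
                           tuple(intervals))
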