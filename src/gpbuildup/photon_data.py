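"""Elemental photon mass attenuation coefficients and mixture arithmetic.

Houses per-element, per-energy partial and total mass attenuation
coefficients (cm²/g), log-log energy interpolation, the weight-fraction
additivity (mixture) rule, the Compton-to-total ratio R, and the location
of process-crossover energies (photoelectric=Compton, Compton=pair).

Cross sections vary over many decades as power laws in energy, so all
energy interpolation is linear in (ln E, ln μ): exact at grid points,
exact for pure power laws, and monotone between nodes.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from typing import Iterable, Union

import numpy as np
import pandas as pd

from .materials import Material

__all__ = [
    "AttenuationDataset",
    "CrossoverEnergies",
    "PROCESSES",
    "load_attenuation",
    "interpolate_coefficient",
    "mixture_coefficient",
    "compton_ratio",
    "crossover_energy",
    "crossover_energies",
]

# Columns of the attenuation CSV schema, in order.
SCHEMA = [
    "Z", "energy_MeV", "photoelectric", "incoherent", "coherent",
    "pair_nuclear", "pair_electron", "total_with_coherent",
    "total_without_coherent",
]

# Stored partial processes plus the derived ones accepted everywhere a
# process name is taken.  "pair" = nuclear + electron-field contributions;
# "total" resolves through the dataset's coherent-scattering convention.
BASE_PROCESSES = ("photoelectric", "incoherent", "coherent",
                  "pair_nuclear", "pair_electron")
PROCESSES = BASE_PROCESSES + ("pair", "total",
                              "total_with_coherent", "total_without_coherent")


class AttenuationError(ValueError):
    """Invalid attenuation data or query."""


@dataclass(frozen=True)
class CrossoverEnergies:
    """Process-equality energies of a material (MeV).

    ``Epe``: photoelectric = Compton (incoherent); below it photoelectric
    absorption dominates and buildup is suppressed.  ``Epp``: Compton =
    pair production; above it pair production dominates.
    """

    material: str
    Epe: float
    Epp: float

    def __post_init__(self) -> None:
        if not self.Epe < self.Epp:
            raise AttenuationError(
                f"Epe ({self.Epe}) must be below Epp ({self.Epp})"
            )


class AttenuationDataset:
    """Per-element partial/total mass attenuation coefficients (cm²/g).

    Parameters
    ----------
    table : pandas.DataFrame
        Columns following the attenuation CSV schema; one row per
        (Z, energy).  Rows are grouped by Z and sorted by energy.
    include_coherent : bool
        Convention for the derived "total" process: whether coherent
        (Rayleigh) scattering counts toward the total.  The buildup/mfp
        literature usually excludes it, since coherent scattering does
        not remove photons from the beam; both conventions are exposed.
    """

    def __init__(self, table: pd.DataFrame, include_coherent: bool = False):
        missing = [c for c in SCHEMA if c not in table.columns]
        if missing:
            raise AttenuationError(f"missing columns: {missing}")
        df = table[SCHEMA].astype(float).copy()
        df["Z"] = df["Z"].astype(int)
        df = df.sort_values(["Z", "energy_MeV"], kind="mergesort")
        df = df.reset_index(drop=True)
        self._validate(df)
        self.table = df
        self.include_coherent = bool(include_coherent)
        self._curves = {
            int(z): g.set_index("energy_MeV")
            for z, g in df.groupby("Z", sort=True)
        }

    @staticmethod
    def _validate(df: pd.DataFrame) -> None:
        coeff_cols = SCHEMA[2:]
        if (df[coeff_cols].to_numpy() < 0).any():
            raise AttenuationError("negative attenuation coefficient")
        for z, g in df.groupby("Z"):
            e = g["energy_MeV"].to_numpy()
            if len(e) < 2 or not np.all(np.diff(e) > 0):
                raise AttenuationError(
                    f"energy grid for Z={z} not strictly increasing"
                )
        partials = (df["photoelectric"] + df["incoherent"]
                    + df["pair_nuclear"] + df["pair_electron"])
        for col, total in (
            ("total_without_coherent", partials),
            ("total_with_coherent", partials + df["coherent"]),
        ):
            rel = np.abs(df[col] - total) / np.maximum(df[col], 1e-300)
            if (rel > 1e-6).any():
                i = int(np.argmax(rel.to_numpy()))
                raise AttenuationError(
                    f"{col} inconsistent with its partials at row {i} "
                    f"(relative error {rel.iloc[i]:.2e})"
                )

    @property
    def elements(self) -> list[int]:
        return sorted(self._curves)

    def energy_span(self, z: int) -> tuple[float, float]:
        idx = self._element(z).index
        return float(idx[0]), float(idx[-1])

    def _element(self, z: int) -> pd.DataFrame:
        try:
            return self._curves[int(z)]
        except KeyError:
            raise AttenuationError(f"element Z={z} not in dataset") from None

    def _process_values(self, z: int, process: str) -> tuple[np.ndarray, np.ndarray]:
        g = self._element(z)
        e = g.index.to_numpy(float)
        if process in BASE_PROCESSES:
            mu = g[process].to_numpy(float)
        elif process == "pair":
            mu = (g["pair_nuclear"] + g["pair_electron"]).to_numpy(float)
        elif process == "total":
            col = ("total_with_coherent" if self.include_coherent
                   else "total_without_coherent")
            mu = g[col].to_numpy(float)
        elif process in ("total_with_coherent", "total_without_coherent"):
            mu = g[process].to_numpy(float)
        else:
            raise AttenuationError(f"unknown process {process!r}")
        return e, mu

    def coefficient(self, z: int, process: str, energy: float) -> float:
        """(μ/ρ) of element ``z`` for ``process`` at ``energy`` (MeV)."""
        e, mu = self._process_values(z, process)
        return interpolate_coefficient(e, mu, energy)

    def with_convention(self, include_coherent: bool) -> "AttenuationDataset":
        if include_coherent == self.include_coherent:
            return self
        return AttenuationDataset(self.table, include_coherent=include_coherent)

    def to_csv(self) -> str:
        buf = io.StringIO()
        self.table.to_csv(buf, index=False)
        return buf.getvalue()


def load_attenuation(source, include_coherent: bool = False) -> AttenuationDataset:
    """Read an attenuation CSV (path, file object, or literal text)."""
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    df = pd.read_csv(source, comment="#")
    return AttenuationDataset(df, include_coherent=include_coherent)


def interpolate_coefficient(energies: np.ndarray, mu: np.ndarray,
                            energy: float) -> float:
    """Log-log linear interpolation of a coefficient curve at ``energy``.

    Exact at grid points and for power-law curves μ ∝ E^k.  Requires the
    bracketing tabulated values to be positive (their logs must exist).
    """
    energies = np.asarray(energies, float)
    mu = np.asarray(mu, float)
    # tolerate exp(log E) round-trip noise at the span edges
    if energies[0] > energy >= energies[0] * (1 - 1e-12):
        energy = float(energies[0])
    elif energies[-1] < energy <= energies[-1] * (1 + 1e-12):
        energy = float(energies[-1])
    if not energies[0] <= energy <= energies[-1]:
        raise AttenuationError(
            f"energy {energy} MeV outside tabulated span "
            f"[{energies[0]}, {energies[-1]}]"
        )
    j = int(np.searchsorted(energies, energy))
    if j < len(energies) and energies[j] == energy:
        return float(mu[j])
    lo, hi = j - 1, j
    if mu[lo] <= 0 or mu[hi] <= 0:
        raise AttenuationError(
            f"non-positive tabulated coefficient bracketing E={energy} MeV"
        )
    t = (math.log(energy) - math.log(energies[lo])) / (
        math.log(energies[hi]) - math.log(energies[lo]))
    return math.exp((1 - t) * math.log(mu[lo]) + t * math.log(mu[hi]))


def mixture_coefficient(m: Material, ds: AttenuationDataset, process: str,
                        energy: float) -> float:
    """Weight-fraction additivity: (μ/ρ)_m = Σ_i w_i (μ/ρ)_i.

    Fractions are normalized before mixing, so raw tabulated compositions
    whose fractions carry rounding behave identically to normalized ones.
    """
    mn = m.normalized()
    return sum(
        w * ds.coefficient(z, process, energy) for z, w in mn.constituents
    )


def compton_ratio(target: Union[Material, int], ds: AttenuationDataset,
                  energy: float) -> float:
    """Ratio R = (μ/ρ)_Compton / (μ/ρ)_total for an element or material.

    The total follows the dataset's coherent-scattering convention.
    R lies in (0, 1]; for elements at energies below ~1 MeV it decreases
    with Z, which is what makes it usable as an equivalent-atomic-number
    matching variable.
    """
    if isinstance(target, Material):
        inc = mixture_coefficient(target, ds, "incoherent", energy)
        tot = mixture_coefficient(target, ds, "total", energy)
    else:
        inc = ds.coefficient(target, "incoherent", energy)
        tot = ds.coefficient(target, "total", energy)
    if tot <= 0:
        raise AttenuationError(f"total coefficient is zero at E={energy} MeV")
    return inc / tot


def _log_mixture_curve(m: Material, ds: AttenuationDataset, process: str):
    def f(log_e: float) -> float:
        v = mixture_coefficient(m, ds, process, math.exp(log_e))
        if v <= 0:
            raise AttenuationError(
                f"{process} coefficient non-positive at "
                f"E={math.exp(log_e):.4g} MeV"
            )
        return math.log(v)
    return f


def crossover_energy(m: Material, ds: AttenuationDataset, process_a: str,
                     process_b: str, bracket: tuple[float, float],
                     rtol: float = 1e-6) -> float:
    """Energy (MeV) where two mixture coefficient curves are equal.

    Solves ln μ_A(E) = ln μ_B(E) under log-log interpolation by bisection
    in ln E to relative tolerance ``rtol``.  The difference must change
    sign exactly once in the bracket (checked on the tabulated grid plus
    the bracket endpoints); symmetric in the two processes.
    """
    e_lo, e_hi = bracket
    if not 0 < e_lo < e_hi:
        raise AttenuationError(f"invalid bracket {bracket}")
    fa = _log_mixture_curve(m, ds, process_a)
    fb = _log_mixture_curve(m, ds, process_b)

    def diff(log_e: float) -> float:
        return fa(log_e) - fb(log_e)

    # sign-change audit on grid nodes inside the bracket plus endpoints
    nodes = sorted({e for z in m.elements
                    for e in _grid_in(ds, z, e_lo, e_hi)} | {e_lo, e_hi})
    vals = [diff(math.log(e)) for e in nodes]
    exact = [nodes[i] for i, v in enumerate(vals) if v == 0]
    n_changes = sum(1 for i in range(len(vals) - 1)
                    if vals[i] * vals[i + 1] < 0)
    if exact:
        if len(exact) > 1 or n_changes > 0:
            raise AttenuationError(
                f"multiple crossovers in bracket {bracket}"
            )
        return float(exact[0])
    if n_changes == 0:
        raise AttenuationError(f"no sign change in bracket {bracket}")
    if n_changes > 1:
        raise AttenuationError(
            f"multiple sign changes ({n_changes}) in bracket {bracket}"
        )
    i = next(i for i in range(len(vals) - 1) if vals[i] * vals[i + 1] < 0)
    lo, hi = math.log(nodes[i]), math.log(nodes[i + 1])
    flo = vals[i]
    while (hi - lo) > rtol:  # tolerance on ln E == relative tolerance on E
        mid = 0.5 * (lo + hi)
        fmid = diff(mid)
        if fmid == 0:
            return math.exp(mid)
        if flo * fmid < 0:
            hi = mid
        else:
            lo, flo = mid, fmid
    return math.exp(0.5 * (lo + hi))


def _grid_in(ds: AttenuationDataset, z: int, e_lo: float,
             e_hi: float) -> Iterable[float]:
    e = ds._element(z).index.to_numpy(float)
    return e[(e > e_lo) & (e < e_hi)]


def crossover_energies(m: Material, ds: AttenuationDataset,
                       pe_bracket: tuple[float, float] = (0.01, 0.2),
                       pp_bracket: tuple[float, float] = (3.0, 100.0),
                       ) -> CrossoverEnergies:
    """Epe (photoelectric=Compton) and Epp (Compton=pair) of a material."""
    epe = crossover_energy(m, ds, "photoelectric", "incoherent", pe_bracket)
    epp = crossover_energy(m, ds, "incoherent", "pair", pp_bracket)
    return CrossoverEnergies(m.name, Epe=epe, Epp=epp)
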