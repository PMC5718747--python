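"""Synthetic element datasets with analytic structure, and reference tables.

Real elemental cross-section tables (XCOM-style) and elemental GP
libraries (ANSI/ANS-6.4.3-style) are licensed tabulations that users
supply themselves.  For testing, this module generates synthetic stand-ins
whose structure is analytically known, so every interpolation stage has
an exact oracle:

* :func:`synthetic_attenuation` — power-law process model with the
  Compton-to-total ratio strictly decreasing in Z below the pair
  threshold, and a closed-form photoelectric/Compton crossover
  :func:`epe_closed_form`.
* :func:`synthetic_gp_library` — every GP parameter exactly linear in
  ln Z per energy, so logarithmic Z-interpolation recovers planted
  fractional-Z parameters to machine precision.

It also exposes the published reference tabulations packaged with this
distribution (tissue GP parameters, Zeq tables, water buildup reference,
crossover energies) for regression tests and the reporting CLI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .gp_params import GPLibrary, GPParameterSet
from .materials import TISSUE_NAMES
from .photon_data import SCHEMA, AttenuationDataset
from .zeq import STANDARD_GRID

__all__ = [
    "SyntheticSpec",
    "synthetic_attenuation",
    "synthetic_gp_library",
    "epe_closed_form",
    "reference_tables",
    "tissue_gp_parameters",
    "gp_parameter_sets",
    "tissue_zeq_table",
    "water_buildup_reference",
    "tissue_crossover_energies",
    "WORKED_RATIO_EXAMPLE",
]

# Printed worked example of the Zeq interpolation: cortical bone at
# 0.03 MeV, material ratio R bracketed by elements 13 and 14.
WORKED_RATIO_EXAMPLE = {
    "material": "cortical_bone", "energy": 0.03,
    "R": 0.1313, "Z1": 13, "R1": 0.1438, "Z2": 14, "R2": 0.1145,
    "Zeq": 13.40,
}


def _default_grid() -> tuple[float, ...]:
    # geometric grid 0.01–100 MeV that contains the standard energies
    extra = np.geomspace(0.01, 100.0, 61)
    return tuple(sorted(set(np.round(extra, 6)) | set(STANDARD_GRID)))


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic elemental attenuation model.

    Per-gram coefficients (cm²/g), with an effective mass number
    A(Z) = 2Z inside the model:

    * photoelectric:  c_pe · Z^p_pe · E^(−q_pe)
    * incoherent:     c_c · (Z/A) · E^(−s) = c_c/2 · E^(−s)
    * coherent:       c_coh · Z^1.5 · E^(−2)
    * pair (nuclear): c_pp · (Z²/A) · ln(E/E_th) above E_th, else 0;
      the electron-field part is the nuclear part divided by Z.

    The ratio R = incoherent/total is strictly decreasing in Z at every
    energy, and the photoelectric/Compton crossover has the closed form
    of :func:`epe_closed_form`.  ``jitter`` applies multiplicative
    log-normal noise of that relative scale to the partials (seeded;
    off by default so fixtures are deterministic).
    """

    zmin: int = 1   # tissue mixtures need H, C, N, O ...
    zmax: int = 30  # ... while Zeq bracketing uses Z = 4-30 only
    energy_grid: tuple[float, ...] = field(default_factory=_default_grid)
    c_pe: float = 1.0e-8
    p_pe: float = 3.5
    q_pe: float = 3.0
    c_c: float = 0.8
    s: float = 0.29
    c_coh: float = 2.0e-6
    c_pp: float = 0.014
    e_threshold: float = 1.022
    jitter: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.jitter and self.seed is None:
            raise ValueError("jitter requires an explicit seed")
        if min(self.c_pe, self.c_c, self.c_coh, self.c_pp) <= 0:
            raise ValueError("all law coefficients must be positive")


def epe_closed_form(spec: SyntheticSpec, z: int) -> float:
    """Exact photoelectric=Compton crossover energy of the jitter-free model.

    Solves c_pe Z^p E^(−q) = (c_c/2) E^(−s)  ⇒
    E = (2 c_pe Z^p / c_c)^(1/(q − s)).
    """
    return (2.0 * spec.c_pe * z ** spec.p_pe / spec.c_c) ** (
        1.0 / (spec.q_pe - spec.s))


def synthetic_attenuation(spec: SyntheticSpec | None = None,
                          ) -> AttenuationDataset:
    """Generate a synthetic elemental attenuation dataset from ``spec``."""
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(spec.seed) if spec.jitter else None
    e = np.asarray(spec.energy_grid, float)
    rows = []
    for z in range(spec.zmin, spec.zmax + 1):
        pe = spec.c_pe * z ** spec.p_pe * e ** (-spec.q_pe)
        inc = 0.5 * spec.c_c * e ** (-spec.s)
        coh = spec.c_coh * z ** 1.5 * e ** (-2.0)
        pair_n = np.where(e > spec.e_threshold,
                          spec.c_pp * 0.5 * z * np.log(
                              np.maximum(e / spec.e_threshold, 1.0)),
                          0.0)
        pair_e = pair_n / z
        if rng is not None:
            for arr in (pe, inc, coh):
                arr *= np.exp(rng.normal(0.0, spec.jitter, size=arr.shape))
        total_wo = pe + inc + pair_n + pair_e
        total_w = total_wo + coh
        for i in range(len(e)):
            rows.append((z, e[i], pe[i], inc[i], coh[i], pair_n[i],
                         pair_e[i], total_w[i], total_wo[i]))
    return AttenuationDataset(pd.DataFrame(rows, columns=SCHEMA))


def synthetic_gp_library(zrange: tuple[int, int] = (4, 30),
                         grid: Sequence[float] = STANDARD_GRID,
                         seed: int | None = None) -> GPLibrary:
    """GP library whose parameters are exactly linear in ln Z per energy.

    Each parameter P(Z, E) = α_P(E) + β_P(E)·ln Z, so the logarithmic
    Z-interpolation is exact: planted fractional-Z parameters are
    recovered to machine precision.  Constraints b ≥ 1 and Xk > 0 hold
    by construction.  A ``seed`` perturbs the per-energy coefficients
    (the ln Z-linearity is preserved); without it the library is fully
    deterministic.
    """
    zlo, zhi = zrange
    grid = tuple(float(e) for e in grid)
    rng = np.random.default_rng(seed)
    rows = []
    for e in grid:
        le = math.log(e)
        # smooth, loosely physical energy shapes with a Compton-region bump
        bump = math.exp(-0.5 * ((le - math.log(0.1)) / 1.2) ** 2)
        wob = (rng.uniform(-0.05, 0.05, size=5) if seed is not None
               else np.zeros(5))
        alpha = {
            "a": -0.1 * bump + 0.02 + wob[0],
            "b": 1.0 + 3.0 * bump + 0.2,
            "c": 1.2 + bump + wob[2],
            "d": 0.05 * bump - 0.01 + wob[3],
            "Xk": 14.0 + wob[4] * 10.0,
        }
        beta = {
            "a": 0.03 + 0.1 * abs(wob[1]),
            "b": -0.05 * bump,           # b decreases with Z, stays >= 1.2
            "c": -0.15,
            "d": -0.01,
            "Xk": 0.8,
        }
        for z in range(zlo, zhi + 1):
            lz = math.log(z)
            rows.append((z, e, *(alpha[p] + beta[p] * lz
                                 for p in ("a", "b", "c", "d", "Xk"))))
    df = pd.DataFrame(rows, columns=["Z", "energy_MeV", "a", "b", "c", "d",
                                     "Xk"])
    return GPLibrary(df, grid=grid)


# ---------------------------------------------------------------------------
# Packaged reference tabulations (published values, stored at printed
# precision; comparisons should use last-digit tolerances).
# ---------------------------------------------------------------------------

def _read_packaged(name: str) -> pd.DataFrame:
    with resources.files("gpbuildup").joinpath("data", name).open("r") as fh:
        return pd.read_csv(fh, comment="#")


def tissue_gp_parameters() -> pd.DataFrame:
    """Published GP parameters of the 12 tissues: tissue, energy, a..Xk."""
    return _read_packaged("tissue_gp_parameters.csv")


def gp_parameter_sets(tissue: str) -> list[GPParameterSet]:
    """The 25 published GP parameter rows of one tissue, as objects."""
    df = tissue_gp_parameters()
    sub = df[df["tissue"] == tissue]
    if sub.empty:
        raise KeyError(
            f"unknown tissue {tissue!r}; known: {sorted(TISSUE_NAMES)}"
        )
    return [
        GPParameterSet(float(r.energy_MeV), r.a, r.b, r.c, r.d, r.Xk)
        for r in sub.sort_values("energy_MeV").itertuples()
    ]


def tissue_zeq_table() -> pd.DataFrame:
    """Published Zeq values: energy_MeV column + one column per tissue."""
    return _read_packaged("tissue_zeq.csv")


def water_buildup_reference() -> pd.DataFrame:
    """Published water buildup factors: standard (ANSI) vs GP-method values."""
    return _read_packaged("water_buildup_reference.csv")


def tissue_crossover_energies() -> pd.DataFrame:
    """Published Epe, Epp and Epeak (MeV) of the 12 tissues."""
    return _read_packaged("tissue_crossover_energies.csv")


def reference_tables() -> dict[str, pd.DataFrame]:
    """All packaged reference tabulations keyed by a short name."""
    return {
        "tissue_gp_parameters": tissue_gp_parameters(),
        "tissue_zeq": tissue_zeq_table(),
        "water_buildup_reference": water_buildup_reference(),
        "tissue_crossover_energies": tissue_crossover_energies(),
    }
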