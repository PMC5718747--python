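"""Element → weight-fraction compositions of multi-element materials.

A :class:`Material` is a named list of ``(Z, weight_fraction)`` pairs.
Element identity is the atomic number; symbols are resolved at parse time
only.  The built-in registry carries the twelve human organ/tissue
compositions used throughout this package plus liquid water.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

__all__ = [
    "Material",
    "parse_composition",
    "normalize",
    "builtin_registry",
    "get_material",
    "SYMBOL_TO_Z",
    "Z_TO_SYMBOL",
    "ATOMIC_MASS",
]

# IUPAC standard atomic weights (conventional values), Z = 1-40.
# Needed for number fractions (Zeff) and stoichiometric compositions.
ATOMIC_MASS: dict[int, float] = {
    1: 1.008, 2: 4.0026, 3: 6.94, 4: 9.0122, 5: 10.81, 6: 12.011,
    7: 14.007, 8: 15.999, 9: 18.998, 10: 20.180, 11: 22.990, 12: 24.305,
    13: 26.982, 14: 28.085, 15: 30.974, 16: 32.06, 17: 35.45, 18: 39.95,
    19: 39.098, 20: 40.078, 21: 44.956, 22: 47.867, 23: 50.942, 24: 51.996,
    25: 54.938, 26: 55.845, 27: 58.933, 28: 58.693, 29: 63.546, 30: 65.38,
    31: 69.723, 32: 72.630, 33: 74.922, 34: 78.971, 35: 79.904, 36: 83.798,
    37: 85.468, 38: 87.62, 39: 88.906, 40: 91.224,
}

_SYMBOLS = [
    "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne", "Na", "Mg",
    "Al", "Si", "P", "S", "Cl", "Ar", "K", "Ca", "Sc", "Ti", "V", "Cr",
    "Mn", "Fe", "Co", "Ni", "Cu", "Zn", "Ga", "Ge", "As", "Se", "Br",
    "Kr", "Rb", "Sr", "Y", "Zr",
]
Z_TO_SYMBOL: dict[int, str] = {z + 1: s for z, s in enumerate(_SYMBOLS)}
SYMBOL_TO_Z: dict[str, int] = {s.lower(): z for z, s in Z_TO_SYMBOL.items()}

# Raw (pre-normalization) weight-fraction sums may carry rounding from the
# source tabulation; accept within this band and rescale silently.
RAW_SUM_TOLERANCE = 2e-3


class CompositionError(ValueError):
    """Invalid material composition."""


@dataclass(frozen=True)
class Material:
    """A named element → weight-fraction composition.

    Parameters
    ----------
    name : str
        Identifier for the material.
    constituents : tuple of (int, float)
        ``(Z, weight_fraction)`` pairs; order is preserved.
    """

    name: str
    constituents: tuple[tuple[int, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for z, w in self.constituents:
            if not (isinstance(z, int) and 1 <= z <= 100):
                raise CompositionError(f"atomic number out of range: {z!r}")
            if not w > 0:
                raise CompositionError(f"non-positive weight fraction for Z={z}: {w}")
            if z in seen:
                raise CompositionError(f"duplicate element Z={z}")
            seen.add(z)

    @property
    def elements(self) -> tuple[int, ...]:
        return tuple(z for z, _ in self.constituents)

    @property
    def weight_fractions(self) -> dict[int, float]:
        return dict(self.constituents)

    def fraction_sum(self) -> float:
        return sum(w for _, w in self.constituents)

    def normalized(self) -> "Material":
        return normalize(self)

    def number_fractions(self) -> dict[int, float]:
        """Mole (atom-number) fractions f_i = (w_i/A_i) / sum_j(w_j/A_j)."""
        moles = {z: w / ATOMIC_MASS[z] for z, w in self.constituents}
        total = sum(moles.values())
        return {z: n / total for z, n in moles.items()}

    def serialize(self) -> str:
        """CSV text in the ``element,weight_fraction`` dialect."""
        buf = io.StringIO()
        buf.write("element,weight_fraction\n")
        for z, w in self.constituents:
            buf.write(f"{Z_TO_SYMBOL.get(z, z)},{w!r}\n")
        return buf.getvalue()


def _resolve_element(token: str) -> int:
    token = token.strip()
    if token.isdigit():
        z = int(token)
        if not 1 <= z <= 100:
            raise CompositionError(f"atomic number out of range: {z}")
        return z
    z = SYMBOL_TO_Z.get(token.lower())
    if z is None:
        raise CompositionError(f"unknown element symbol: {token!r}")
    return z


def parse_composition(source: str, name: str = "material") -> Material:
    """Parse a composition table into a validated (unnormalized) Material.

    Two dialects are accepted:

    * CSV with header ``element,weight_fraction``; ``#`` starts a comment;
      the element column holds a symbol (case-insensitive) or an integer Z.
    * Inline pairs, e.g. ``"H 0.102, O 0.898"``.

    The raw fractions must sum to 1 within ±2e-3; outside that band the
    composition is rejected rather than silently rescaled.
    """
    pairs: list[tuple[int, float]] = []
    lines = [ln.split("#", 1)[0].strip() for ln in source.splitlines()]
    lines = [ln for ln in lines if ln]
    if not lines:
        raise CompositionError("empty composition")

    if lines[0].replace(" ", "").lower() == "element,weight_fraction":
        for ln in lines[1:]:
            parts = [p.strip() for p in ln.split(",")]
            if len(parts) != 2:
                raise CompositionError(f"malformed row: {ln!r}")
            pairs.append((_resolve_element(parts[0]), _parse_fraction(parts[1])))
    else:
        for chunk in ",".join(lines).split(","):
            chunk = chunk.strip()
            if not chunk:
                continue
            parts = chunk.replace(":", " ").split()
            if len(parts) != 2:
                raise CompositionError(f"malformed entry: {chunk!r}")
            pairs.append((_resolve_element(parts[0]), _parse_fraction(parts[1])))

    if not pairs:
        raise CompositionError("composition has no entries")
    m = Material(name, tuple(pairs))  # validates duplicates/signs
    s = m.fraction_sum()
    if abs(s - 1.0) > RAW_SUM_TOLERANCE:
        raise CompositionError(
            f"weight fractions sum to {s:.6f}, outside [{1 - RAW_SUM_TOLERANCE}, "
            f"{1 + RAW_SUM_TOLERANCE}]"
        )
    return m


def _parse_fraction(token: str) -> float:
    try:
        return float(token)
    except ValueError:
        raise CompositionError(f"non-numeric weight fraction: {token!r}") from None


def normalize(m: Material) -> Material:
    """Rescale weight fractions to sum exactly to 1 (order preserved)."""
    s = m.fraction_sum()
    return replace(
        m, constituents=tuple((z, w / s) for z, w in m.constituents)
    )


# Built-in tissue compositions (weight fractions, published reference values)
# plus water from 2:1 H:O stoichiometry with standard atomic weights.
_BUILTIN: dict[str, dict[str, float]] = {
    "adipose_tissue": {"H": 0.114, "C": 0.598, "N": 0.007, "O": 0.278,
                       "Na": 0.001, "S": 0.001, "Cl": 0.001},
    "blood": {"H": 0.102, "C": 0.110, "N": 0.033, "O": 0.745, "Na": 0.001,
              "P": 0.001, "S": 0.002, "Cl": 0.003, "K": 0.002, "Fe": 0.001},
    "cortical_bone": {"H": 0.034, "C": 0.155, "N": 0.042, "O": 0.435,
                      "Na": 0.001, "Mg": 0.002, "P": 0.103, "S": 0.003,
                      "Ca": 0.225},
    "brain": {"H": 0.107, "C": 0.145, "N": 0.022, "O": 0.712, "Na": 0.002,
              "P": 0.004, "S": 0.002, "Cl": 0.003, "K": 0.003},
    "breast_tissue": {"H": 0.106, "C": 0.332, "N": 0.030, "O": 0.527,
                      "Na": 0.001, "P": 0.001, "S": 0.002, "Cl": 0.001},
    "eye_lens": {"H": 0.096, "C": 0.195, "N": 0.057, "O": 0.646,
                 "Na": 0.001, "P": 0.001, "S": 0.003, "Cl": 0.001},
    "lung_tissue": {"H": 0.103, "C": 0.105, "N": 0.031, "O": 0.749,
                    "Na": 0.002, "P": 0.002, "S": 0.003, "Cl": 0.003,
                    "K": 0.002},
    "skeletal_muscle": {"H": 0.102, "C": 0.143, "N": 0.034, "O": 0.710,
                        "Na": 0.001, "P": 0.002, "S": 0.003, "Cl": 0.001,
                        "K": 0.004},
    "ovary": {"H": 0.105, "C": 0.093, "N": 0.024, "O": 0.768, "Na": 0.002,
              "P": 0.002, "S": 0.002, "Cl": 0.002, "K": 0.002},
    "testis": {"H": 0.106, "C": 0.099, "N": 0.020, "O": 0.766, "Na": 0.002,
               "P": 0.001, "S": 0.002, "Cl": 0.002, "K": 0.002},
    "soft_tissue": {"H": 0.102, "C": 0.143, "N": 0.034, "O": 0.708,
                    "Na": 0.002, "P": 0.003, "S": 0.003, "Cl": 0.002,
                    "K": 0.003},
    "soft_tissue4": {"H": 0.101174, "C": 0.111, "N": 0.026, "O": 0.761826},
    "water": {"H": 0.111898, "O": 0.888102},
}

TISSUE_NAMES: tuple[str, ...] = tuple(n for n in _BUILTIN if n != "water")


def builtin_registry() -> dict[str, Material]:
    """The 12 built-in organ/tissue compositions plus water, by name."""
    return {
        name: Material(
            name, tuple((SYMBOL_TO_Z[s.lower()], w) for s, w in comp.items())
        )
        for name, comp in _BUILTIN.items()
    }


def get_material(name_or_path: str) -> Material:
    """Resolve a registry name or a composition-file path to a Material."""
    reg = builtin_registry()
    if name_or_path in reg:
        return reg[name_or_path]
    try:
        with open(name_or_path, encoding="utf-8") as fh:
            text = fh.read()
    except OSError:
        raise CompositionError(
            f"{name_or_path!r} is neither a registry name "
            f"({', '.join(sorted(reg))}) nor a readable composition file"
        ) from None
    import os

    stem = os.path.splitext(os.path.basename(name_or_path))[0]
    return parse_composition(text, name=stem)
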