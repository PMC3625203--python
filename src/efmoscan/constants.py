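"""Physical constants, unit conversions and element tables.

All unit conversions used anywhere in the package come from this module so
that energies and distances are reproducible bit-for-bit.  User-facing
coordinates are in Angstrom; everything inside the energy machinery is in
hartree and bohr.
"""

from __future__ import annotations

from scipy import constants as _sc

# CODATA (via scipy.constants)
BOHR_TO_ANGSTROM: float = _sc.physical_constants["Bohr radius"][0] * 1e10
ANGSTROM_TO_BOHR: float = 1.0 / BOHR_TO_ANGSTROM
HARTREE_TO_KCALMOL: float = (
    _sc.physical_constants["Hartree energy"][0] * _sc.Avogadro / _sc.calorie / 1000.0
)
KCALMOL_TO_HARTREE: float = 1.0 / HARTREE_TO_KCALMOL

# Bondi van der Waals radii, Angstrom.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "He": 1.40,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "Ne": 1.54,
    "Na": 2.27,
    "Mg": 1.73,
    "Si": 2.10,
    "P": 1.80,
    "S": 1.80,
    "Cl": 1.75,
    "Ar": 1.88,
    "K": 2.75,
    "Ca": 2.31,
    "Br": 1.85,
    "I": 1.98,
    "Zn": 1.39,
    "Fe": 2.00,
}

# Pyykko & Atsumi single-bond covalent radii, Angstrom.
COVALENT_RADII: dict[str, float] = {
    "H": 0.32,
    "He": 0.46,
    "Li": 1.33,
    "Be": 1.02,
    "B": 0.85,
    "C": 0.75,
    "N": 0.71,
    "O": 0.63,
    "F": 0.64,
    "Ne": 0.67,
    "Na": 1.55,
    "Mg": 1.39,
    "Si": 1.16,
    "P": 1.11,
    "S": 1.03,
    "Cl": 0.99,
    "K": 1.96,
    "Ca": 1.71,
    "Fe": 1.16,
    "Zn": 1.18,
    "Br": 1.14,
    "I": 1.33,
}

KNOWN_ELEMENTS = frozenset(VDW_RADII) & frozenset(COVALENT_RADII)


def vdw_radius(element: str) -> float:
    """Bondi van der Waals radius in Angstrom."""
    try:
        return VDW_RADII[element]
    except KeyError:
        raise KeyError(f"no van der Waals radius tabulated for element {element!r}")


def covalent_radius(element: str) -> float:
    """Pyykko covalent radius in Angstrom."""
    try:
        return COVALENT_RADII[element]
    except KeyError:
        raise KeyError(f"no covalent radius tabulated for element {element!r}")
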