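"""Embedded periodic-table data used throughout the package.

Atomic masses are the IUPAC/CIAAW 2021 standard atomic weights
(abridged to four decimals).  Covalent radii follow Cordero et al.,
Dalton Trans. 2008 (single-bond values); van der Waals radii follow
Bondi, J. Phys. Chem. 1964, with the revised H value of Rowland &
Taylor 1996.  All radii in angstroms.

The table deliberately covers only the elements that occur in organic
and main-group supramolecular building blocks; asking for anything
else raises ``KeyError`` rather than silently guessing.
"""

from __future__ import annotations

#: element symbol -> (mass / u, covalent radius / A, vdW radius / A)
_TABLE: dict[str, tuple[float, float, float]] = {
    "H":  (1.008,   0.31, 1.10),
    "He": (4.0026,  0.28, 1.40),
    "Li": (6.94,    1.28, 1.81),
    "Be": (9.0122,  0.96, 1.53),
    "B":  (10.81,   0.84, 1.92),
    "C":  (12.011,  0.76, 1.70),
    "N":  (14.007,  0.71, 1.55),
    "O":  (15.999,  0.66, 1.52),
    "F":  (18.998,  0.57, 1.47),
    "Ne": (20.180,  0.58, 1.54),
    "Na": (22.990,  1.66, 2.27),
    "Mg": (24.305,  1.41, 1.73),
    "Al": (26.982,  1.21, 1.84),
    "Si": (28.085,  1.11, 2.10),
    "P":  (30.974,  1.07, 1.80),
    "S":  (32.06,   1.05, 1.80),
    "Cl": (35.45,   1.02, 1.75),
    "Ar": (39.95,   1.06, 1.88),
    "K":  (39.098,  2.03, 2.75),
    "Ca": (40.078,  1.76, 2.31),
    "Zn": (65.38,   1.22, 1.39),
    "Ga": (69.723,  1.22, 1.87),
    "Ge": (72.630,  1.20, 2.11),
    "As": (74.922,  1.19, 1.85),
    "Se": (78.971,  1.20, 1.90),
    "Br": (79.904,  1.20, 1.85),
    "Kr": (83.798,  1.16, 2.02),
    "Sn": (118.71,  1.39, 2.17),
    "Sb": (121.76,  1.39, 2.06),
    "Te": (127.60,  1.38, 2.06),
    "I":  (126.90,  1.39, 1.98),
    "Xe": (131.29,  1.40, 2.16),
}

ELEMENTS = frozenset(_TABLE)


def atomic_mass(element: str) -> float:
    """Standard atomic weight of *element* in unified mass units."""
    return _TABLE[element][0]


def covalent_radius(element: str) -> float:
    """Single-bond covalent radius of *element* in angstroms."""
    return _TABLE[element][1]


def vdw_radius(element: str) -> float:
    """Van der Waals radius of *element* in angstroms."""
    return _TABLE[element][2]


def is_known_element(element: str) -> bool:
    return element in _TABLE
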