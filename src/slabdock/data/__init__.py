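"""Versioned static data tables: radii, atomic masses, oxidation states."""

from __future__ import annotations

from importlib import resources

DATA_VERSION = "2025.1"

#: Standard atomic weights (IUPAC 2021 abridged), g/mol.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "He": 4.0026, "Li": 6.94, "Be": 9.0122, "B": 10.81,
    "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998, "Ne": 20.180,
    "Na": 22.990, "Mg": 24.305, "Al": 26.982, "Si": 28.085, "P": 30.974,
    "S": 32.06, "Cl": 35.45, "Ar": 39.95, "K": 39.098, "Ca": 40.078,
    "Sc": 44.956, "Ti": 47.867, "V": 50.942, "Cr": 51.996, "Mn": 54.938,
    "Fe": 55.845, "Co": 58.933, "Ni": 58.693, "Cu": 63.546, "Zn": 65.38,
    "Ga": 69.723, "Ge": 72.630, "As": 74.922, "Se": 78.971, "Br": 79.904,
    "Kr": 83.798, "Rb": 85.468, "Sr": 87.62, "Y": 88.906, "Zr": 91.224,
    "Nb": 92.906, "Mo": 95.95, "Ru": 101.07, "Rh": 102.91, "Pd": 106.42,
    "Ag": 107.87, "Cd": 112.41, "In": 114.82, "Sn": 118.71, "Sb": 121.76,
    "Te": 127.60, "I": 126.90, "Xe": 131.29, "Cs": 132.91, "Ba": 137.33,
}

#: Common oxidation states per element, most probable first.  The order is
#: the preference order used when several charge-neutral assignments exist.
OXIDATION_STATES: dict[str, tuple[int, ...]] = {
    "H": (1, -1),
    "Li": (1,), "Na": (1,), "K": (1,), "Rb": (1,), "Cs": (1,),
    "Be": (2,), "Mg": (2,), "Ca": (2,), "Sr": (2,), "Ba": (2,),
    "Zn": (2,), "Cd": (2,),
    "B": (3,), "Al": (3,), "Ga": (3,), "In": (3,),
    "Sc": (3,), "Y": (3,),
    "C": (4, -4, 2), "Si": (4, -4), "Ge": (4, 2), "Sn": (4, 2),
    "N": (-3, 5, 3), "P": (5, 3, -3), "As": (3, 5, -3), "Sb": (3, 5, -3),
    "O": (-2,), "S": (-2, 6, 4), "Se": (-2, 4, 6), "Te": (-2, 4, 6),
    "F": (-1,), "Cl": (-1, 5, 7), "Br": (-1, 5, 7), "I": (-1, 5, 7),
    "Ti": (4, 3), "Zr": (4,), "V": (5, 4, 3), "Nb": (5,),
    "Cr": (3, 6, 2), "Mo": (6, 4), "Mn": (2, 4, 7),
    "Fe": (3, 2), "Co": (2, 3), "Ni": (2,), "Cu": (2, 1),
    "Ag": (1,), "Pd": (2,),
}


def _read_radius_file(name: str) -> dict[str, float]:
    table: dict[str, float] = {}
    text = resources.files(__package__).joinpath(name).read_text()
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        element, value = line.split()
        table[element] = float(value)
    return table


def load_vdw_radii() -> dict[str, float]:
    """Crystallographic van der Waals radii (Alvarez 2013), Å."""
    return _read_radius_file("vdw_radii.txt")


def load_covalent_radii() -> dict[str, float]:
    """Single-bond covalent radii (Cordero 2008), Å."""
    return _read_radius_file("covalent_radii.txt")
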