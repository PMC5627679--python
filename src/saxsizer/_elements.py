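"""Minimal atomic data for X-ray scattering-length-density calculations.

Atomic numbers and standard atomic weights (IUPAC 2021, conventional values)
for the elements likely to appear in nanoparticle/solvent formulas. Electron
counts are the non-anomalous Z; dispersion corrections are out of scope.
"""

from __future__ import annotations

import re

# symbol -> (atomic number Z, atomic weight g/mol)
ATOMIC_DATA: dict[str, tuple[int, float]] = {
    "H": (1, 1.008),
    "D": (1, 2.014),
    "He": (2, 4.0026),
    "Li": (3, 6.94),
    "B": (5, 10.81),
    "C": (6, 12.011),
    "N": (7, 14.007),
    "O": (8, 15.999),
    "F": (9, 18.998),
    "Na": (11, 22.990),
    "Mg": (12, 24.305),
    "Al": (13, 26.982),
    "Si": (14, 28.085),
    "P": (15, 30.974),
    "S": (16, 32.06),
    "Cl": (17, 35.45),
    "K": (19, 39.098),
    "Ca": (20, 40.078),
    "Ti": (22, 47.867),
    "Cr": (24, 51.996),
    "Mn": (25, 54.938),
    "Fe": (26, 55.845),
    "Co": (27, 58.933),
    "Ni": (28, 58.693),
    "Cu": (29, 63.546),
    "Zn": (30, 65.38),
    "Se": (34, 78.971),
    "Br": (35, 79.904),
    "Zr": (40, 91.224),
    "Mo": (42, 95.95),
    "Pd": (46, 106.42),
    "Ag": (47, 107.8682),
    "Cd": (48, 112.414),
    "Sn": (50, 118.710),
    "I": (53, 126.904),
    "Ba": (56, 137.327),
    "Pt": (78, 195.084),
    "Au": (79, 196.967),
    "Pb": (82, 207.2),
}

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*\.?\d*)")


def parse_formula(formula: str) -> dict[str, float]:
    """Parse a simple chemical formula (no parentheses) into element counts.

    >>> parse_formula("H2O")
    {'H': 2.0, 'O': 1.0}
    """
    counts: dict[str, float] = {}
    pos = 0
    for match in _TOKEN.finditer(formula):
        if match.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
        pos = match.end()
        symbol, number = match.groups()
        if symbol not in ATOMIC_DATA:
            raise ValueError(f"unknown element symbol {symbol!r} in formula {formula!r}")
        counts[symbol] = counts.get(symbol, 0.0) + (float(number) if number else 1.0)
    if pos != len(formula) or not counts:
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


def electrons_and_mass(formula: str) -> tuple[float, float]:
    """Total electron count and molar mass (g/mol) of one formula unit."""
    counts = parse_formula(formula)
    electrons = sum(n * ATOMIC_DATA[sym][0] for sym, n in counts.items())
    mass = sum(n * ATOMIC_DATA[sym][1] for sym, n in counts.items())
    return electrons, mass
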