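"""Minimal element table: symbol -> (mass in u, atomic number).

Covers the species that occur in phosphatidylcholine bilayers with water and
the common monovalent/divalent salts. Electron counts default to the atomic
number of the neutral atom; formal ion charges are a topology concern.
"""

from __future__ import annotations

ELEMENTS: dict[str, tuple[float, int]] = {
    "H": (1.008, 1),
    "C": (12.011, 6),
    "N": (14.007, 7),
    "O": (15.999, 8),
    "F": (18.998, 9),
    "Na": (22.990, 11),
    "Mg": (24.305, 12),
    "P": (30.974, 15),
    "S": (32.06, 16),
    "Cl": (35.45, 17),
    "K": (39.098, 19),
    "Ca": (40.078, 20),
    "Br": (79.904, 35),
    "I": (126.904, 53),
    "Cs": (132.905, 55),
}

# Common MD ion atom names that do not parse as element symbols.
ION_NAMES: dict[str, str] = {
    "SOD": "Na",
    "NA": "Na",
    "NA+": "Na",
    "CLA": "Cl",
    "CL": "Cl",
    "CL-": "Cl",
    "POT": "K",
    "K+": "K",
    "CAL": "Ca",
    "CA2+": "Ca",
    "MG": "Mg",
    "MG2+": "Mg",
    "CES": "Cs",
}


def element_from_name(name: str, is_lipid: bool) -> str:
    """Infer the chemical element from an MD atom name.

    For lipid atoms the leading letter decides (POPC names are like C12,
    H11A, O13, P, N); for solvent/ion atoms the ion-name dictionary is
    consulted first so that e.g. "CAL" resolves to calcium, not carbon.
    """
    clean = name.strip().upper()
    if not is_lipid:
        if clean in ION_NAMES:
            return ION_NAMES[clean]
        two = clean[:2].capitalize()
        if two in ELEMENTS:
            return two
    first = clean[0]
    if first in ELEMENTS:
        return first
    raise KeyError(f"cannot infer element from atom name {name!r}")


def mass_of(element: str) -> float:
    return ELEMENTS[element][0]


def electrons_of(element: str) -> int:
    return ELEMENTS[element][1]
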