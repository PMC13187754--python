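"""Physical constants and element data shared across the package."""

# Gas constant in kcal mol^-1 K^-1 (single source of truth; energies are kcal/mol).
R_KCAL = 1.9872e-3

#: Bondi van-der-Waals radii (angstrom) for the elements that occur in
#: drug-like ketone substrates.
BONDI_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "Cl": 1.75,
    "Br": 1.85,
    "I": 1.98,
    "Si": 2.10,
    "B": 1.92,
}

#: Single-bond covalent radii (angstrom), used only to infer connectivity
#: from 3D coordinates (bond if d < 1.3 * (r_i + r_j)).
COVALENT_RADII = {
    "H": 0.31,
    "C": 0.76,
    "N": 0.71,
    "O": 0.66,
    "F": 0.57,
    "P": 1.07,
    "S": 1.05,
    "Cl": 1.02,
    "Br": 1.20,
    "I": 1.39,
    "Si": 1.11,
    "B": 0.84,
}


def vdw_radius(element: str) -> float:
    try:
        return BONDI_RADII[element]
    except KeyError:
        raise KeyError(f"no van-der-Waals radius tabulated for element {element!r}")


def covalent_radius(element: str) -> float:
    try:
        return COVALENT_RADII[element]
    except KeyError:
        raise KeyError(f"no covalent radius tabulated for element {element!r}")
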