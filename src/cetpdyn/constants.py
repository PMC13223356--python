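"""Physical constants, unit conversions and small lookup tables.

Internal unit conventions used throughout the package:

* lengths in nm (PDB Angstrom coordinates are converted on load),
* times in ps,
* energies in kcal/mol (kJ/mol accepted on input and divided by 4.184).
"""

from __future__ import annotations

from pathlib import Path

#: Boltzmann constant in kcal/mol/K.
KB_KCAL = 0.0019872041

#: kJ per kcal.
KJ_PER_KCAL = 4.184

#: Angstrom per nm.
A_PER_NM = 10.0


def kjmol_to_kcalmol(x: float) -> float:
    return x / KJ_PER_KCAL


def kt_kcal(temperature_k: float) -> float:
    """Thermal energy kB*T in kcal/mol."""
    return KB_KCAL * temperature_k


#: Van der Waals radii per element, nm.  Conventional values; used by the
#: tunnel volume grid.  Elements not listed fall back to carbon.
ATOM_RADII_NM = {
    "C": 0.170,
    "N": 0.155,
    "O": 0.152,
    "S": 0.180,
    "P": 0.180,
    "H": 0.120,
}

DEFAULT_ATOM_RADIUS_NM = 0.170

#: Default water-probe radius for cavity detection, nm.
DEFAULT_PROBE_RADIUS_NM = 0.14


def atom_radius_nm(element: str) -> float:
    return ATOM_RADII_NM.get(element.upper(), DEFAULT_ATOM_RADIUS_NM)


_DATA_DIR = Path(__file__).parent / "data"


def load_hydrophobicity_scale(path: str | Path | None = None) -> dict[str, float]:
    """Load a residue->hydrophobicity map from a two-column text file.

    Lines are ``RESNAME value``; '#' starts a comment.  With no argument the
    shipped Kyte-Doolittle scale is returned.
    """
    p = Path(path) if path is not None else _DATA_DIR / "kyte_doolittle.txt"
    scale: dict[str, float] = {}
    for raw in p.read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        name, value = line.split()
        scale[name.upper()] = float(value)
    if not scale:
        raise ValueError(f"empty hydrophobicity scale file: {p}")
    return scale
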