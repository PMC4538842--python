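"""Idealized base geometries in the standard base reference frame.

Each base is tabulated with its ring atoms (plus the glycosidic C1′) in
the standard coordinate frame used for nucleic-acid conformational
analysis: the origin sits in the base-pair plane, x points toward the
major groove, y runs along the long base-pair axis toward the sugar of
the leading strand, and z is the stacking normal.  These constants are
shared by the duplex builders and the base-frame fitting, which makes
the two exact inverses of each other.
"""

from __future__ import annotations

import numpy as np

# ring atoms used for least-squares frame fitting, in fixed order
PURINE_RING = ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4")
PYRIMIDINE_RING = ("N1", "C2", "N3", "C4", "C5", "C6")

# standard-reference-frame coordinates (Å); z = 0 for the planar rings
BASE_COORDS: dict[str, dict[str, tuple[float, float, float]]] = {
    "A": {
        "N9": (-1.291, 4.498, 0.000),
        "C8": (0.024, 4.897, 0.000),
        "N7": (0.877, 3.902, 0.000),
        "C5": (0.071, 2.771, 0.000),
        "C6": (0.369, 1.398, 0.000),
        "N6": (1.611, 0.909, 0.000),
        "N1": (-0.668, 0.532, 0.000),
        "C2": (-1.912, 1.023, 0.000),
        "N3": (-2.320, 2.290, 0.000),
        "C4": (-1.267, 3.124, 0.000),
        "C1'": (-2.479, 5.346, 0.000),
    },
    "G": {
        "N9": (-1.289, 4.551, 0.000),
        "C8": (0.023, 4.962, 0.000),
        "N7": (0.870, 3.969, 0.000),
        "C5": (0.071, 2.833, 0.000),
        "C6": (0.424, 1.460, 0.000),
        "O6": (1.554, 0.955, 0.000),
        "N1": (-0.700, 0.641, 0.000),
        "C2": (-1.999, 1.087, 0.000),
        "N2": (-2.949, 0.139, -0.001),
        "N3": (-2.342, 2.364, 0.001),
        "C4": (-1.265, 3.177, 0.000),
        "C1'": (-2.477, 5.399, 0.000),
    },
    "C": {
        "N1": (-1.285, 4.542, 0.000),
        "C2": (-1.472, 3.158, 0.000),
        "O2": (-2.628, 2.709, 0.001),
        "N3": (-0.391, 2.344, 0.000),
        "C4": (0.837, 2.868, 0.000),
        "N4": (1.875, 2.027, 0.001),
        "C5": (1.056, 4.275, 0.000),
        "C6": (-0.023, 5.068, 0.000),
        "C1'": (-2.477, 5.402, 0.000),
    },
    "T": {
        "N1": (-1.284, 4.500, 0.000),
        "C2": (-1.462, 3.135, 0.000),
        "O2": (-2.562, 2.608, 0.000),
        "N3": (-0.298, 2.407, 0.000),
        "C4": (0.994, 2.897, 0.000),
        "O4": (1.944, 2.119, 0.000),
        "C5": (1.106, 4.338, 0.000),
        "C7": (2.466, 4.961, 0.001),
        "C6": (-0.024, 5.057, 0.000),
        "C1'": (-2.481, 5.354, 0.000),
    },
}
BASE_COORDS["U"] = {
    k: v for k, v in BASE_COORDS["T"].items() if k != "C7"
}

_RESNAME_ALIASES = {
    "A": "A", "DA": "A", "ADE": "A", "RA": "A",
    "G": "G", "DG": "G", "GUA": "G", "RG": "G",
    "C": "C", "DC": "C", "CYT": "C", "RC": "C",
    "T": "T", "DT": "T", "THY": "T",
    "U": "U", "RU": "U", "URA": "U",
}

COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G", "U": "A"}


def base_code(resname: str) -> str:
    """One-letter base code for a residue name (DA, GUA, C, …)."""
    code = _RESNAME_ALIASES.get(resname.strip().upper())
    if code is None:
        raise KeyError(f"unknown nucleotide residue name {resname!r}")
    return code


def ring_atom_names(code: str) -> tuple[str, ...]:
    return PURINE_RING if code in ("A", "G") else PYRIMIDINE_RING


def ring_coords(code: str) -> np.ndarray:
    """Reference ring-atom coordinates, ordered as :func:`ring_atom_names`."""
    table = BASE_COORDS[code]
    return np.array([table[a] for a in ring_atom_names(code)], dtype=float)


def all_atom_names(code: str) -> tuple[str, ...]:
    return tuple(BASE_COORDS[code])


def all_coords(code: str) -> np.ndarray:
    return np.array(list(BASE_COORDS[code].values()), dtype=float)
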