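"""Residue chemistry templates and per-element parameter tables.

The package supports a compact set of amino-acid residues sufficient to build
synthetic helix-bundle dimers with hydrogen-bond donors/acceptors and
hydrophobic side chains.  Unknown residues in parsed structures are excluded
from the chemistry tables (with a warning), never from the coordinates.

Conventions
-----------
* Donors are (heavy atom, attached hydrogen) pairs; the backbone amide N-H is
  a donor for every residue except at a chain N-terminus without an H.
* Acceptors are N/O heavy atoms with a lone pair (backbone carbonyl O plus
  side-chain O/S as listed).
* Hydrophobic atoms are the side-chain carbon and sulfur atoms of *all*
  residues, regardless of residue polarity: occupancy analyses count contacts
  through aliphatic segments of polar residues too.
"""

from __future__ import annotations

# Bondi van der Waals radii, Angstrom.
VDW_RADII = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.20,
}

SUPPORTED_ELEMENTS = frozenset(VDW_RADII)

# Atomic solvation parameters, kcal/(mol * A^2), Eisenberg-McLachlan style:
# apolar atoms gain free energy on burial, polar atoms pay a small penalty.
# Hydrogens carry no independent term (their area rides on the heavy atom).
SOLVATION_SIGMA = {
    "C": 0.016,
    "S": 0.021,
    "N": -0.006,
    "O": -0.006,
    "H": 0.0,
}

BACKBONE_ATOMS = ("N", "CA", "C", "O")

# Per-residue side-chain templates.  Each entry:
#   atoms: ordered side-chain atom names (element inferred from first letter,
#          two-letter names like "SG" are sulfur/oxygen by leading letter)
#   donors: side-chain (heavy, hydrogen) pairs
#   acceptors: side-chain acceptor heavy atoms
RESIDUE_TEMPLATES = {
    "GLY": {"atoms": (), "donors": (), "acceptors": ()},
    "ALA": {"atoms": ("CB",), "donors": (), "acceptors": ()},
    "VAL": {"atoms": ("CB", "CG1", "CG2"), "donors": (), "acceptors": ()},
    "LEU": {"atoms": ("CB", "CG", "CD1", "CD2"), "donors": (), "acceptors": ()},
    "SER": {"atoms": ("CB", "OG", "HG"), "donors": (("OG", "HG"),), "acceptors": ("OG",)},
    "CYS": {"atoms": ("CB", "SG"), "donors": (), "acceptors": ()},
    "MET": {"atoms": ("CB", "CG", "SD", "CE"), "donors": (), "acceptors": ()},
}

SUPPORTED_RESIDUES = frozenset(RESIDUE_TEMPLATES)

ONE_TO_THREE = {
    "G": "GLY", "A": "ALA", "V": "VAL", "L": "LEU",
    "S": "SER", "C": "CYS", "M": "MET",
}


def element_of(atom_name: str) -> str:
    """Infer the element symbol from a PDB-style atom name."""
    name = atom_name.strip()
    if name.startswith(("1", "2", "3")):
        name = name[1:]
    sym = name[0].upper()
    if sym not in SUPPORTED_ELEMENTS:
        raise ValueError(f"cannot infer a supported element from atom name {atom_name!r}")
    return sym


def is_hydrophobic_atom(residue_name: str, atom_name: str) -> bool:
    """Side-chain C or S atoms of any residue count as hydrophobic."""
    if atom_name in BACKBONE_ATOMS or atom_name in ("H", "HG"):
        return False
    return element_of(atom_name) in ("C", "S")
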