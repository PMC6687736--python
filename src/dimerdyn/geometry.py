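"""Internal-coordinate geometry: peptide-chain construction and superposition.

Chains are built atom-by-atom with the natural extension reference frame
(NeRF): each new atom is placed from three previously placed atoms given a
bond length, bond angle and torsion.  Ideal bond geometry (Engh-Huber-like
values) is used throughout; an alpha-helix built with phi/psi = (-57, -47)
degrees has a rise of ~1.5 A per residue and ~3.6 residues per turn.
"""

from __future__ import annotations

import numpy as np

from .chemistry import RESIDUE_TEMPLATES

# Ideal backbone geometry (lengths in Angstrom, angles in degrees).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_N_H = 1.010
BOND_CA_CB = 1.530
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
ANGLE_C_N_H = 119.0

HELIX_PHI_PSI = (-57.0, -47.0)
EXTENDED_PHI_PSI = (180.0, 180.0)


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D given atoms A-B-C, |CD|, angle(BCD) and torsion(ABCD)."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(torsion),
        bond * np.sin(angle) * np.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _sidechain_coords(res_name: str, n: np.ndarray, ca: np.ndarray,
                      c: np.ndarray) -> dict[str, np.ndarray]:
    """Idealized side-chain atom positions for the supported residues."""
    out: dict[str, np.ndarray] = {}
    atoms = RESIDUE_TEMPLATES[res_name]["atoms"]
    if not atoms:
        return out
    cb = place_atom(n, c, ca, BOND_CA_CB, 110.5, 122.5)
    out["CB"] = cb
    if res_name == "ALA":
        return out
    if res_name == "VAL":
        out["CG1"] = place_atom(n, ca, cb, 1.53, 110.5, -60.0)
        out["CG2"] = place_atom(n, ca, cb, 1.53, 110.5, 60.0)
    elif res_name == "LEU":
        cg = place_atom(n, ca, cb, 1.53, 114.0, -60.0)
        out["CG"] = cg
        out["CD1"] = place_atom(ca, cb, cg, 1.53, 110.5, 180.0)
        out["CD2"] = place_atom(ca, cb, cg, 1.53, 110.5, 60.0)
    elif res_name == "SER":
        og = place_atom(n, ca, cb, 1.417, 110.8, 60.0)
        out["OG"] = og
        out["HG"] = place_atom(ca, cb, og, 0.96, 109.5, 180.0)
    elif res_name == "CYS":
        out["SG"] = place_atom(n, ca, cb, 1.808, 113.8, -60.0)
    elif res_name == "MET":
        cg = place_atom(n, ca, cb, 1.52, 114.0, -60.0)
        out["CG"] = cg
        sd = place_atom(ca, cb, cg, 1.803, 112.7, 180.0)
        out["SD"] = sd
        out["CE"] = place_atom(cb, cg, sd, 1.791, 100.9, 180.0)
    return out


def amide_hydrogen(n: np.ndarray, ca: np.ndarray, c_prev: np.ndarray) -> np.ndarray:
    """Amide H on the bisector opposite the two N neighbours (DSSP convention)."""
    u = n - c_prev
    u /= np.linalg.norm(u)
    v = n - ca
    v /= np.linalg.norm(v)
    w = u + v
    w /= np.linalg.norm(w)
    return n + BOND_N_H * w


def build_chain(sequence: list[str], phi_psi: list[tuple[float, float]],
                ) -> list[dict[str, np.ndarray]]:
    """Build a peptide chain from per-residue (phi, psi); omega fixed at 180.

    Returns one dict of atom-name -> position per residue (N, CA, C, O,
    amide H where defined, plus side-chain atoms from the templates).
    """
    if len(sequence) != len(phi_psi):
        raise ValueError("sequence and phi/psi lists differ in length")
    residues: list[dict[str, np.ndarray]] = []
    # Seed frame for the first residue.
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([BOND_N_CA, 0.0, 0.0])
    c = place_atom(np.array([-1.0, 1.0, 0.0]), n, ca,
                   BOND_CA_C, ANGLE_N_CA_C, phi_psi[0][0])
    prev = {"N": n, "CA": ca, "C": c}
    for i, (res_name, (phi, psi)) in enumerate(zip(sequence, phi_psi)):
        if i > 0:
            n = place_atom(prev["N"], prev["CA"], prev["C"],
                           BOND_C_N, ANGLE_CA_C_N, prev_psi)
            ca = place_atom(prev["CA"], prev["C"], n,
                            BOND_N_CA, ANGLE_C_N_CA, 180.0)  # omega
            c = place_atom(prev["C"], n, ca, BOND_CA_C, ANGLE_N_CA_C, phi)
        res = {"N": n, "CA": ca, "C": c}
        res.update(_sidechain_coords(res_name, n, ca, c))
        if i > 0:
            res["H"] = amide_hydrogen(n, ca, prev["C"])
        residues.append(res)
        prev = res
        prev_psi = psi
    # Carbonyl oxygens need the next residue's N; the last one uses psi.
    for i, res in enumerate(residues):
        if i + 1 < len(residues):
            n_next = residues[i + 1]["N"]
            res["O"] = place_atom(n_next, res["CA"], res["C"],
                                  BOND_C_O, ANGLE_CA_C_O, 180.0)
        else:
            res["O"] = place_atom(res["N"], res["CA"], res["C"],
                                  BOND_C_O, ANGLE_CA_C_O, phi_psi[i][1] + 180.0)
    return residues


def kabsch(mobile: np.ndarray, reference: np.ndarray,
           ) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of `mobile` onto `reference`.

    Returns (rotation, translation, rmsd) such that
    ``mobile @ rotation.T + translation`` best fits `reference`; the rotation
    is proper (det = +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2:
        raise ValueError("coordinate sets must share the same (n, 3) shape")
    mu_m = mobile.mean(axis=0)
    mu_r = reference.mean(axis=0)
    x = mobile - mu_m
    y = reference - mu_r
    h = x.T @ y
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    flip = np.diag([1.0, 1.0, d])
    rot = vt.T @ flip @ u.T
    fitted = x @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - y) ** 2, axis=1))))
    return rot, mu_r - mu_m @ rot.T, rmsd


def apply_transform(coords: np.ndarray, rot: np.ndarray, trans: np.ndarray) -> np.ndarray:
    return coords @ rot.T + trans
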