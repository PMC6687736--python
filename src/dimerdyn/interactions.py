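"""Hydrogen-bond and hydrophobic-contact occupancy over a stable window.

Occupancy is the percentage of analyzed frames in which an interaction
satisfies its geometric criteria:

* hydrogen bond: donor-acceptor distance <= 3.2 A *and* donor-hydrogen-
  acceptor angle >= 120 degrees,
* hydrophobic contact: the minimum distance between the two residues'
  side-chain C/S atom sets lies within [3.5, 5.5] A.

Atom-level hydrogen bonds are aggregated to residue pairs by the maximum
occupancy over atom pairs (residue-pair tables are what the field reports);
the union-of-frames alternative is not the default.  The census counts
contacts between the four central helices and summarizes whether helix A1
reaches both B1 and B2 (the interface "balance" criterion) or only one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stability import StableWindow
from .structures import HelixSet, Trajectory
from .tables import OCCUPANCY_COLUMNS, validate_occupancy_table


@dataclass(frozen=True)
class HBondCriteria:
    max_donor_acceptor_distance: float = 3.2  # A
    min_dha_angle: float = 120.0              # degrees

    def __post_init__(self):
        if self.max_donor_acceptor_distance <= 0:
            raise ValueError("distance cutoff must be positive")
        if not 0 < self.min_dha_angle <= 180:
            raise ValueError("angle cutoff must lie in (0, 180]")


@dataclass(frozen=True)
class HydrophobicCriteria:
    distance_range: tuple[float, float] = (3.5, 5.5)  # A

    def __post_init__(self):
        lo, hi = self.distance_range
        if not 0 < lo < hi:
            raise ValueError("need 0 < min < max distance")


# strength vocabulary thresholds (percent occupancy)
STRONG_MIN = 50.0
MEDIUM_MIN = 20.0


def strength_label(occupancy_percent: float,
                   strong_min: float = STRONG_MIN,
                   medium_min: float = MEDIUM_MIN) -> str:
    """Qualitative persistence label: strong / medium / periodic / absent."""
    x = float(occupancy_percent)
    if not 0 <= x <= 100:
        raise ValueError(f"occupancy {x} outside [0, 100]")
    if x >= strong_min:
        return "strong"
    if x >= medium_min:
        return "medium"
    if x > 0:
        return "periodic"
    return "absent"


def _window_frames(traj: Trajectory, window: StableWindow | None) -> np.ndarray:
    if window is None:
        return traj.coords
    idx = window.frame_indices()
    if len(idx) == 0:
        raise ValueError("empty stable window")
    if idx[-1] >= traj.n_frames:
        raise ValueError("window exceeds trajectory length")
    return traj.coords[idx]


def _restrict(indices: np.ndarray, resid: np.ndarray,
              selection_residues) -> np.ndarray:
    if selection_residues is None:
        return indices
    sel = set(int(r) for r in selection_residues)
    keep = np.array([int(r) in sel for r in resid])
    return indices[keep]


def hbond_occupancy(traj: Trajectory, window: StableWindow | None = None,
                    criteria: HBondCriteria = HBondCriteria(),
                    selection_residues=None,
                    min_occupancy_percent: float = 0.0,
                    frame_chunk: int = 200) -> pd.DataFrame:
    """Residue-pair hydrogen-bond occupancy table over the window.

    Donor/acceptor candidates come from the topology chemistry tables;
    same-residue pairs are excluded.  The donor-acceptor distance screens
    all pairs; the D-H-A angle is evaluated only for candidates inside the
    distance cutoff.  Rows with occupancy at or below
    `min_occupancy_percent` (default: only exact zeros) are dropped.
    """
    topo = traj.topology
    if len(topo.donor_table) == 0 or len(topo.acceptor_table) == 0:
        return _empty_table()
    frames = _window_frames(traj, window)
    donors = _restrict(np.arange(len(topo.donor_table)),
                       topo.dimer_resid[topo.donor_table[:, 0]],
                       selection_residues)
    acceptors = _restrict(np.arange(len(topo.acceptor_table)),
                          topo.dimer_resid[topo.acceptor_table],
                          selection_residues)
    if len(donors) == 0 or len(acceptors) == 0:
        return _empty_table()
    d_idx = topo.donor_table[donors, 0]
    h_idx = topo.donor_table[donors, 1]
    a_idx = topo.acceptor_table[acceptors]
    d_res = topo.dimer_resid[d_idx]
    a_res = topo.dimer_resid[a_idx]
    same = d_res[:, None] == a_res[None, :]
    n_frames = len(frames)
    counts = np.zeros((len(d_idx), len(a_idx)), dtype=int)
    for lo in range(0, n_frames, frame_chunk):
        f = frames[lo:lo + frame_chunk]
        D, H, A = f[:, d_idx], f[:, h_idx], f[:, a_idx]
        da = np.linalg.norm(D[:, :, None, :] - A[:, None, :, :], axis=3)
        da[:, same] = np.inf
        ft, dt, at = np.nonzero(da <= criteria.max_donor_acceptor_distance)
        if len(ft) == 0:
            continue
        hd = D[ft, dt] - H[ft, dt]
        ha = A[ft, at] - H[ft, dt]
        cosang = np.einsum("ij,ij->i", hd, ha) / (
            np.linalg.norm(hd, axis=1) * np.linalg.norm(ha, axis=1))
        ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        ok = ang >= criteria.min_dha_angle
        np.add.at(counts, (dt[ok], at[ok]), 1)
    best: dict[tuple[int, int], int] = {}
    for di, ai in zip(*np.nonzero(counts)):
        pair = tuple(sorted((int(d_res[di]), int(a_res[ai]))))
        if counts[di, ai] > best.get(pair, 0):
            best[pair] = int(counts[di, ai])
    rows = [{"res1": p[0], "res2": p[1], "kind": "HB",
             "occupancy": 100.0 * c / n_frames,
             "label": strength_label(100.0 * c / n_frames)}
            for p, c in best.items()]
    df = pd.DataFrame(rows, columns=OCCUPANCY_COLUMNS)
    df = df[df["occupancy"] > min_occupancy_percent] if len(df) else df
    return validate_occupancy_table(df) if len(df) else _empty_table()


def hydrophobic_occupancy(traj: Trajectory, window: StableWindow | None = None,
                          criteria: HydrophobicCriteria = HydrophobicCriteria(),
                          selection_residues=None,
                          min_occupancy_percent: float = 0.0,
                          frame_chunk: int = 64) -> pd.DataFrame:
    """Residue-pair hydrophobic-contact occupancy table.

    A residue pair counts in a frame iff the minimum distance over its
    side-chain C/S atoms lies within the criteria band.  Intra-residue and
    sequence-adjacent pairs (|delta local index| <= 1 within a chain) are
    excluded.
    """
    topo = traj.topology
    atoms = _restrict(topo.hydrophobic_atom_table,
                      topo.dimer_resid[topo.hydrophobic_atom_table],
                      selection_residues)
    if len(atoms) < 2:
        return _empty_table()
    frames = _window_frames(traj, window)
    n_frames = len(frames)
    resid = topo.dimer_resid[atoms]
    uniq = np.unique(resid)
    res_pos = {r: i for i, r in enumerate(uniq)}
    atom_res = np.array([res_pos[r] for r in resid])
    nr = len(uniq)
    lo_cut, hi_cut = criteria.distance_range
    counts = np.zeros((nr, nr), dtype=int)
    big = 1e9
    for lo in range(0, n_frames, frame_chunk):
        f = frames[lo:lo + frame_chunk][:, atoms]
        d = np.linalg.norm(f[:, :, None, :] - f[:, None, :, :], axis=3)
        # reduce atom-atom to residue-residue minima
        nf = d.shape[0]
        dmin = np.full((nf, nr, nr), big)
        np.minimum.at(dmin, (slice(None), atom_res[:, None], atom_res[None, :]), d)
        hit = (dmin >= lo_cut) & (dmin <= hi_cut)
        counts += hit.sum(axis=0)
    rows = []
    for i in range(nr):
        for j in range(i + 1, nr):
            cnt = max(counts[i, j], counts[j, i])
            if cnt == 0:
                continue
            ri, rj = int(uniq[i]), int(uniq[j])
            if _adjacent(topo, ri, rj):
                continue
            occ = 100.0 * cnt / n_frames
            rows.append({"res1": ri, "res2": rj, "kind": "HI",
                         "occupancy": occ, "label": strength_label(occ)})
    df = pd.DataFrame(rows, columns=OCCUPANCY_COLUMNS)
    df = df[df["occupancy"] > min_occupancy_percent] if len(df) else df
    return validate_occupancy_table(df) if len(df) else _empty_table()


def _adjacent(topo, res_i: int, res_j: int) -> bool:
    a = topo.residues[topo.residue_index(res_i)]
    b = topo.residues[topo.residue_index(res_j)]
    return a.chain_id == b.chain_id and abs(a.local_index - b.local_index) <= 1


def _empty_table() -> pd.DataFrame:
    df = pd.DataFrame(columns=OCCUPANCY_COLUMNS)
    return df


# ---------------------------------------------------------------------------
# Contact census
# ---------------------------------------------------------------------------

HELIX_PAIRS = (("A1", "A2"), ("A1", "B1"), ("A1", "B2"),
               ("A2", "B1"), ("A2", "B2"), ("B1", "B2"))
INTERSUBUNIT = {("A1", "B1"), ("A1", "B2"), ("A2", "B1"), ("A2", "B2")}


@dataclass
class ContactCensus:
    pair_counts: dict[tuple[str, str], int]
    total: int
    intersubunit: int
    a1_balance: str  # 'both' | 'B1' | 'B2' | 'undefined'

    def to_dict(self) -> dict:
        return {"pair_counts": {f"{a}-{b}": c for (a, b), c
                                in self.pair_counts.items()},
                "total": self.total, "intersubunit": self.intersubunit,
                "a1_balance": self.a1_balance}


def contact_census(hb_table: pd.DataFrame | None,
                   hi_table: pd.DataFrame | None,
                   helix_set: HelixSet,
                   occupancy_threshold_percent: float = 10.0) -> ContactCensus:
    """Count interactions between the four central helices.

    A row counts iff its occupancy reaches the threshold and both partners
    lie inside helices of the HelixSet.  Reports per-helix-pair counts, the
    total, the intersubunit subtotal, and whether A1's intersubunit contacts
    reach both B1 and B2 or only one of them.
    """
    frames = [t for t in (hb_table, hi_table) if t is not None and len(t)]
    rows = pd.concat(frames, ignore_index=True) if frames else _empty_table()
    counts = {pair: 0 for pair in HELIX_PAIRS}
    a1_targets = set()
    for _, row in rows.iterrows():
        if row["occupancy"] < occupancy_threshold_percent:
            continue
        s1 = helix_set.segment_of(int(row["res1"]))
        s2 = helix_set.segment_of(int(row["res2"]))
        if s1 is None or s2 is None or s1 == s2:
            continue
        pair = tuple(sorted((s1, s2)))
        counts[pair] += 1
        if "A1" in pair:
            other = pair[0] if pair[1] == "A1" else pair[1]
            if other in ("B1", "B2"):
                a1_targets.add(other)
    total = sum(counts.values())
    inter = sum(c for p, c in counts.items() if p in INTERSUBUNIT)
    if not a1_targets:
        balance = "undefined"
    elif a1_targets == {"B1", "B2"}:
        balance = "both"
    else:
        balance = a1_targets.pop()
    return ContactCensus(counts, total, inter, balance)
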