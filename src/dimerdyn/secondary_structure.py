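"""Per-frame secondary-structure assignment and helical content (SSC).

Assignment follows the Kabsch-Sander electrostatic hydrogen-bond model: for
a candidate bond from the amide N-H of one residue to the carbonyl C=O of
another,

    E = 0.084 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN) * 332  kcal/mol

and the bond exists when E < -0.5 kcal/mol.  A residue is labelled H
(alpha-helix) when it sits inside two consecutive i -> i+4 bonded turns, E
(strand) when it takes part in a parallel or antiparallel bridge, else C.
Only the H/non-H distinction feeds the SSC figures; E is retained for
completeness.

SSC of a helix segment over a window is the percentage of residue-frames
labelled H; the accumulated average pools the residue-frames of all four
central helices (a residue-frame-weighted mean of segment SSCs).
"""

from __future__ import annotations

import numpy as np

from .stability import StableWindow
from .structures import HelixSet, Topology, Trajectory

KS_COUPLING = 0.084 * 332.0  # kcal/mol * A
KS_CUTOFF = -0.5             # kcal/mol
MIN_CHAIN_LEN = 5


def _backbone_indices(topology: Topology):
    """Per-residue N/H/C/O indices (-1 where absent)."""
    n_res = len(topology.residues)
    out = {name: np.full(n_res, -1, dtype=int) for name in ("N", "H", "C", "O")}
    for ri, res in enumerate(topology.residues):
        for i in range(res.start, res.stop):
            nm = topology.names[i]
            if nm in out:
                out[nm][ri] = i
    return out


def hbond_energy_matrix(coords: np.ndarray, topology: Topology) -> np.ndarray:
    """E[i, j]: Kabsch-Sander energy of the bond CO(i) ... HN(j).

    +inf where undefined (missing atoms, same residue).
    """
    idx = _backbone_indices(topology)
    n_res = len(topology.residues)
    ok_acc = (idx["C"] >= 0) & (idx["O"] >= 0)
    ok_don = (idx["N"] >= 0) & (idx["H"] >= 0)
    E = np.full((n_res, n_res), np.inf)
    ai = np.flatnonzero(ok_acc)
    dj = np.flatnonzero(ok_don)
    if len(ai) == 0 or len(dj) == 0:
        return E
    C = coords[idx["C"][ai]]
    O = coords[idx["O"][ai]]
    N = coords[idx["N"][dj]]
    H = coords[idx["H"][dj]]

    def dist(a, b):
        return np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)

    r_on = dist(O, N)
    r_ch = dist(C, H)
    r_oh = dist(O, H)
    r_cn = dist(C, N)
    with np.errstate(divide="ignore"):
        e = KS_COUPLING * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
    E[np.ix_(ai, dj)] = e
    np.fill_diagonal(E, np.inf)
    return E


def assign_frame(coords: np.ndarray, topology: Topology) -> np.ndarray:
    """Per-residue {H, E, C} labels for one frame."""
    n_res = len(topology.residues)
    labels = np.full(n_res, "C", dtype="U1")
    chains = [np.flatnonzero(
        np.array([r.chain_id for r in topology.residues]) == c)
        for c in ("A", "B")]
    if n_res < MIN_CHAIN_LEN:
        return labels
    E = hbond_energy_matrix(coords, topology)
    hb = E < KS_CUTOFF

    # helix: two consecutive i -> i+4 turns mark residues i+1 .. i+4
    for chain in chains:
        if len(chain) < MIN_CHAIN_LEN:
            continue
        c = chain  # residues are stored in chain order
        turns = np.zeros(len(c), dtype=bool)
        for k in range(len(c) - 4):
            turns[k] = hb[c[k], c[k + 4]]
        for k in range(len(c) - 5):
            if turns[k] and turns[k + 1]:
                labels[c[k + 1:k + 5]] = "H"

    # strand: parallel/antiparallel bridges between non-neighbouring residues
    order = {r: i for i, r in enumerate(range(n_res))}
    res = topology.residues
    for i in range(n_res):
        for j in range(i + 1, n_res):
            same_chain = res[i].chain_id == res[j].chain_id
            if same_chain and abs(res[i].local_index - res[j].local_index) < 3:
                continue
            par = anti = False
            if 0 < i < n_res - 1 and 0 < j < n_res - 1:
                par = (hb[i - 1, j] and hb[j, i + 1]) or \
                      (hb[j - 1, i] and hb[i, j + 1])
                anti = (hb[i, j] and hb[j, i]) or \
                       (hb[i - 1, j + 1] and hb[j - 1, i + 1])
            if par or anti:
                for r in (i, j):
                    if labels[r] != "H":
                        labels[r] = "E"
    return labels


def assign(traj: Trajectory, window: StableWindow | None = None) -> np.ndarray:
    """Label matrix (window frames x residues) over {H, E, C}."""
    idx = window.frame_indices() if window is not None else np.arange(traj.n_frames)
    return np.stack([assign_frame(traj.coords[t], traj.topology) for t in idx])


def ssc(labels: np.ndarray, topology: Topology, helix_set: HelixSet,
        ) -> dict[str, float]:
    """Per-segment and accumulated helical content (percent).

    `labels` is a (frames x residues) matrix as returned by :func:`assign`.
    """
    labels = np.atleast_2d(labels)
    out: dict[str, float] = {}
    pooled_h = pooled_n = 0
    for seg in HelixSet.SEGMENTS:
        rids = [topology.residue_index(r) for r in helix_set.residues(seg)]
        if not rids:
            raise ValueError(f"segment {seg} is empty")
        block = labels[:, rids]
        h = int((block == "H").sum())
        n = block.size
        out[seg] = 100.0 * h / n
        pooled_h += h
        pooled_n += n
    out["accumulated"] = 100.0 * pooled_h / pooled_n
    return out
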