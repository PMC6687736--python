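"""Independent naive oracles used to cross-check the library implementations.

These deliberately re-derive each quantity with a different code path
(per-frame loops, direct formulas, no shared helpers) so that agreement with
the library is meaningful.
"""

from __future__ import annotations

import math

import numpy as np


def naive_hbond_occupancy(traj, window=None, max_da=3.2, min_angle=120.0):
    """Residue-pair H-bond occupancy by per-frame recount.

    Independent of the library path: loops over frames and evaluates every
    donor x acceptor pair with cdist / explicit angle formulas, then takes
    the residue-pair maximum at the end.
    """
    from scipy.spatial.distance import cdist
    topo = traj.topology
    frames = traj.coords if window is None else traj.coords[window.frame_indices()]
    d_idx = topo.donor_table[:, 0]
    h_idx = topo.donor_table[:, 1]
    a_idx = topo.acceptor_table
    if len(d_idx) == 0 or len(a_idx) == 0:
        return {}
    d_res = topo.dimer_resid[d_idx]
    a_res = topo.dimer_resid[a_idx]
    same = d_res[:, None] == a_res[None, :]
    counts = np.zeros((len(d_idx), len(a_idx)), dtype=int)
    cos_cut = math.cos(math.radians(min_angle))
    for frame in frames:
        D, H, A = frame[d_idx], frame[h_idx], frame[a_idx]
        dist = cdist(D, A)
        hd = D - H
        ha = A[None, :, :] - H[:, None, :]
        cosang = np.einsum("dj,daj->da", hd, ha)
        cosang /= np.linalg.norm(hd, axis=1)[:, None]
        cosang /= np.linalg.norm(ha, axis=2)
        # angle >= min_angle  <=>  cos(angle) <= cos(min_angle)
        counts += (dist <= max_da) & (cosang <= cos_cut) & ~same
    pair_counts: dict[tuple, int] = {}
    for di in range(len(d_idx)):
        for ai in range(len(a_idx)):
            c = counts[di, ai]
            if c == 0:
                continue
            pair = tuple(sorted((int(d_res[di]), int(a_res[ai]))))
            pair_counts[pair] = max(pair_counts.get(pair, 0), int(c))
    n = len(frames)
    return {p: 100.0 * c / n for p, c in pair_counts.items()}


def naive_hydrophobic_occupancy(traj, window=None, lo=3.5, hi=5.5):
    """Residue-pair hydrophobic occupancy by per-frame min-distance recount.

    Per frame: full atom-atom cdist over the hydrophobic atoms, reduced to
    residue-pair minima with minimum.reduceat over rows then columns.
    """
    from scipy.spatial.distance import cdist
    topo = traj.topology
    frames = traj.coords if window is None else traj.coords[window.frame_indices()]
    atoms = topo.hydrophobic_atom_table
    if len(atoms) < 2:
        return {}
    resid = topo.dimer_resid[atoms]
    order = np.argsort(resid, kind="stable")
    atoms = atoms[order]
    resid = resid[order]
    uniq, starts = np.unique(resid, return_index=True)
    nr = len(uniq)
    counts = np.zeros((nr, nr), dtype=int)
    for frame in frames:
        d = cdist(frame[atoms], frame[atoms])
        rows = np.minimum.reduceat(d, starts, axis=0)
        dmin = np.minimum.reduceat(rows, starts, axis=1)
        counts += (dmin >= lo) & (dmin <= hi)
    n = len(frames)
    out: dict[tuple, int] = {}
    for i in range(nr):
        ri = topo.residues[topo.residue_index(int(uniq[i]))]
        for j in range(i + 1, nr):
            if counts[i, j] == 0:
                continue
            rj = topo.residues[topo.residue_index(int(uniq[j]))]
            if (ri.chain_id == rj.chain_id
                    and abs(ri.local_index - rj.local_index) <= 1):
                continue
            out[(int(uniq[i]), int(uniq[j]))] = 100.0 * counts[i, j] / n
    return out


def table_to_dict(df):
    return {tuple(sorted((int(r.res1), int(r.res2)))): float(r.occupancy)
            for r in df.itertuples()}


def planted_hbond_recount(traj, log, manifest, max_da=3.2, min_angle=120.0):
    """Per planted bond: frames whose designated atoms satisfy the criteria."""
    from dimerdyn.synthetic import _resolve_hbond_atoms
    topo = traj.topology
    out = []
    for hb in manifest.hbonds:
        d, h, a, _ = _resolve_hbond_atoms(topo, hb)
        hits = []
        for frame in traj.coords:
            dist = math.dist(frame[d], frame[a])
            v1, v2 = frame[d] - frame[h], frame[a] - frame[h]
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            ang = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
            hits.append(dist <= max_da and ang >= min_angle)
        out.append(np.array(hits))
    return out


def grid_min_rmsd(mobile, reference, n_angles=24):
    """Brute-force minimum RMSD over a discretized rotation grid.

    Translation is handled exactly (centroid match); rotations scan a
    uniform Euler-angle grid.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    x = mobile - mobile.mean(axis=0)
    y = reference - reference.mean(axis=0)
    best = np.inf
    angles = np.linspace(0, 2 * np.pi, n_angles, endpoint=False)
    half = np.linspace(0, np.pi, n_angles // 2 + 1)
    for a in angles:
        ca, sa = np.cos(a), np.sin(a)
        rz1 = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1]])
        for b in half:
            cb, sb = np.cos(b), np.sin(b)
            ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
            for c in angles:
                cc, sc = np.cos(c), np.sin(c)
                rz2 = np.array([[cc, -sc, 0], [sc, cc, 0], [0, 0, 1]])
                rot = rz1 @ ry @ rz2
                rmsd = np.sqrt(np.mean(np.sum((x @ rot.T - y) ** 2, axis=1)))
                best = min(best, rmsd)
    return best


def fine_grid_sasa(coords, radii, probe=1.4, n_points=8000):
    """High-resolution quadrature SASA (independent dense point set)."""
    coords = np.asarray(coords, float)
    radii = np.asarray(radii, float) + probe
    rng = np.random.default_rng(12345)
    pts = rng.standard_normal((n_points, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    out = np.empty(len(coords))
    for i in range(len(coords)):
        sphere = coords[i] + radii[i] * pts
        free = np.ones(n_points, dtype=bool)
        for j in range(len(coords)):
            if j == i:
                continue
            free &= np.linalg.norm(sphere - coords[j], axis=1) >= radii[j]
        out[i] = 4 * np.pi * radii[i] ** 2 * free.mean()
    return out


def binom_ci(n, p, alpha=0.01):
    """Two-sided (1-alpha) binomial interval on the success count."""
    from scipy import stats
    lo = stats.binom.ppf(alpha / 2, n, p)
    hi = stats.binom.ppf(1 - alpha / 2, n, p)
    return lo, hi
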