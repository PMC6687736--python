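"""Synthetic C2-symmetric four-helix-bundle dimers with planted ground truth.

The generator stands in for unavailable long MD trajectories of a helix-bundle
dimer.  It is a *statistical* emulator, not a physical one: frames are the
ideal bundle plus

* Gaussian concerted motions along planted orthonormal modes (built from
  per-helix rigid translations so helix internal geometry survives),
* per-frame Bernoulli on/off hydrogen bonds and hydrophobic contacts imposed
  by placing designated side-chain atoms at formed/broken geometry,
* partial helix unwinding (extended-strand replacement) in a stated fraction
  of frames,
* an optional initial drift phase in which chain B relaxes toward its
  plateau position.

Every stochastic element is drawn from one seeded generator and logged, so
analyses can be checked against exact ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import geometry
from .chemistry import ONE_TO_THREE, RESIDUE_TEMPLATES
from .structures import (CHAIN_B_OFFSET, HelixSet, Topology, Trajectory)

FORMED_HBOND_DA = 2.9      # A, donor-acceptor distance when formed
FORMED_HBOND_ANGLE = 165.0  # deg, D-H-A angle when formed
BROKEN_HBOND_DA = 4.5      # A, outside the 3.2 A criterion
FORMED_CONTACT = 4.5       # A, inside the 3.5-5.5 A hydrophobic band
BROKEN_CONTACT = 8.0       # A, outside it

DEFAULT_HELIX_SEQUENCE_CYCLE = "LASA"


class OverlapError(ValueError):
    """Helix spacing smaller than the sum of backbone radii."""


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------

@dataclass
class PlantedHBond:
    donor_res: int            # dimer numbering
    acceptor_res: int
    occupancy: float
    donor_atom: str | None = None     # auto: side-chain donor, else backbone N
    hydrogen_atom: str | None = None
    acceptor_atom: str | None = None  # auto: side-chain acceptor (required)


@dataclass
class PlantedContact:
    res_a: int
    res_b: int
    occupancy: float
    atom_a: str | None = None  # auto: outermost hydrophobic side-chain atom
    atom_b: str | None = None


@dataclass
class UnwoundSegment:
    start: int  # dimer numbering, inclusive
    end: int
    fraction: float


@dataclass
class DriftSpec:
    n_frames: int
    amplitude: float = 8.0  # A; chain-B displacement decaying linearly to 0


@dataclass
class GroundTruthManifest:
    """Machine-readable ground truth for one synthetic run."""
    modes: list[tuple[np.ndarray, float]] = field(default_factory=list)
    hbonds: list[PlantedHBond] = field(default_factory=list)
    contacts: list[PlantedContact] = field(default_factory=list)
    unwound: list[UnwoundSegment] = field(default_factory=list)
    drift: DriftSpec | None = None
    seed: int = 0

    def validate(self):
        for hb in self.hbonds:
            if not 0.0 <= hb.occupancy <= 1.0:
                raise ValueError(f"H-bond occupancy {hb.occupancy} outside [0, 1]")
        for c in self.contacts:
            if not 0.0 <= c.occupancy <= 1.0:
                raise ValueError(f"contact occupancy {c.occupancy} outside [0, 1]")
        for u in self.unwound:
            if not 0.0 <= u.fraction <= 1.0:
                raise ValueError(f"unwound fraction {u.fraction} outside [0, 1]")
        if self.modes:
            vecs = np.stack([np.asarray(v, dtype=float).ravel()
                             for v, _ in self.modes])
            gram = vecs @ vecs.T
            if not np.allclose(gram, np.eye(len(vecs)), atol=1e-8):
                raise ValueError("planted mode vectors are not orthonormal")

    def to_json(self, path=None) -> str:
        d = {
            "modes": [{"vector": np.asarray(v).ravel().tolist(), "variance": s}
                      for v, s in self.modes],
            "hbonds": [vars(h) for h in self.hbonds],
            "contacts": [vars(c) for c in self.contacts],
            "unwound": [vars(u) for u in self.unwound],
            "drift": vars(self.drift) if self.drift else None,
            "seed": self.seed,
        }
        text = json.dumps(d, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "GroundTruthManifest":
        text = str(text_or_path)
        if "{" not in text:  # a path, not a JSON document
            text = Path(text).read_text()
        d = json.loads(text)
        return cls(
            modes=[(np.asarray(m["vector"], dtype=float), float(m["variance"]))
                   for m in d["modes"]],
            hbonds=[PlantedHBond(**h) for h in d["hbonds"]],
            contacts=[PlantedContact(**c) for c in d["contacts"]],
            unwound=[UnwoundSegment(**u) for u in d["unwound"]],
            drift=DriftSpec(**d["drift"]) if d.get("drift") else None,
            seed=int(d["seed"]),
        )


# ---------------------------------------------------------------------------
# Ideal bundle construction
# ---------------------------------------------------------------------------

def _axis_align(residues: list[dict[str, np.ndarray]]) -> list[dict]:
    """Rotate/translate a built chain so its CA axis is +z, centroid at origin."""
    cas = np.array([r["CA"] for r in residues])
    centroid = cas.mean(axis=0)
    centered = cas - centroid
    # principal axis of the CA cloud
    _, _, vt = np.linalg.svd(centered)
    axis = vt[0]
    if axis @ (cas[-1] - cas[0]) < 0:
        axis = -axis
    # rotation taking axis -> z
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    s = np.linalg.norm(v)
    c = axis @ z
    if s < 1e-12:
        rot = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
    return [{k: rot @ (p - centroid) for k, p in r.items()} for r in residues]


def _transform(residues, rot=None, offset=(0.0, 0.0, 0.0)):
    rot = np.eye(3) if rot is None else rot
    off = np.asarray(offset, dtype=float)
    return [{k: rot @ p + off for k, p in r.items()} for r in residues]


ROT_FLIP_X = np.diag([1.0, -1.0, -1.0])   # 180 deg about x: +z -> -z
ROT_C2_Z = np.diag([-1.0, -1.0, 1.0])     # the dimer C2 operator


def _expand_sequence(spec: str | None, n: int) -> list[str]:
    cycle = spec if spec else DEFAULT_HELIX_SEQUENCE_CYCLE
    seq = [ONE_TO_THREE[cycle[i % len(cycle)].upper()] for i in range(n)]
    return seq


def build_ideal_bundle(n_res_per_helix: int = 14,
                       sequence_spec: str | None = None,
                       inter_helix_spacing: float = 10.0,
                       loop_length: int = 4,
                       ) -> tuple[Topology, np.ndarray, HelixSet]:
    """Ideal C2-symmetric four-helix bundle dimer.

    Each monomer is helix-loop-helix; helices sit on the corners of a square
    of side `inter_helix_spacing` with antiparallel neighbours; chain B is
    chain A rotated by the C2 operator about the bundle axis.  Returns the
    topology, coordinates and the HelixSet of the four central helices in
    dimer numbering.
    """
    if n_res_per_helix < 8:
        raise ValueError("n_res_per_helix must be >= 8")
    helix_seq = _expand_sequence(sequence_spec, n_res_per_helix)
    helical = [geometry.HELIX_PHI_PSI] * n_res_per_helix
    template = _axis_align(geometry.build_chain(helix_seq, helical))
    backbone_r = max(np.linalg.norm(np.array([r[a][0], r[a][1]]))
                     for r in template for a in ("N", "CA", "C", "O"))
    if inter_helix_spacing < 2 * backbone_r:
        raise OverlapError(
            f"spacing {inter_helix_spacing} A < twice the backbone helix "
            f"radius ({backbone_r:.2f} A)")
    s = inter_helix_spacing / 2.0
    helix1 = _transform(template, offset=(-s, -s, 0.0))
    helix2 = _transform(template, ROT_FLIP_X, offset=(-s, +s, 0.0))
    # loop: glycines strung between the helix1 C-terminus and helix2 N-terminus
    a0 = helix1[-1]["C"]
    a1 = helix2[0]["N"]
    loop_res = []
    gly = geometry.build_chain(["GLY"] * 1, [(180.0, 180.0)])[0]
    gly_centered = {k: p - gly["CA"] for k, p in gly.items()}
    path = a1 - a0
    path_dir = path / np.linalg.norm(path)
    perp = np.cross(path_dir, np.array([0.0, 0.0, 1.0]))
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(path_dir, np.array([1.0, 0.0, 0.0]))
    perp /= np.linalg.norm(perp)
    frame_rot = np.column_stack([perp, np.cross(path_dir, perp), path_dir])
    for i in range(loop_length):
        t = (i + 1) / (loop_length + 1)
        pos = a0 + t * path
        loop_res.append({k: frame_rot @ p + pos for k, p in gly_centered.items()})
    chain_a = helix1 + loop_res + helix2
    # every residue with a predecessor gets an amide H (segment joints too)
    for i in range(1, len(chain_a)):
        res, prev = chain_a[i], chain_a[i - 1]
        if "H" not in res and "C" in prev:
            res["H"] = geometry.amide_hydrogen(res["N"], res["CA"], prev["C"])
    chain_b = [{k: ROT_C2_Z @ p for k, p in r.items()} for r in chain_a]

    atom_order = ["N", "CA", "C", "O", "H"]
    names, elements, chain_ids, res_local, res_names = [], [], [], [], []
    coords = []
    seq_a = (helix_seq + ["GLY"] * loop_length + helix_seq)
    for chain_id, residues in (("A", chain_a), ("B", chain_b)):
        for i, res in enumerate(residues):
            rname = seq_a[i]
            side = list(RESIDUE_TEMPLATES.get(rname, {"atoms": ()})["atoms"])
            for a in atom_order + side:
                if a not in res:
                    continue
                names.append(a)
                elements.append(a[0] if a[0] in "CNOSH" else "C")
                chain_ids.append(chain_id)
                res_local.append(i + 1)
                res_names.append(rname)
                coords.append(res[a])
    topo = Topology(names, elements, chain_ids, res_local, res_names)
    n, L = n_res_per_helix, loop_length
    helix_set = HelixSet(
        A1=(1, n), A2=(n + L + 1, 2 * n + L),
        B1=(CHAIN_B_OFFSET + 1, CHAIN_B_OFFSET + n),
        B2=(CHAIN_B_OFFSET + n + L + 1, CHAIN_B_OFFSET + 2 * n + L))
    return topo, np.array(coords), helix_set


# ---------------------------------------------------------------------------
# Planted modes
# ---------------------------------------------------------------------------

def _rigid_body_basis(points: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the 6 rigid-body directions of a point cloud."""
    n = len(points)
    centered = points - points.mean(axis=0)
    basis = []
    for ax in range(3):
        v = np.zeros((n, 3))
        v[:, ax] = 1.0
        basis.append(v.ravel())
    for ax in range(3):
        e = np.zeros(3)
        e[ax] = 1.0
        basis.append(np.cross(np.broadcast_to(e, (n, 3)), centered).ravel())
    b = np.stack(basis)
    q, _ = np.linalg.qr(b.T)
    return q.T  # 6 x 3n


def make_helix_modes(topology: Topology, base_coords: np.ndarray,
                     helix_set: HelixSet,
                     variances: tuple[float, ...] = (4.0, 1.0),
                     ) -> list[tuple[np.ndarray, float]]:
    """Concerted modes from per-helix rigid translations of the CA atoms.

    Mode 1 is interface breathing (chain-A helices vs chain-B helices along
    x), mode 2 an intra-chain scissor.  Both carry zero net translation and
    torque by symmetry; they are nevertheless explicitly projected off the
    rigid-body subspace and orthonormalized.
    """
    ca = topology.ca_indices
    ca_res = topology.dimer_resid[ca]
    seg_of = np.array([helix_set.segment_of(int(r)) or "" for r in ca_res])
    n_ca = len(ca)
    patterns = [
        {"A1": (1, 0, 0), "A2": (1, 0, 0), "B1": (-1, 0, 0), "B2": (-1, 0, 0)},
        {"A1": (0, 1, 0), "A2": (0, -1, 0), "B1": (0, -1, 0), "B2": (0, 1, 0)},
    ]
    raw = []
    for pat in patterns[:len(variances)]:
        v = np.zeros((n_ca, 3))
        for seg, d in pat.items():
            v[seg_of == seg] = d
        raw.append(v.ravel())
    ca_coords = np.asarray(base_coords, dtype=float)[ca]
    return _finalize_modes(raw, variances, ca_coords)


def _finalize_modes(raw_vectors, variances, ca_coords) -> list[tuple[np.ndarray, float]]:
    rigid = _rigid_body_basis(ca_coords)
    out = []
    prev: list[np.ndarray] = []
    for v, var in zip(raw_vectors, variances):
        v = np.asarray(v, dtype=float).ravel().copy()
        v -= rigid.T @ (rigid @ v)
        for p in prev:
            v -= (p @ v) * p
        nrm = np.linalg.norm(v)
        if nrm < 1e-9:
            raise ValueError("planted mode degenerates after projection")
        v /= nrm
        prev.append(v)
        out.append((v, float(var)))
    return out


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulationLog:
    """Exact per-frame draw log for one synthetic run."""
    mode_amplitudes: np.ndarray        # (n_frames, n_modes)
    hbond_formed: np.ndarray           # (n_frames, n_hbonds), bool
    contact_formed: np.ndarray         # (n_frames, n_contacts), bool
    unwound: np.ndarray                # (n_frames, n_segments), bool
    plateau_start: int                 # first frame after the drift phase
    base_coords: np.ndarray            # plateau mean structure, (n_atoms, 3)


def _resolve_hbond_atoms(topology: Topology, hb: PlantedHBond):
    rid = hb.donor_res
    res = topology.residues[topology.residue_index(rid)]
    tpl = RESIDUE_TEMPLATES.get(res.name, {"donors": ()})
    if hb.donor_atom is not None:
        d = topology.atom_index(rid, hb.donor_atom)
        h = topology.atom_index(rid, hb.hydrogen_atom)
    elif tpl["donors"]:
        heavy, hyd = tpl["donors"][0]
        d = topology.atom_index(rid, heavy)
        h = topology.atom_index(rid, hyd)
    else:
        d = topology.atom_index(rid, "N")
        h = topology.atom_index(rid, "H")
    aid = hb.acceptor_res
    ares = topology.residues[topology.residue_index(aid)]
    atpl = RESIDUE_TEMPLATES.get(ares.name, {"acceptors": ()})
    if hb.acceptor_atom is not None:
        acc_name = hb.acceptor_atom
    else:
        side_acc = [a for a in atpl["acceptors"]]
        if not side_acc:
            raise ValueError(
                f"planted H-bond acceptor residue {aid} ({ares.name}) has no "
                "side-chain acceptor; backbone O cannot be displaced")
        acc_name = side_acc[0]
    a = topology.atom_index(aid, acc_name)
    # atoms that ride along with the acceptor (attached hydrogens)
    riders = []
    for heavy, hyd in RESIDUE_TEMPLATES.get(ares.name, {"donors": ()})["donors"]:
        if heavy == acc_name:
            try:
                riders.append(topology.atom_index(aid, hyd))
            except KeyError:
                pass
    return d, h, a, riders


def _resolve_contact_atoms(topology: Topology, c: PlantedContact):
    def outermost(rid, override):
        if override is not None:
            return topology.atom_index(rid, override)
        res = topology.residues[topology.residue_index(rid)]
        tpl = RESIDUE_TEMPLATES.get(res.name)
        if tpl is None or not tpl["atoms"]:
            raise ValueError(f"residue {rid} has no hydrophobic side-chain atom")
        for name in reversed(tpl["atoms"]):
            if name[0] in "CS":
                return topology.atom_index(rid, name)
        raise ValueError(f"residue {rid} has no hydrophobic side-chain atom")
    return outermost(c.res_a, c.atom_a), outermost(c.res_b, c.atom_b)


def _extended_template(topology: Topology, segment: UnwoundSegment):
    """Extended-strand replacement geometry for one segment."""
    rids = list(range(segment.start, segment.end + 1))
    res_names = [topology.residues[topology.residue_index(r)].name for r in rids]
    ext = geometry.build_chain(res_names, [geometry.EXTENDED_PHI_PSI] * len(rids))
    atom_idx, local = [], []
    for rid, res in zip(rids, ext):
        for name, pos in res.items():
            try:
                atom_idx.append(topology.atom_index(rid, name))
                local.append(pos)
            except KeyError:
                continue
    anchor = [topology.atom_index(rids[0], a) for a in ("N", "CA", "C")]
    anchor_local = np.array([ext[0][a] for a in ("N", "CA", "C")])
    return np.array(atom_idx), np.array(local), np.array(anchor), anchor_local


def simulate_trajectory(topology: Topology, base_coords: np.ndarray,
                        manifest: GroundTruthManifest, n_frames: int,
                        frame_interval_ps: float = 2.0,
                        ) -> tuple[Trajectory, SimulationLog]:
    """Generate a seeded stochastic trajectory realizing the manifest."""
    if n_frames < 10:
        raise ValueError("n_frames must be >= 10")
    manifest.validate()
    rng = np.random.default_rng(manifest.seed)
    base = np.asarray(base_coords, dtype=float)
    n_atoms = topology.n_atoms
    ca = topology.ca_indices

    # all stochastic draws up front, in fixed order -> bit reproducibility
    k = len(manifest.modes)
    amps = rng.standard_normal((n_frames, k)) if k else np.zeros((n_frames, 0))
    amps = amps * np.sqrt([var for _, var in manifest.modes])
    hb_draws = rng.random((n_frames, len(manifest.hbonds)))
    hb_formed = hb_draws < np.array([h.occupancy for h in manifest.hbonds])
    ct_draws = rng.random((n_frames, len(manifest.contacts)))
    ct_formed = ct_draws < np.array([c.occupancy for c in manifest.contacts])
    uw_draws = rng.random((n_frames, len(manifest.unwound)))
    uw_on = uw_draws < np.array([u.fraction for u in manifest.unwound])

    # 1. concerted modes: CA displacement extended rigidly over each residue
    frames = np.broadcast_to(base, (n_frames, n_atoms, 3)).copy()
    if k:
        mode_full = np.zeros((k, n_atoms, 3))
        for m, (vec, _) in enumerate(manifest.modes):
            v = np.asarray(vec, dtype=float).reshape(len(ca), 3)
            for ci, atom in enumerate(ca):
                res = topology.residues[topology.atom_residue[atom]]
                mode_full[m, res.start:res.stop] = v[ci]
        frames += np.einsum("fk,kaj->faj", amps, mode_full)

    # 2. drift phase: chain B displaced along +x with a quadratic decay
    # (fast early relaxation, small slow tail), monotone RMSD vs frame 0
    plateau_start = 0
    if manifest.drift is not None and manifest.drift.n_frames > 0:
        nd = min(manifest.drift.n_frames, n_frames)
        plateau_start = nd
        chain_b = topology.chain_atoms("B")
        ramp = manifest.drift.amplitude * (1.0 - np.arange(nd) / nd) ** 2
        frames[:nd, chain_b, 0] += ramp[:, None]

    # 3. unwinding: replace segment geometry with an extended strand
    templates = [_extended_template(topology, u) for u in manifest.unwound]
    for si, (idx, local, anchor, anchor_local) in enumerate(templates):
        for t in np.flatnonzero(uw_on[:, si]):
            rot, trans, _ = geometry.kabsch(anchor_local, frames[t, anchor])
            frames[t, idx] = geometry.apply_transform(local, rot, trans)

    # 4. planted hydrogen bonds: place the acceptor atom (and its riders)
    cos_t = np.cos(np.deg2rad(180.0 - FORMED_HBOND_ANGLE))
    sin_t = np.sin(np.deg2rad(180.0 - FORMED_HBOND_ANGLE))
    for bi, hb in enumerate(manifest.hbonds):
        d_i, h_i, a_i, riders = _resolve_hbond_atoms(topology, hb)
        dres = topology.residues[topology.atom_residue[d_i]]
        out_dir = base[d_i] - base[dres.start:dres.stop].mean(axis=0)
        D = frames[:, d_i]
        H = frames[:, h_i]
        u = H - D
        dh = np.linalg.norm(u, axis=1, keepdims=True)
        u = u / dh
        p = out_dir - (u @ out_dir)[:, None] * u
        pn = np.linalg.norm(p, axis=1, keepdims=True)
        fallback = np.cross(u, np.array([0.0, 0.0, 1.0]))
        small = (pn < 1e-6).ravel()
        p[small] = fallback[small]
        p /= np.linalg.norm(p, axis=1, keepdims=True)
        w = cos_t * u + sin_t * p
        dh_ = dh.ravel()
        # |DA|^2 = |DH|^2 + r^2 + 2 |DH| r cos(180 - angle); solve for r > 0
        disc = dh_**2 * cos_t**2 - dh_**2 + FORMED_HBOND_DA**2
        r = -dh_ * cos_t + np.sqrt(disc)
        formed_pos = H + r[:, None] * w
        broken_pos = D + BROKEN_HBOND_DA * w
        new_pos = np.where(hb_formed[:, bi, None], formed_pos, broken_pos)
        delta = new_pos - frames[:, a_i]
        frames[:, a_i] = new_pos
        for rider in riders:
            frames[:, rider] += delta

    # 5. planted hydrophobic contacts: place the designated partner atom
    for ci, c in enumerate(manifest.contacts):
        a_i, b_i = _resolve_contact_atoms(topology, c)
        ares = topology.residues[topology.atom_residue[a_i]]
        A = frames[:, a_i]
        out_dir = A - frames[:, ares.start:ares.stop].mean(axis=1)
        out_dir /= np.linalg.norm(out_dir, axis=1, keepdims=True)
        dist = np.where(ct_formed[:, ci], FORMED_CONTACT, BROKEN_CONTACT)
        frames[:, b_i] = A + dist[:, None] * out_dir

    traj = Trajectory(frames, topology, frame_interval_ps)
    log = SimulationLog(mode_amplitudes=amps, hbond_formed=hb_formed,
                        contact_formed=ct_formed, unwound=uw_on,
                        plateau_start=plateau_start, base_coords=base)
    return traj, log


# ---------------------------------------------------------------------------
# Default study conditions
# ---------------------------------------------------------------------------

def default_manifest(topology: Topology, base_coords: np.ndarray,
                     helix_set: HelixSet, seed: int = 0,
                     variances: tuple[float, ...] = (4.0, 1.0),
                     hbond_occupancies: tuple[float, ...] = (0.719, 0.574),
                     contact_occupancies: tuple[float, ...] = (0.60, 0.30),
                     unwound_fraction: float = 0.30,
                     drift: DriftSpec | None = None,
                     ) -> GroundTruthManifest:
    """Study-condition manifest for a default bundle.

    H-bonds pair SER side chains across the interface (A1-B1 and A2-B2, the
    wild-type-like pattern of strong interface bonds); contacts pair LEU side
    chains A1-B2 and A2-B1; one central sub-segment of A1 unwinds in
    `unwound_fraction` of frames.
    """
    def residues_of(seg, name3):
        return [r for r in helix_set.residues(seg)
                if topology.residues[topology.residue_index(r)].name == name3]

    hbonds, contacts = [], []
    ser = {s: residues_of(s, "SER") for s in HelixSet.SEGMENTS}
    leu = {s: residues_of(s, "LEU") for s in HelixSet.SEGMENTS}
    pairs = [("A1", "B1"), ("A2", "B2")]
    for occ, (sa, sb) in zip(hbond_occupancies, pairs):
        if ser[sa] and ser[sb]:
            hbonds.append(PlantedHBond(ser[sa][0], ser[sb][0], occ))
    cpairs = [("A1", "B2"), ("A2", "B1")]
    for occ, (sa, sb) in zip(contact_occupancies, cpairs):
        if leu[sa] and leu[sb]:
            contacts.append(PlantedContact(leu[sa][0], leu[sb][0], occ))
    lo, hi = helix_set.A1
    mid = (lo + hi) // 2
    unwound = []
    if unwound_fraction > 0:
        # a 4-residue central segment: one helical turn melting out
        unwound = [UnwoundSegment(max(lo + 1, mid - 1), min(hi, mid + 2),
                                  unwound_fraction)]
    return GroundTruthManifest(
        modes=make_helix_modes(topology, base_coords, helix_set, variances),
        hbonds=hbonds, contacts=contacts, unwound=unwound,
        drift=drift, seed=seed)
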