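"""Structure and trajectory containers, dimer numbering, and file I/O.

A two-chain topology uses a *dimer numbering* convention: chain A residues
keep their 1-based local indices, chain B residue ``i`` is numbered
``i + CHAIN_B_OFFSET``.  With the offset of 913 (the length of the chain-A
subunit in the motivating system) the four central helices of a C2 dimer map
as A1 609-639 <-> B1 1522-1552 and A2 692-715 <-> B2 1605-1628.

PDB files are read and written through biotite; DCD through mdtraj's raw
coordinate reader.  Water and ions are never read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from . import chemistry
from .chemistry import RESIDUE_TEMPLATES, SUPPORTED_ELEMENTS

CHAIN_B_OFFSET = 913
DEFAULT_FRAME_INTERVAL_PS = 2.0


class ChainMappingError(ValueError):
    """Raised when a structure has more than two chains and no mapping."""


@dataclass(frozen=True)
class AtomRecord:
    serial: int
    name: str
    element: str
    residue_local_index: int
    residue_name: str
    chain_id: str
    position: np.ndarray

    def __post_init__(self):
        if self.element not in SUPPORTED_ELEMENTS:
            raise ValueError(f"unsupported element {self.element!r}")
        if not np.all(np.isfinite(self.position)):
            raise ValueError("non-finite atom position")


@dataclass(frozen=True)
class Residue:
    chain_id: str
    local_index: int
    name: str
    start: int  # atom span [start, stop)
    stop: int

    @property
    def dimer_index(self) -> int:
        return self.local_index + (CHAIN_B_OFFSET if self.chain_id == "B" else 0)


class Topology:
    """Atom/residue bookkeeping plus chemistry tables for a two-chain dimer.

    Parameters are parallel per-atom arrays.  Chemistry tables (donors,
    acceptors, hydrophobic atoms) are derived from the residue templates;
    residues with unknown names stay in the coordinates but are excluded from
    the tables with a warning.
    """

    def __init__(self, names, elements, chain_ids, res_local, res_names):
        self.names = list(names)
        self.elements = list(elements)
        self.chain_ids = np.asarray(chain_ids, dtype="U1")
        self.res_local = np.asarray(res_local, dtype=int)
        self.res_names = list(res_names)
        self.n_atoms = len(self.names)
        if not set(self.chain_ids) <= {"A", "B"}:
            raise ChainMappingError("chain ids must be 'A' or 'B' after mapping")
        self._build_residues()
        self._build_chemistry()

    # -- residue bookkeeping -------------------------------------------------
    def _build_residues(self):
        self.residues: list[Residue] = []
        start = 0
        for i in range(1, self.n_atoms + 1):
            if i == self.n_atoms or (self.chain_ids[i] != self.chain_ids[start]
                                     or self.res_local[i] != self.res_local[start]):
                self.residues.append(Residue(
                    chain_id=str(self.chain_ids[start]),
                    local_index=int(self.res_local[start]),
                    name=self.res_names[start],
                    start=start, stop=i))
                start = i
        self.atom_residue = np.empty(self.n_atoms, dtype=int)
        for ri, res in enumerate(self.residues):
            self.atom_residue[res.start:res.stop] = ri
        # dimer numbering per atom and per residue; must be a bijection
        self.dimer_resid = np.array([self.residues[ri].dimer_index
                                     for ri in self.atom_residue])
        ids = [r.dimer_index for r in self.residues]
        if len(set(ids)) != len(ids):
            raise ValueError("dimer residue numbering is not a bijection")
        self._dimer_to_res = {r.dimer_index: i for i, r in enumerate(self.residues)}

    def _build_chemistry(self):
        """Donor/acceptor/hydrophobic tables and atom-name lookup."""
        self._atom_lookup: dict[tuple[int, str], int] = {}
        for i in range(self.n_atoms):
            self._atom_lookup[(int(self.dimer_resid[i]), self.names[i])] = i
        donors: list[tuple[int, int]] = []      # (heavy, hydrogen) atom indices
        acceptors: list[int] = []
        hydrophobic: list[int] = []
        warned: set[str] = set()
        for res in self.residues:
            if res.name not in RESIDUE_TEMPLATES:
                if res.name not in warned:
                    warnings.warn(f"unknown residue {res.name}: excluded from "
                                  "chemistry tables", stacklevel=2)
                    warned.add(res.name)
                continue
            rid = res.dimer_index
            n_idx = self._atom_lookup.get((rid, "N"))
            h_idx = self._atom_lookup.get((rid, "H"))
            if n_idx is not None and h_idx is not None:
                donors.append((n_idx, h_idx))
            o_idx = self._atom_lookup.get((rid, "O"))
            if o_idx is not None:
                acceptors.append(o_idx)
            tpl = RESIDUE_TEMPLATES[res.name]
            for heavy, hyd in tpl["donors"]:
                hi = self._atom_lookup.get((rid, heavy))
                hh = self._atom_lookup.get((rid, hyd))
                if hi is not None and hh is not None:
                    donors.append((hi, hh))
            for acc in tpl["acceptors"]:
                ai = self._atom_lookup.get((rid, acc))
                if ai is not None:
                    acceptors.append(ai)
            for name in tpl["atoms"]:
                ai = self._atom_lookup.get((rid, name))
                if ai is not None and chemistry.is_hydrophobic_atom(res.name, name):
                    hydrophobic.append(ai)
        self.donor_table = np.array(donors, dtype=int).reshape(-1, 2)
        self.acceptor_table = np.array(acceptors, dtype=int)
        self.hydrophobic_atom_table = np.array(hydrophobic, dtype=int)

    # -- selections ----------------------------------------------------------
    @property
    def ca_indices(self) -> np.ndarray:
        return np.array([i for i, n in enumerate(self.names) if n == "CA"])

    @property
    def backbone_indices(self) -> np.ndarray:
        bb = set(chemistry.BACKBONE_ATOMS)
        return np.array([i for i, n in enumerate(self.names) if n in bb])

    def atom_index(self, dimer_resid: int, atom_name: str) -> int:
        key = (int(dimer_resid), atom_name)
        if key not in self._atom_lookup:
            raise KeyError(f"no atom {atom_name} in dimer residue {dimer_resid}")
        return self._atom_lookup[key]

    def residue_index(self, dimer_resid: int) -> int:
        return self._dimer_to_res[int(dimer_resid)]

    def residue_atoms(self, dimer_resid: int) -> np.ndarray:
        res = self.residues[self.residue_index(dimer_resid)]
        return np.arange(res.start, res.stop)

    def chain_atoms(self, chain_id: str) -> np.ndarray:
        return np.flatnonzero(self.chain_ids == chain_id)

    def has_amide_hydrogens(self) -> bool:
        return any(n == "H" for n in self.names)

    def atom_records(self, coords: np.ndarray) -> list[AtomRecord]:
        return [AtomRecord(serial=i + 1, name=self.names[i],
                           element=self.elements[i],
                           residue_local_index=int(self.res_local[i]),
                           residue_name=self.res_names[i],
                           chain_id=str(self.chain_ids[i]),
                           position=np.asarray(coords[i], dtype=float))
                for i in range(self.n_atoms)]


@dataclass
class Trajectory:
    """Ordered frame stack (Angstrom) over a fixed topology."""
    coords: np.ndarray            # (n_frames, n_atoms, 3)
    topology: Topology
    frame_interval_ps: float = DEFAULT_FRAME_INTERVAL_PS

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must be (n_frames, n_atoms, 3)")
        if self.coords.shape[0] < 1:
            raise ValueError("trajectory must contain at least one frame")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frame 0 atom count {self.coords.shape[1]} does not match "
                f"topology ({self.topology.n_atoms})")
        if self.frame_interval_ps <= 0:
            raise ValueError("frame_interval_ps must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def duration_ns(self) -> float:
        return (self.n_frames - 1) * self.frame_interval_ps / 1000.0


@dataclass(frozen=True)
class HelixSet:
    """The four central helices, inclusive dimer-numbered residue ranges."""
    A1: tuple[int, int]
    A2: tuple[int, int]
    B1: tuple[int, int]
    B2: tuple[int, int]

    SEGMENTS = ("A1", "A2", "B1", "B2")

    def __post_init__(self):
        spans = []
        for name in self.SEGMENTS:
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"segment {name} has lo > hi")
            chain_b = name.startswith("B")
            if chain_b and lo <= CHAIN_B_OFFSET:
                raise ValueError(f"segment {name} must lie in chain B")
            if not chain_b and hi > CHAIN_B_OFFSET:
                raise ValueError(f"segment {name} must lie in chain A")
            spans.append(set(range(lo, hi + 1)))
        for i in range(4):
            for j in range(i + 1, 4):
                if spans[i] & spans[j]:
                    raise ValueError("helix segments must be disjoint")

    def residues(self, name: str) -> range:
        lo, hi = getattr(self, name)
        return range(lo, hi + 1)

    def segment_of(self, dimer_resid: int) -> str | None:
        for name in self.SEGMENTS:
            lo, hi = getattr(self, name)
            if lo <= dimer_resid <= hi:
                return name
        return None

    def to_dict(self) -> dict:
        return {name: list(getattr(self, name)) for name in self.SEGMENTS}

    @classmethod
    def from_dict(cls, d: dict) -> "HelixSet":
        return cls(**{k: tuple(v) for k, v in d.items()})


# ---------------------------------------------------------------------------
# PDB / DCD I/O
# ---------------------------------------------------------------------------

def _local_index(chain: str, res_id: int) -> int:
    """Interpret a file residue id: chain B ids above the offset are dimer ids."""
    if chain == "B" and res_id > CHAIN_B_OFFSET:
        return res_id - CHAIN_B_OFFSET
    return res_id


def _stack_to_topology(array: struc.AtomArray, chain_map: dict[str, str] | None,
                       ) -> Topology:
    chains = sorted(set(array.chain_id))
    if chain_map is None:
        if len(chains) > 2:
            raise ChainMappingError(
                f"structure has chains {chains}; a chain mapping is required "
                "for more than two chains")
        chain_map = {c: mapped for c, mapped in zip(chains, ("A", "B"))}
    mapped = [chain_map.get(c) for c in array.chain_id]
    keep = np.array([m is not None for m in mapped])
    array = array[keep]
    mapped_ids = np.array([m for m in mapped if m is not None])
    res_local = np.array([_local_index(c, int(r))
                          for c, r in zip(mapped_ids, array.res_id)])
    elements = [e.capitalize() if len(e) > 1 else e.upper() for e in array.element]
    elements = [e if e in SUPPORTED_ELEMENTS else chemistry.element_of(n)
                for e, n in zip(elements, array.atom_name)]
    return Topology(names=list(array.atom_name), elements=elements,
                    chain_ids=mapped_ids, res_local=res_local,
                    res_names=list(array.res_name))


def read_structure(path, chain_map: dict[str, str] | None = None,
                   ) -> tuple[Topology, np.ndarray]:
    """Read a PDB file; returns the topology and the first model's coordinates."""
    pdb = PDBFile.read(str(path))
    array = pdb.get_structure(model=1)
    topo = _stack_to_topology(array, chain_map)
    return topo, np.asarray(array.coord, dtype=float)


def _biotite_template(topology: Topology) -> struc.AtomArray:
    arr = struc.AtomArray(topology.n_atoms)
    arr.chain_id = topology.chain_ids
    arr.res_id = topology.dimer_resid
    arr.res_name = np.array(topology.res_names)
    arr.atom_name = np.array(topology.names)
    arr.element = np.array(topology.elements)
    arr.hetero = np.zeros(topology.n_atoms, dtype=bool)
    return arr


def write_structure(topology: Topology, coords: np.ndarray, path) -> None:
    """Write a single-model PDB."""
    arr = _biotite_template(topology)
    arr.coord = np.asarray(coords, dtype=np.float32)
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a multi-model PDB (.pdb) or a DCD (.dcd)."""
    path = Path(path)
    if path.suffix.lower() == ".dcd":
        from mdtraj.formats import DCDTrajectoryFile
        with DCDTrajectoryFile(str(path), "w") as f:
            f.write(np.asarray(traj.coords, dtype=np.float32))
        return
    template = _biotite_template(traj.topology)
    stack = struc.from_template(template, np.asarray(traj.coords, dtype=np.float32))
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def read_trajectory(path, topology: Topology,
                    frame_interval_ps: float = DEFAULT_FRAME_INTERVAL_PS,
                    ) -> Trajectory:
    """Read a multi-model PDB or DCD trajectory over a known topology."""
    path = Path(path)
    if path.suffix.lower() == ".dcd":
        from mdtraj.formats import DCDTrajectoryFile
        with DCDTrajectoryFile(str(path)) as f:
            xyz, _, _ = f.read()
        coords = np.asarray(xyz, dtype=float)
        for t, frame in enumerate(coords):
            if frame.shape[0] != topology.n_atoms:
                raise ValueError(f"frame {t}: atom count {frame.shape[0]} does "
                                 f"not match topology ({topology.n_atoms})")
        return Trajectory(coords, topology, frame_interval_ps)
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure()
    coords = np.atleast_3d(np.asarray(stack.coord, dtype=float))
    if coords.ndim == 2:
        coords = coords[None]
    for t, frame in enumerate(coords):
        if frame.shape[0] != topology.n_atoms:
            raise ValueError(f"frame {t}: atom count {frame.shape[0]} does not "
                             f"match topology ({topology.n_atoms})")
    return Trajectory(coords, topology, frame_interval_ps)


def ensure_polar_hydrogens(topology: Topology, coords: np.ndarray,
                           ) -> tuple[Topology, np.ndarray]:
    """Place backbone amide hydrogens by idealized geometry if absent.

    The H sits 1.01 A from N on the bisector opposite the CA and previous-C
    directions (the DSSP placement).  Chain N-termini get no H.  Structures
    that already contain amide hydrogens are returned unchanged.
    """
    from .geometry import amide_hydrogen
    if topology.has_amide_hydrogens():
        return topology, coords
    coords = np.asarray(coords, dtype=float)
    multi = coords.ndim == 3
    frames = coords if multi else coords[None]
    names, elements, chain_ids, res_local, res_names = [], [], [], [], []
    new_frames: list[list[np.ndarray]] = [[] for _ in frames]
    prev_c: dict[str, int | None] = {}
    for res in topology.residues:
        span = range(res.start, res.stop)
        local_names = {topology.names[i]: i for i in span}
        for i in span:
            names.append(topology.names[i])
            elements.append(topology.elements[i])
            chain_ids.append(str(topology.chain_ids[i]))
            res_local.append(int(topology.res_local[i]))
            res_names.append(topology.res_names[i])
            for fi, frame in enumerate(frames):
                new_frames[fi].append(frame[i])
            if (topology.names[i] == "N" and prev_c.get(res.chain_id) is not None
                    and "CA" in local_names):
                names.append("H")
                elements.append("H")
                chain_ids.append(str(topology.chain_ids[i]))
                res_local.append(int(topology.res_local[i]))
                res_names.append(topology.res_names[i])
                for fi, frame in enumerate(frames):
                    h = amide_hydrogen(frame[i], frame[local_names["CA"]],
                                       frame[prev_c[res.chain_id]])
                    new_frames[fi].append(h)
        prev_c[res.chain_id] = local_names.get("C")
    new_topo = Topology(names, elements, chain_ids, res_local, res_names)
    out = np.array([np.vstack(f) for f in new_frames])
    return new_topo, (out if multi else out[0])
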