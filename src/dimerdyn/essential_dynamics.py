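"""Essential dynamics: PCA of coordinate fluctuations and of helix distances.

Three schemes mirror common practice for dimer interfaces:

* PCA-1 -- Cartesian PCA over all C-alpha atoms (global concerted motions),
* PCA-2 -- Cartesian PCA over the C-alpha atoms of the four central helices,
* PCA-3 -- PCA over the 6 inter-helix centroid distances sampled every
  `stride` frames, with frames from several systems pooled so their
  projection clouds can be compared in one plane.

Cartesian schemes subsample the window uniformly to `target_frames` (2,500
by default), superpose every frame onto the iteratively refined mean over
the analysis selection itself (removing rigid-body motion), and
eigendecompose the 3N covariance.  No mass weighting.  Eigenvector sign is
fixed by making the largest-magnitude component positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .geometry import apply_transform, kabsch
from .stability import StableWindow
from .structures import HelixSet, Topology, Trajectory

DEFAULT_TARGET_FRAMES = 2500
DEFAULT_STRIDE = 50

FEATURE_PAIRS = (("A1", "A2"), ("A1", "B1"), ("A1", "B2"),
                 ("A2", "B1"), ("A2", "B2"), ("B1", "B2"))


@dataclass
class ModeSet:
    """Eigenvalues (A^2, descending), orthonormal modes, and projections."""
    eigenvalues: np.ndarray        # (k,)
    eigenvectors: np.ndarray       # (k, 3n) rows orthonormal
    mean_structure: np.ndarray     # (n, 3) over the selection
    explained_fraction: np.ndarray
    projections: np.ndarray        # (frames, k)
    selection: np.ndarray          # atom indices into the parent topology

    def __post_init__(self):
        lam = np.asarray(self.eigenvalues, dtype=float)
        if np.any(lam < -1e-8):
            raise ValueError("negative eigenvalue beyond tolerance")
        self.eigenvalues = np.clip(lam, 0.0, None)


def _uniform_subsample(n: int, target: int) -> np.ndarray:
    if n <= target:
        return np.arange(n)
    return np.unique(np.linspace(0, n - 1, target).round().astype(int))


def _superposed_stack(frames: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-pass iterative-mean superposition of a (F, n, 3) stack."""
    ref = frames[0]
    fitted = frames
    for _ in range(2):
        aligned = np.empty_like(frames)
        for t, f in enumerate(frames):
            rot, trans, _ = kabsch(f, ref)
            aligned[t] = apply_transform(f, rot, trans)
        ref = aligned.mean(axis=0)
        fitted = aligned
    return fitted, ref


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    out = vectors.copy()
    for i, v in enumerate(out):
        j = np.argmax(np.abs(v))
        if v[j] < 0:
            out[i] = -v
    return out


def pca_cartesian(traj: Trajectory, window: StableWindow | None = None,
                  selection: np.ndarray | None = None,
                  target_frames: int = DEFAULT_TARGET_FRAMES) -> ModeSet:
    """Cartesian essential-dynamics PCA over an atom selection.

    Default selection: all C-alpha atoms (PCA-1); pass the central-helix
    C-alphas for PCA-2.
    """
    sel = traj.topology.ca_indices if selection is None else np.asarray(selection)
    idx = window.frame_indices() if window is not None else np.arange(traj.n_frames)
    if len(idx) < 2:
        raise ValueError("PCA needs at least 2 frames")
    idx = idx[_uniform_subsample(len(idx), target_frames)]
    frames = traj.coords[idx][:, sel]
    fitted, mean = _superposed_stack(frames)
    x = (fitted - mean).reshape(len(fitted), -1)
    cov = x.T @ x / (len(x) - 1)
    lam, vec = np.linalg.eigh(cov)
    order = np.argsort(lam)[::-1]
    lam = np.clip(lam[order], 0.0, None)
    vec = _fix_signs(vec[:, order].T)
    total = lam.sum()
    frac = lam / total if total > 0 else np.zeros_like(lam)
    proj = x @ vec.T
    return ModeSet(eigenvalues=lam, eigenvectors=vec, mean_structure=mean,
                   explained_fraction=frac, projections=proj, selection=sel)


def project(frames: np.ndarray, mode_set: ModeSet, k: int,
            selection_applied: bool = False) -> np.ndarray:
    """Projection of frames onto mode k after superposing onto the PCA mean.

    `frames` is (F, n_atoms, 3) over the full topology (the ModeSet's
    selection is applied) or, with `selection_applied`, already restricted.
    """
    if not 0 <= k < len(mode_set.eigenvalues):
        raise IndexError(f"mode index {k} out of range")
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    sub = frames if selection_applied else frames[:, mode_set.selection]
    if sub.shape[1] != len(mode_set.mean_structure):
        raise ValueError("frame selection does not match the ModeSet")
    v = mode_set.eigenvectors[k]
    out = np.empty(len(sub))
    for t, f in enumerate(sub):
        rot, trans, _ = kabsch(f, mode_set.mean_structure)
        out[t] = (apply_transform(f, rot, trans)
                  - mode_set.mean_structure).ravel() @ v
    return out


def pc_correlation(series_a: np.ndarray, series_b: np.ndarray) -> float | None:
    """r^2 between two PC projection series (sign- and length-invariant).

    Unequal lengths are resampled to the shorter by linear interpolation.
    Returns None when either series has zero variance.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    n = min(len(a), len(b))
    if n < 2:
        return None
    if len(a) != n:
        a = np.interp(np.linspace(0, len(a) - 1, n), np.arange(len(a)), a)
    if len(b) != n:
        b = np.interp(np.linspace(0, len(b) - 1, n), np.arange(len(b)), b)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return None
    r, _ = stats.pearsonr(a, b)
    return float(r * r)


def helix_distance_features(traj: Trajectory, helix_set: HelixSet,
                            stride: int = DEFAULT_STRIDE,
                            window: StableWindow | None = None) -> pd.DataFrame:
    """Per-sampled-frame 6-vector of inter-helix C-alpha centroid distances."""
    topo = traj.topology
    centroids = {}
    for seg in HelixSet.SEGMENTS:
        ca = [topo.atom_index(r, "CA") for r in helix_set.residues(seg)]
        if not ca:
            raise ValueError(f"helix {seg} resolves to no atoms")
        centroids[seg] = np.array(ca)
    idx = window.frame_indices() if window is not None else np.arange(traj.n_frames)
    idx = idx[::max(1, stride)]
    rows = {}
    for sa, sb in FEATURE_PAIRS:
        ca_a = traj.coords[idx][:, centroids[sa]].mean(axis=1)
        ca_b = traj.coords[idx][:, centroids[sb]].mean(axis=1)
        rows[f"{sa}-{sb}"] = np.linalg.norm(ca_a - ca_b, axis=1)
    df = pd.DataFrame(rows)
    df.insert(0, "frame", idx)
    return df


@dataclass
class FeaturePCA:
    """Joint distance-feature PCA over one or more systems."""
    loadings: np.ndarray                 # (n_components, 6)
    explained_variance_ratio: np.ndarray
    projections: dict[str, np.ndarray]   # system -> (frames, n_components)
    dispersion: dict[str, float]         # trace of projection covariance
    centroids: dict[str, np.ndarray]

    def centroid_separation(self, a: str, b: str) -> float:
        return float(np.linalg.norm(self.centroids[a] - self.centroids[b]))


def pca_features(feature_sets: dict[str, pd.DataFrame],
                 n_components: int = 2) -> FeaturePCA:
    """PCA of pooled inter-helix distance features (the combined analysis).

    Features from all systems are concatenated and jointly mean-centered
    (no z-scoring); per-system projection clouds, dispersions (trace of the
    projection covariance) and centroid positions are reported.
    """
    names = list(feature_sets)
    cols = [c for c in feature_sets[names[0]].columns if c != "frame"]
    blocks = [np.asarray(feature_sets[n][cols], dtype=float) for n in names]
    pooled = np.vstack(blocks)
    if len(pooled) < 2:
        raise ValueError("need at least 2 frames across systems")
    pca = PCA(n_components=min(n_components, pooled.shape[1]))
    scores = pca.fit_transform(pooled)
    projections, dispersion, centroids = {}, {}, {}
    at = 0
    for name, block in zip(names, blocks):
        s = scores[at:at + len(block)]
        at += len(block)
        projections[name] = s
        centroids[name] = s.mean(axis=0)
        dispersion[name] = float(np.trace(np.cov(s.T))) if len(s) > 1 else 0.0
    return FeaturePCA(loadings=pca.components_,
                      explained_variance_ratio=pca.explained_variance_ratio_,
                      projections=projections, dispersion=dispersion,
                      centroids=centroids)


def export_mode_animation(mode_set: ModeSet, topology: Topology,
                          base_coords: np.ndarray, k: int, amplitude: float,
                          n_steps: int, pdb_path, arrows_path=None) -> None:
    """Multi-model PDB sweeping mean - amp*v_k .. mean + amp*v_k.

    Selection atoms move along the mode; all other atoms stay at their base
    positions.  An optional CSV lists the per-atom displacement vectors.
    """
    from .structures import Trajectory as _T, write_trajectory
    if not 0 <= k < len(mode_set.eigenvalues):
        raise IndexError(f"mode index {k} out of range")
    v = mode_set.eigenvectors[k].reshape(-1, 3)
    scales = np.linspace(-amplitude, amplitude, max(2, n_steps))
    base = np.asarray(base_coords, dtype=float).copy()
    base[mode_set.selection] = mode_set.mean_structure
    frames = np.stack([base] * len(scales))
    for i, c in enumerate(scales):
        frames[i, mode_set.selection] = mode_set.mean_structure + c * v
    write_trajectory(_T(frames, topology), pdb_path)
    if arrows_path is not None:
        pd.DataFrame({
            "atom_index": mode_set.selection,
            "dx": v[:, 0], "dy": v[:, 1], "dz": v[:, 2],
        }).to_csv(arrows_path, index=False)
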