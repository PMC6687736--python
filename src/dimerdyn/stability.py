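"""Trajectory stability: superposition, RMSD series, stable-window detection.

All downstream statistics (occupancies, secondary-structure content, average
structures, essential dynamics) are computed over a *stable window*: a
contiguous trajectory segment whose backbone RMSD series has plateaued.  The
qualification rule is transparent: a window qualifies when the least-squares
slope of its RMSD-vs-time series stays within `slope_tol` (A/ns), its
standard deviation within `sd_tol` (A), and every tenth of the window is
itself stationary: block SD within `sd_tol` and block mean within `sd_tol`
of the window mean (without the block guard a long plateau dilutes a
localized equilibration ramp out of the global statistics).  Among qualifying windows the longest wins, with ties broken
toward the latest start.  A trajectory with no qualifying window of at
least `min_span_ns` raises; there is never a silent full-range fallback.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import apply_transform, kabsch
from .structures import Trajectory

DEFAULT_MIN_SPAN_NS = 40.0
DEFAULT_SLOPE_TOL = 0.01   # A/ns
DEFAULT_SD_TOL = 0.5       # A


class DegenerateFitError(ValueError):
    """Fewer than three non-collinear atoms selected for superposition."""


class UnstableTrajectoryError(RuntimeError):
    """No window satisfies the stability rule."""


@dataclass(frozen=True)
class StableWindow:
    start_frame: int   # inclusive
    end_frame: int     # inclusive
    span_ns: float

    def __post_init__(self):
        if self.start_frame > self.end_frame:
            raise ValueError("start_frame must be <= end_frame")

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1

    def frame_indices(self) -> np.ndarray:
        return np.arange(self.start_frame, self.end_frame + 1)

    def to_dict(self) -> dict:
        return {"start_frame": self.start_frame, "end_frame": self.end_frame,
                "span_ns": self.span_ns}


def _check_selection(coords: np.ndarray) -> None:
    if len(coords) < 3:
        raise DegenerateFitError("superposition needs at least 3 atoms")
    centered = coords - coords.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise DegenerateFitError("selected atoms are collinear")


def superpose(mobile: np.ndarray, reference: np.ndarray,
              selection: np.ndarray | None = None,
              ) -> tuple[np.ndarray, np.ndarray, float]:
    """Kabsch fit of `mobile` onto `reference` over `selection`.

    Returns (rotation, translation, fitted RMSD over the selection).  The
    transform applies to the full coordinate set via
    :func:`dimerdyn.geometry.apply_transform`.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    sel = np.arange(len(mobile)) if selection is None else np.asarray(selection)
    _check_selection(mobile[sel])
    return kabsch(mobile[sel], reference[sel])


def rmsd_series(traj: Trajectory, reference: np.ndarray | None = None,
                selection: np.ndarray | None = None) -> np.ndarray:
    """Per-frame fitted RMSD (A) against a reference (default frame 0).

    Backbone atoms (N, CA, C, O) are the default selection.
    """
    sel = traj.topology.backbone_indices if selection is None else np.asarray(selection)
    ref = traj.coords[0] if reference is None else np.asarray(reference, dtype=float)
    _check_selection(ref[sel])
    out = np.empty(traj.n_frames)
    for t in range(traj.n_frames):
        _, _, out[t] = kabsch(traj.coords[t][sel], ref[sel])
    return out


def find_stable_window(series: np.ndarray, frame_interval_ps: float,
                       min_span_ns: float = DEFAULT_MIN_SPAN_NS,
                       slope_tol: float = DEFAULT_SLOPE_TOL,
                       sd_tol: float = DEFAULT_SD_TOL,
                       max_grid: int = 400) -> StableWindow:
    """Latest-longest plateau window of an RMSD series.

    Candidate windows are evaluated on a start/end grid (at most `max_grid`
    points per axis, exact for short series) with O(1) per-window slope and
    SD from prefix sums.
    """
    series = np.asarray(series, dtype=float)
    n = len(series)
    dt_ns = frame_interval_ps / 1000.0
    total_ns = (n - 1) * dt_ns
    if total_ns < min_span_ns:
        raise UnstableTrajectoryError(
            f"trajectory spans {total_ns:.1f} ns < required {min_span_ns} ns")
    t = np.arange(n) * dt_ns
    c_y = np.concatenate([[0.0], np.cumsum(series)])
    c_y2 = np.concatenate([[0.0], np.cumsum(series**2)])
    c_t = np.concatenate([[0.0], np.cumsum(t)])
    c_t2 = np.concatenate([[0.0], np.cumsum(t**2)])
    c_ty = np.concatenate([[0.0], np.cumsum(t * series)])
    stride = max(1, n // max_grid)
    starts = np.arange(0, n, stride)
    min_len = int(np.ceil(min_span_ns / dt_ns)) + 1
    best = None  # (length, start, end)
    for i in starts:
        ends = np.arange(i + min_len - 1, n, stride)
        if len(ends) == 0:
            continue
        if ends[-1] != n - 1:
            ends = np.append(ends, n - 1)
        m = (ends - i + 1).astype(float)
        sy = c_y[ends + 1] - c_y[i]
        sy2 = c_y2[ends + 1] - c_y2[i]
        st = c_t[ends + 1] - c_t[i]
        st2 = c_t2[ends + 1] - c_t2[i]
        sty = c_ty[ends + 1] - c_ty[i]
        denom = m * st2 - st**2
        slope = np.where(denom > 0, (m * sty - st * sy) / np.where(denom > 0, denom, 1), 0.0)
        var = sy2 / m - (sy / m) ** 2
        sd = np.sqrt(np.maximum(var, 0.0))
        ok = (np.abs(slope) <= slope_tol) & (sd <= sd_tol)
        for e in ends[ok]:
            length = e - i + 1
            cand = (length, i, e)
            if best is not None:
                bl, bi, _ = best
                if length < bl or (length == bl and i < bi):
                    continue
            if _blocks_stationary(c_y, c_y2, i, int(e), sd_tol):
                best = cand
    if best is None:
        raise UnstableTrajectoryError(
            "no stable window: RMSD never plateaus within the slope/SD "
            f"tolerances (slope_tol={slope_tol} A/ns, sd_tol={sd_tol} A)")
    length, i, e = best
    return StableWindow(int(i), int(e), (e - i) * dt_ns)


def _blocks_stationary(c_y, c_y2, start: int, end: int, sd_tol: float,
                       n_blocks: int = 10) -> bool:
    """Per-block SD and mean-level criteria (localized-transient guard)."""
    n = end - start + 1
    window_mean = (c_y[end + 1] - c_y[start]) / n
    bounds = np.linspace(start, end + 1, n_blocks + 1).round().astype(int)
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        m = hi - lo
        if m < 2:
            continue
        sy = c_y[hi] - c_y[lo]
        sy2 = c_y2[hi] - c_y2[lo]
        mean = sy / m
        var = sy2 / m - mean**2
        if np.sqrt(max(var, 0.0)) > sd_tol:
            return False
        if abs(mean - window_mean) > sd_tol:
            return False
    return True


def average_structure(traj: Trajectory, window: StableWindow,
                      selection: np.ndarray | None = None) -> np.ndarray:
    """Two-pass iterative mean structure over the window.

    Frames are superposed (over `selection`, default backbone) onto the first
    window frame, averaged, then superposed onto that mean and averaged
    again.  The transform of each fit is applied to all atoms.
    """
    sel = traj.topology.backbone_indices if selection is None else np.asarray(selection)
    idx = window.frame_indices()
    if idx[-1] >= traj.n_frames:
        raise ValueError("window exceeds trajectory length")
    ref = traj.coords[idx[0]]
    for _ in range(2):
        acc = np.zeros_like(ref)
        for t in idx:
            rot, trans, _ = kabsch(traj.coords[t][sel], ref[sel])
            acc += apply_transform(traj.coords[t], rot, trans)
        ref = acc / len(idx)
    return ref
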