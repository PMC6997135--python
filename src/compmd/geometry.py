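"""Superposition and basic conformational descriptors.

RMSD here is always the least-squares value after optimal rigid-body
superposition (Kabsch), i.e. RMSD = sqrt(Σ δ_i² / N) over the selected atoms
with δ_i the residual per-atom displacement.  RMSF is measured about the
iteratively superposed ensemble mean, and converts to a crystallographic
B-factor through B = (8π²/3)·RMSF².
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    DegenerateGeometryError,
    InsufficientFramesError,
    SelectionError,
)
from .traj_io import ELEMENT_MASSES, Frame, Trajectory

__all__ = [
    "SuperpositionTransform",
    "RmsdResult",
    "kabsch_superpose",
    "rmsd_series",
    "rmsf",
    "bfactor_from_rmsf",
    "radius_of_gyration",
    "distance_series",
    "angle_series",
    "pearson_correlation",
    "element_masses",
]


@dataclass
class SuperpositionTransform:
    """Proper rotation + translation mapping mobile onto reference frames."""

    rotation: np.ndarray      # 3×3, det = +1
    translation: np.ndarray   # 3-vector, Å

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class RmsdResult:
    value: float                    # Å
    n_atoms: int
    per_atom_deviation: np.ndarray  # δ_i, Å


def _as_coords(obj) -> np.ndarray:
    if isinstance(obj, Trajectory):
        if obj.n_frames != 1:
            raise ValueError("expected a single frame")
        return obj.xyz[0]
    if isinstance(obj, Frame):
        return obj.coordinates
    return np.asarray(obj, dtype=float)


def _resolve_sel(sel, n_atoms: int) -> np.ndarray:
    sel = np.arange(n_atoms) if sel is None else np.asarray(sel, dtype=int)
    if sel.size == 0:
        raise SelectionError("empty atom selection")
    return sel


def _kabsch_matrix(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Optimal proper rotation for centered coordinate sets."""
    h = mobile.T @ reference
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    flip = np.diag([1.0, 1.0, d])
    return vt.T @ flip @ u.T


def kabsch_superpose(mobile, reference, sel=None
                     ) -> tuple[SuperpositionTransform, RmsdResult]:
    """Least-squares superposition of ``mobile`` onto ``reference``.

    The rotation branch is corrected to a proper rotation (det +1), so
    mirror images are never matched by reflection.  Raises
    :class:`DegenerateGeometryError` for <3 or collinear selected atoms.
    """
    mob = _as_coords(mobile)
    ref = _as_coords(reference)
    sel = _resolve_sel(sel, mob.shape[0])
    if sel.size < 3:
        raise DegenerateGeometryError(
            "superposition needs at least 3 selected atoms")
    p = mob[sel]
    q = ref[sel]
    p_c = p - p.mean(axis=0)
    q_c = q - q.mean(axis=0)
    # collinear points span a rank<2 subspace and leave a free rotation
    if np.linalg.matrix_rank(p_c, tol=1e-8) < 2:
        raise DegenerateGeometryError("selected atoms are collinear")
    rot = _kabsch_matrix(p_c, q_c)
    translation = q.mean(axis=0) - rot @ p.mean(axis=0)
    transform = SuperpositionTransform(rotation=rot, translation=translation)
    deviations = np.linalg.norm(transform.apply(p) - q, axis=1)
    value = float(np.sqrt(np.mean(deviations**2)))
    return transform, RmsdResult(value=value, n_atoms=sel.size,
                                 per_atom_deviation=deviations)


def _batch_superpose(xyz: np.ndarray, reference: np.ndarray,
                     sel: np.ndarray) -> np.ndarray:
    """Superpose every frame of ``xyz`` (F,N,3) onto ``reference`` using
    the selection for the fit; returns transformed copies of all atoms."""
    p = xyz[:, sel, :]
    q = reference[sel]
    p_mean = p.mean(axis=1, keepdims=True)
    q_mean = q.mean(axis=0)
    h = np.einsum("fni,nj->fij", p - p_mean, q - q_mean)
    u, _, vt = np.linalg.svd(h)
    det = np.linalg.det(np.einsum("fij,fjk->fik",
                                  np.swapaxes(vt, 1, 2), np.swapaxes(u, 1, 2)))
    flip = np.repeat(np.eye(3)[None], xyz.shape[0], axis=0)
    flip[:, 2, 2] = np.sign(det)
    rot = np.einsum("fij,fjk,fkl->fil", np.swapaxes(vt, 1, 2), flip,
                    np.swapaxes(u, 1, 2))
    out = np.einsum("fij,fnj->fni", rot, xyz - p_mean) + q_mean
    return out


def _batch_rmsd(xyz: np.ndarray, reference: np.ndarray,
                sel: np.ndarray) -> np.ndarray:
    moved = _batch_superpose(xyz, reference, sel)
    d = moved[:, sel, :] - reference[sel]
    return np.sqrt(np.mean(np.sum(d * d, axis=2), axis=1))


@dataclass
class SeriesStats:
    values: np.ndarray
    mean: float
    sd: float
    window: tuple[int, int]   # [start, stop) frame range of the statistics


def rmsd_series(traj: Trajectory, reference, sel=None,
                equilibration_fraction: float = 0.1) -> SeriesStats:
    """Per-frame superposed RMSD versus a reference frame.

    The summary mean ± sd is taken over the frames after an equilibration
    cutoff, by default discarding the first 10 % of the trajectory.
    """
    ref = _as_coords(reference)
    sel = _resolve_sel(sel, traj.n_atoms)
    values = _batch_rmsd(traj.xyz, ref, sel)
    start = int(np.floor(equilibration_fraction * traj.n_frames))
    start = min(start, traj.n_frames - 1)
    window = values[start:]
    return SeriesStats(values=values, mean=float(window.mean()),
                       sd=float(window.std()), window=(start, traj.n_frames))


def rmsf(traj: Trajectory, sel=None, n_iterations: int = 2,
         fit_sel=None) -> np.ndarray:
    """Per-atom root-mean-square fluctuation about the ensemble mean.

    Frames are superposed onto the running mean structure, the mean is
    recomputed, and the procedure is iterated (twice by default) so the
    reference is self-consistent.  ``fit_sel`` optionally restricts the
    superposition fit to a rigid core (defaults to ``sel``), so a mobile
    segment does not drag the reference frame.  Returns RMSF for the
    selected atoms, Å.
    """
    if traj.n_frames < 2:
        raise InsufficientFramesError("RMSF needs at least 2 frames")
    sel = _resolve_sel(sel, traj.n_atoms)
    fit = sel if fit_sel is None else _resolve_sel(fit_sel, traj.n_atoms)
    xyz = traj.xyz
    mean = xyz.mean(axis=0)
    for _ in range(n_iterations):
        xyz = _batch_superpose(xyz, mean, fit)
        mean = xyz.mean(axis=0)
    d = xyz[:, sel, :] - mean[sel]
    return np.sqrt(np.mean(np.sum(d * d, axis=2), axis=0))


def bfactor_from_rmsf(rmsf_values) -> np.ndarray:
    """Convert RMSF (Å) to crystallographic B-factor (Å²): B = 8π²/3 · RMSF²."""
    arr = np.asarray(rmsf_values, dtype=float)
    if np.any(arr < 0):
        raise ValueError("RMSF must be non-negative")
    result = (8.0 * np.pi**2 / 3.0) * arr**2
    return result if arr.ndim else float(result)


def element_masses(traj: Trajectory, sel=None) -> np.ndarray:
    """Atomic masses for a selection, from a built-in element table."""
    sel = _resolve_sel(sel, traj.n_atoms)
    return np.array([ELEMENT_MASSES.get(traj.topology[i].element.upper(), 12.011)
                     for i in sel])


def radius_of_gyration(frame, sel=None, masses=None) -> float:
    """Mass-weighted radius of gyration about the center of mass (Å).

    Masses default to unit weights (geometric Rg); pass
    :func:`element_masses` output for a mass-weighted value.
    """
    coords = _as_coords(frame)
    sel = _resolve_sel(sel, coords.shape[0])
    x = coords[sel]
    m = np.ones(sel.size) if masses is None else np.asarray(masses, dtype=float)
    if m.shape != (sel.size,):
        raise ValueError("masses must match the selection size")
    if np.any(m < 0) or m.sum() <= 0:
        raise ValueError("masses must be positive with nonzero total")
    com = (m[:, None] * x).sum(axis=0) / m.sum()
    return float(np.sqrt((m * np.sum((x - com) ** 2, axis=1)).sum() / m.sum()))


def distance_series(traj: Trajectory, atom_i: int, atom_j: int) -> np.ndarray:
    """Euclidean distance between two atoms per frame (Å)."""
    if atom_i == atom_j:
        raise ValueError("distance requires two distinct atoms")
    d = traj.xyz[:, atom_i, :] - traj.xyz[:, atom_j, :]
    return np.linalg.norm(d, axis=1)


def angle_series(traj: Trajectory, atom_i: int, atom_j: int,
                 atom_k: int) -> np.ndarray:
    """Angle at the middle atom ``atom_j``, degrees in [0, 180], per frame."""
    if len({atom_i, atom_j, atom_k}) != 3:
        raise ValueError("angle requires three distinct atoms")
    v1 = traj.xyz[:, atom_i, :] - traj.xyz[:, atom_j, :]
    v2 = traj.xyz[:, atom_k, :] - traj.xyz[:, atom_j, :]
    cosang = np.sum(v1 * v2, axis=1) / (
        np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1))
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def pearson_correlation(x, y) -> float:
    """Pearson correlation coefficient r ∈ [−1, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("series must be 1-D of equal length")
    if x.size < 3:
        raise ValueError("correlation needs at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance series")
    return float(np.corrcoef(x, y)[0, 1])
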