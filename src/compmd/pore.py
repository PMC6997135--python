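"""Maximal-probe-radius pore profiling along a channel axis.

At stations spaced along the axis, the largest sphere that fits without
overlapping any atom's van der Waals sphere is found by maximizing
``min_i (|p − x_i| − r_i)`` over the plane perpendicular to the axis — a
coarse in-plane grid followed by deterministic pattern-search refinement.
Station radii classify water passage: < 1.15 Å blocked, 1.15–2.30 Å
single-file water, > 2.30 Å bulk (two or more waters abreast), using the
conventional 1.15 Å effective water radius.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .traj_io import ELEMENT_VDW, Trajectory

__all__ = [
    "SINGLE_FILE_RADIUS",
    "BULK_RADIUS",
    "PoreStation",
    "PoreProfile",
    "probe_radius_at",
    "optimize_center",
    "pore_profile",
]

SINGLE_FILE_RADIUS = 1.15  # Å: smallest radius passing one water
BULK_RADIUS = 2.30         # Å: two waters abreast


def probe_radius_at(point, atoms, radii) -> float:
    """Largest probe sphere centered at ``point`` not overlapping any atom.

    Equals ``min_i (|point − atom_i| − vdw_i)``; negative when the point lies
    inside an atom's van der Waals sphere.
    """
    atoms = np.asarray(atoms, dtype=float)
    if atoms.ndim != 2 or atoms.shape[0] == 0:
        raise ValueError("need at least one atom")
    radii = np.asarray(radii, dtype=float)
    d = np.linalg.norm(atoms - np.asarray(point, dtype=float), axis=1)
    return float(np.min(d - radii))


def optimize_center(station: np.ndarray, in_plane_u: np.ndarray,
                    in_plane_v: np.ndarray, atoms: np.ndarray,
                    radii: np.ndarray, search_radius: float = 5.0,
                    coarse_pitch: float = 0.5,
                    tol: float = 0.05) -> tuple[np.ndarray, float]:
    """Maximize the probe radius over the plane through ``station``.

    Coarse grid at 0.5 Å pitch within ``search_radius`` of the axis point,
    then pattern search halving the step until below ``tol`` (0.05 Å).
    Fully deterministic: grid ties resolve to the first maximal point.
    """
    if search_radius <= 0:
        raise ValueError("search_radius must be > 0")
    station = np.asarray(station, dtype=float)

    def value(a, b):
        return probe_radius_at(station + a * in_plane_u + b * in_plane_v,
                               atoms, radii)

    ticks = np.arange(-search_radius, search_radius + coarse_pitch / 2,
                      coarse_pitch)
    best_a = best_b = 0.0
    best = value(0.0, 0.0)
    for a in ticks:
        for b in ticks:
            if a * a + b * b > search_radius**2:
                continue
            v = value(a, b)
            if v > best + 1e-12:
                best, best_a, best_b = v, a, b

    step = coarse_pitch / 2.0
    while step >= tol:
        improved = True
        while improved:
            improved = False
            for da, db in ((step, 0), (-step, 0), (0, step), (0, -step)):
                a, b = best_a + da, best_b + db
                if a * a + b * b > search_radius**2:
                    continue
                v = value(a, b)
                if v > best + 1e-12:
                    best, best_a, best_b = v, a, b
                    improved = True
        step /= 2.0
    center = station + best_a * in_plane_u + best_b * in_plane_v
    return center, best


def _classify(radius: float) -> str:
    if radius < SINGLE_FILE_RADIUS:
        return "blocked"
    if radius <= BULK_RADIUS:
        return "single-file"
    return "bulk"


@dataclass
class PoreStation:
    axial_position: float      # Å along the axis from the first endpoint
    center: np.ndarray         # optimized probe center
    radius: float              # Å
    classification: str        # blocked / single-file / bulk
    nearest_residue: tuple     # (chain, residue_index) of the limiting atom


@dataclass
class PoreProfile:
    stations: list
    step: float

    def min_station(self) -> PoreStation:
        return min(self.stations, key=lambda s: s.radius)

    def radii(self) -> np.ndarray:
        return np.array([s.radius for s in self.stations])

    def axial_positions(self) -> np.ndarray:
        return np.array([s.axial_position for s in self.stations])


def _axis_frame(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors spanning the plane perpendicular to ``direction``."""
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, direction)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(direction, helper)
    u /= np.linalg.norm(u)
    v = np.cross(direction, u)
    v /= np.linalg.norm(v)
    return u, v


def _resolve_radii(traj: Trajectory, radii, topology_table) -> np.ndarray:
    if radii is not None:
        radii = np.asarray(radii, dtype=float)
        if radii.shape != (traj.n_atoms,):
            raise ValueError("radii must provide one value per atom")
        return radii
    if topology_table is not None:
        return topology_table.align(traj.topology, "vdw_radius")
    return np.array([ELEMENT_VDW.get(a.element.upper(), 1.7)
                     for a in traj.topology])


def pore_profile(traj: Trajectory, axis="auto", step: float = 0.25,
                 search_radius: float = 5.0, radii=None,
                 topology_table=None, frame: int = 0,
                 lining_sel=None) -> PoreProfile:
    """Probe-radius profile of a channel along an axis.

    ``axis`` is a pair of 3-vectors (endpoints) or ``"auto"``, which takes
    the principal axis of the channel-lining selection (``lining_sel``,
    default all atoms) spanning its extent.  Van der Waals radii come from
    an explicit per-atom array, else a topology table, else a built-in
    element table.  At each station the in-plane probe center is optimized;
    the nearest residue is the residue of the atom realizing the minimum
    at the optimized center.
    """
    if traj.n_atoms == 0:
        raise ValueError("structure is empty")
    coords = traj.xyz[frame]
    radii = _resolve_radii(traj, radii, topology_table)

    if isinstance(axis, str) and axis == "auto":
        sel = (np.arange(traj.n_atoms) if lining_sel is None
               else np.asarray(lining_sel, int))
        pts = coords[sel]
        centroid = pts.mean(axis=0)
        centered = pts - centroid
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        direction = vt[0]
        if direction[np.argmax(np.abs(direction))] < 0:
            direction = -direction
        t = centered @ direction
        p0 = centroid + t.min() * direction
        p1 = centroid + t.max() * direction
    else:
        p0, p1 = (np.asarray(p, dtype=float) for p in axis)
    length = np.linalg.norm(p1 - p0)
    if length == 0:
        raise ValueError("axis endpoints must be distinct")
    direction = (p1 - p0) / length
    u, v = _axis_frame(direction)

    stations = []
    positions = np.arange(0.0, length + step / 2, step)
    for z in positions:
        station_point = p0 + z * direction
        center, radius = optimize_center(station_point, u, v, coords, radii,
                                         search_radius=search_radius)
        d = np.linalg.norm(coords - center, axis=1) - radii
        limiting = int(np.argmin(d))
        atom = traj.topology[limiting]
        stations.append(PoreStation(
            axial_position=float(z), center=center, radius=float(radius),
            classification=_classify(radius),
            nearest_residue=(atom.chain, atom.residue_index)))
    return PoreProfile(stations=stations, step=float(step))
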