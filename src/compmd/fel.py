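"""PCA of superposed coordinates and free-energy landscapes.

The covariance of the superposed Cartesian coordinates is diagonalized; the
leading principal components (PC1, PC2) serve as reaction coordinates.  The
free-energy surface is the Boltzmann inversion of the sampled probability,
ΔG(X) = −k_B·T·ln P(X), shifted so its minimum is zero.  Bins never visited
carry NaN ("unsampled") rather than an infinite energy.  Basins are
connected low-ΔG bin regions; each reports its member frames, the time
intervals covering most of them, occupancy, and an occupancy-based basin
free energy −k_B·T·ln ΣP.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .errors import InsufficientFramesError
from .geometry import _batch_superpose
from .traj_io import Trajectory

__all__ = [
    "BOLTZMANN_KJ",
    "PcaModel",
    "FELGrid",
    "Basin",
    "pca",
    "fel_grid",
    "find_basins",
    "pc_gaussianity",
]

BOLTZMANN_KJ = 0.0083145  # k_B in kJ·mol⁻¹·K⁻¹


@dataclass
class PcaModel:
    mean: np.ndarray          # (n_sel, 3) mean structure after superposition
    components: np.ndarray    # (n_modes, 3·n_sel) orthonormal rows
    eigenvalues: np.ndarray   # Å² variance per mode, non-increasing
    projections: np.ndarray   # (n_frames, n_modes)
    sel: np.ndarray

    def reconstruct(self, frame_index: int) -> np.ndarray:
        """Invert the projection of one frame back to superposed coordinates."""
        flat = self.projections[frame_index] @ self.components
        return self.mean + flat.reshape(-1, 3)


def pca(traj: Trajectory, sel=None, n_iterations: int = 2) -> PcaModel:
    """Principal component analysis of superposed coordinates.

    Frames are superposed onto the (iterated) mean structure first, so rigid
    body motion does not leak into the modes.  Coordinates are mass
    unweighted.  Eigenvector signs follow a deterministic convention: the
    largest-magnitude component of each mode is positive.
    """
    if traj.n_frames < 3:
        raise InsufficientFramesError("PCA needs at least 3 frames")
    sel = np.arange(traj.n_atoms) if sel is None else np.asarray(sel, int)
    xyz = traj.xyz
    mean = xyz.mean(axis=0)
    for _ in range(n_iterations):
        xyz = _batch_superpose(xyz, mean, sel)
        mean = xyz.mean(axis=0)
    x = (xyz[:, sel, :] - mean[sel]).reshape(traj.n_frames, -1)
    # economy SVD: modes with zero variance beyond min(F, 3k) are irrelevant
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    eigenvalues = s**2 / traj.n_frames
    components = vt
    # sign convention
    for k in range(components.shape[0]):
        j = np.argmax(np.abs(components[k]))
        if components[k, j] < 0:
            components[k] = -components[k]
    projections = x @ components.T
    return PcaModel(mean=mean[sel], components=components,
                    eigenvalues=eigenvalues, projections=projections,
                    sel=sel)


@dataclass
class FELGrid:
    x_edges: np.ndarray
    y_edges: np.ndarray
    probability: np.ndarray   # P(X), sums to 1
    delta_g: np.ndarray       # kJ·mol⁻¹, min 0; NaN marks unsampled bins
    temperature: float        # K
    boltzmann_constant: float
    projections: np.ndarray   # (n_frames, 2) used to build the grid

    @property
    def n_frames(self) -> int:
        return self.projections.shape[0]

    def bin_of_frames(self) -> tuple[np.ndarray, np.ndarray]:
        """(ix, iy) bin index per frame, clipped to the grid."""
        ix = np.clip(np.searchsorted(self.x_edges, self.projections[:, 0],
                                     side="right") - 1,
                     0, len(self.x_edges) - 2)
        iy = np.clip(np.searchsorted(self.y_edges, self.projections[:, 1],
                                     side="right") - 1,
                     0, len(self.y_edges) - 2)
        return ix, iy


def fel_grid(projections, temperature: float = 300.0,
             bins: int = 50, pad_fraction: float = 0.02) -> FELGrid:
    """2-D free-energy surface over (PC1, PC2) via Boltzmann inversion.

    The histogram range is the projection range padded by 2 % per side.
    ΔG = −k_B·T·ln P, shifted so the sampled minimum is zero; empty bins are
    NaN (unsampled), never a finite energy.
    """
    proj = np.asarray(projections, dtype=float)
    if proj.ndim != 2 or proj.shape[1] < 2:
        raise ValueError("projections must be (n_frames, >=2)")
    if temperature <= 0:
        raise ValueError("temperature must be > 0 K")
    if bins < 2:
        raise ValueError("need at least 2 bins per axis")
    proj = proj[:, :2]

    def padded_edges(v):
        lo, hi = v.min(), v.max()
        span = hi - lo
        if span == 0:
            lo, hi = lo - 0.5, hi + 0.5
        else:
            lo, hi = lo - pad_fraction * span, hi + pad_fraction * span
        return np.linspace(lo, hi, bins + 1)

    x_edges = padded_edges(proj[:, 0])
    y_edges = padded_edges(proj[:, 1])
    counts, _, _ = np.histogram2d(proj[:, 0], proj[:, 1],
                                  bins=[x_edges, y_edges])
    probability = counts / counts.sum()
    if np.count_nonzero(counts) == 1:
        warnings.warn("all projections fall into a single bin; "
                      "the free-energy surface is degenerate")
    with np.errstate(divide="ignore"):
        delta_g = np.where(probability > 0,
                           -BOLTZMANN_KJ * temperature *
                           np.log(np.where(probability > 0, probability, 1.0)),
                           np.nan)
    delta_g -= np.nanmin(delta_g)
    return FELGrid(x_edges=x_edges, y_edges=y_edges, probability=probability,
                   delta_g=delta_g, temperature=float(temperature),
                   boltzmann_constant=BOLTZMANN_KJ, projections=proj)


@dataclass
class Basin:
    bins: np.ndarray            # (k, 2) bin indices of the region
    min_delta_g: float          # kJ·mol⁻¹
    occupancy: float            # ΣP over the basin bins
    free_energy: float          # −k_B·T·ln occupancy
    frames: np.ndarray          # member frame indices
    time_intervals: list        # frame-index (start, stop) runs covering ≥80%


def find_basins(grid: FELGrid, depth_cut: float,
                coverage: float = 0.8,
                min_occupancy: float = 0.01) -> list[Basin]:
    """Connected low-free-energy regions of the surface.

    A basin is an 8-connected region of bins with ΔG ≤ ``depth_cut``
    (unsampled bins never belong).  Regions holding less than
    ``min_occupancy`` of the total probability are sampling noise (stray
    sparsely hit bins) and are discarded.  Basins are sorted by their
    minimum ΔG.  ``time_intervals`` lists the contiguous frame runs,
    longest first, that together cover at least ``coverage`` of the basin's
    frames.
    """
    if depth_cut <= 0:
        raise ValueError("depth_cut must be > 0")
    mask = np.nan_to_num(grid.delta_g, nan=np.inf) <= depth_cut
    labels, n_regions = ndimage.label(mask, structure=np.ones((3, 3)))
    ix, iy = grid.bin_of_frames()
    frame_region = labels[ix, iy]

    basins = []
    for region in range(1, n_regions + 1):
        region_bins = np.argwhere(labels == region)
        frames = np.flatnonzero(frame_region == region)
        occupancy = float(
            grid.probability[region_bins[:, 0], region_bins[:, 1]].sum())
        if occupancy < min_occupancy:
            continue
        kt = grid.boltzmann_constant * grid.temperature
        runs = _contiguous_runs(frames)
        runs.sort(key=lambda r: r[1] - r[0], reverse=True)
        covered, intervals = 0, []
        needed = coverage * max(len(frames), 1)
        for start, stop in runs:
            intervals.append((int(start), int(stop)))
            covered += stop - start
            if covered >= needed:
                break
        basins.append(Basin(
            bins=region_bins,
            min_delta_g=float(np.nanmin(
                grid.delta_g[region_bins[:, 0], region_bins[:, 1]])),
            occupancy=occupancy,
            free_energy=float(-kt * np.log(occupancy)) if occupancy > 0
            else float("inf"),
            frames=frames,
            time_intervals=sorted(intervals),
        ))
    basins.sort(key=lambda b: b.min_delta_g)
    return basins


def _contiguous_runs(indices: np.ndarray) -> list:
    """[start, stop) runs of consecutive integers."""
    if indices.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(indices) > 1)
    starts = np.concatenate(([0], breaks + 1))
    stops = np.concatenate((breaks + 1, [indices.size]))
    return [(int(indices[a]), int(indices[b - 1]) + 1)
            for a, b in zip(starts, stops)]


@dataclass
class GaussianityReport:
    excess_kurtosis: float
    skewness: float
    bimodality_coefficient: float  # Sarle's b = (skew² + 1) / kurtosis


def pc_gaussianity(series) -> GaussianityReport:
    """Non-Gaussianity descriptors of a principal-component projection.

    Reports the sample excess kurtosis and Sarle's bimodality coefficient
    b = (skew² + 1) / kurtosis (plain, non-excess kurtosis in the
    denominator).  A Gaussian gives excess kurtosis 0 and b ≈ 1/3; a
    well-separated symmetric two-point mixture drives excess kurtosis toward
    −2 and b toward 1.  Values are reported, not thresholded.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 20:
        raise ValueError("need a 1-D series of at least 20 samples")
    if np.ptp(x) == 0:
        raise ValueError("moments undefined for a constant series")
    excess = float(stats.kurtosis(x, fisher=True, bias=True))
    skew = float(stats.skew(x, bias=True))
    return GaussianityReport(
        excess_kurtosis=excess,
        skewness=skew,
        bimodality_coefficient=(skew**2 + 1.0) / (excess + 3.0),
    )
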