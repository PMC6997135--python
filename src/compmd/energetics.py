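"""End-state binding free-energy bookkeeping (MM/PB(GB)SA style).

The ledger is ΔG_bind = ΔH − TΔS with
ΔH = ΔE_VDW + ΔE_ELE + ΔG_polar + ΔG_nonpolar: vacuum Lennard-Jones and
Coulomb cross terms computed here; polar solvation (PB/GB) and the entropy
term are accepted as externally computed inputs; nonpolar solvation is the
linear SASA model γ·SASA + β.  Per-residue decomposition splits the
receptor-ligand interaction over receptor residues and ranks them by total
contribution.  All energies in kJ·mol⁻¹, distances in Å, charges in
elementary charges.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ClashError, SchemaError, TableParseError
from .traj_io import TopologyTable, Trajectory

__all__ = [
    "COULOMB_CONSTANT",
    "EnergyComponents",
    "coulomb_lj_interaction",
    "shrake_rupley_sasa",
    "nonpolar_solvation",
    "binding_free_energy",
    "per_residue_decomposition",
    "load_component_table",
]

# f = 1/(4πε0) in kJ·mol⁻¹·Å·e⁻²
COULOMB_CONSTANT = 1389.35458

# SASA→energy coefficients: 0.00542 kcal·mol⁻¹·Å⁻² and 0.92 kcal·mol⁻¹
GAMMA_KJ_PER_A2 = 0.0227
BETA_KJ = 3.849


@dataclass
class EnergyComponents:
    """The free-energy ledger; invariants enforced at construction."""

    vdw: float
    ele: float
    polar_solv: float
    nonpolar_solv: float
    entropy_term: float     # TΔS, kJ·mol⁻¹
    enthalpy: float         # ΔH
    binding: float          # ΔG_bind
    temperature: float = 300.0

    def __post_init__(self):
        parts = self.vdw + self.ele + self.polar_solv + self.nonpolar_solv
        if abs(self.enthalpy - parts) > 1e-6:
            raise ValueError("enthalpy must equal the sum of its components")
        if abs(self.binding - (self.enthalpy - self.entropy_term)) > 1e-6:
            raise ValueError("binding must equal enthalpy - entropy_term")

    @property
    def polar_total(self) -> float:
        """ELE driving force: vacuum electrostatics + polar solvation."""
        return self.ele + self.polar_solv

    @property
    def nonpolar_total(self) -> float:
        """VDW driving force: vacuum Lennard-Jones + nonpolar solvation."""
        return self.vdw + self.nonpolar_solv


def binding_free_energy(vdw: float, ele: float, polar_solv: float,
                        nonpolar_solv: float, entropy_term: float,
                        temperature: float = 300.0) -> EnergyComponents:
    """Assemble the ledger: ΔH = sum of components, ΔG_bind = ΔH − TΔS."""
    for name, v in (("vdw", vdw), ("ele", ele), ("polar_solv", polar_solv),
                    ("nonpolar_solv", nonpolar_solv),
                    ("entropy_term", entropy_term)):
        if not np.isfinite(v):
            raise ValueError(f"{name} must be finite")
    enthalpy = vdw + ele + polar_solv + nonpolar_solv
    return EnergyComponents(
        vdw=vdw, ele=ele, polar_solv=polar_solv,
        nonpolar_solv=nonpolar_solv, entropy_term=entropy_term,
        enthalpy=enthalpy, binding=enthalpy - entropy_term,
        temperature=temperature)


def _pair_energies(coords_a, coords_b, q_a, q_b, sig_a, sig_b, eps_a, eps_b,
                   dielectric: float, cutoff: float | None
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Per-pair (ele, vdw) matrices with Lorentz–Berthelot combination."""
    delta = coords_a[:, None, :] - coords_b[None, :, :]
    r = np.linalg.norm(delta, axis=2)
    if np.any(r < 0.1):
        raise ClashError("interacting atoms closer than 0.1 Å")
    ele = COULOMB_CONSTANT * np.outer(q_a, q_b) / (dielectric * r)
    sigma = 0.5 * (sig_a[:, None] + sig_b[None, :])
    epsilon = np.sqrt(np.outer(eps_a, eps_b))
    sr6 = (sigma / r) ** 6
    vdw = 4.0 * epsilon * (sr6**2 - sr6)
    if cutoff is not None:
        mask = r <= cutoff
        ele = ele * mask
        vdw = vdw * mask
    return ele, vdw


def coulomb_lj_interaction(traj: Trajectory, receptor_sel, ligand_sel,
                           topology_table: TopologyTable,
                           dielectric: float = 1.0,
                           cutoff: float | None = None,
                           frame: int = 0) -> tuple[float, float]:
    """Cross-interaction (ele, vdw) between two selections, kJ·mol⁻¹.

    ele = Σ f·q_i·q_j / (ε·r_ij); vdw = Σ 4ε_ij[(σ_ij/r)¹² − (σ_ij/r)⁶]
    with σ combined arithmetically and ε geometrically.  No cutoff by
    default.
    """
    receptor_sel = np.asarray(receptor_sel, dtype=int)
    ligand_sel = np.asarray(ligand_sel, dtype=int)
    if receptor_sel.size == 0 or ligand_sel.size == 0:
        raise ValueError("both selections must be non-empty")
    q = topology_table.align(traj.topology, "charge")
    sig = topology_table.align(traj.topology, "lj_sigma")
    eps = topology_table.align(traj.topology, "lj_epsilon")
    coords = traj.xyz[frame]
    ele, vdw = _pair_energies(
        coords[receptor_sel], coords[ligand_sel],
        q[receptor_sel], q[ligand_sel], sig[receptor_sel], sig[ligand_sel],
        eps[receptor_sel], eps[ligand_sel], dielectric, cutoff)
    return float(ele.sum()), float(vdw.sum())


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic, nearly uniform unit-sphere point set."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    rho = np.sqrt(1.0 - z**2)
    return np.column_stack((rho * np.cos(phi), rho * np.sin(phi), z))


def shrake_rupley_sasa(coords, radii, sel=None, probe: float = 1.4,
                       n_points: int = 960) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Å²), point-sampling method.

    Each selected atom's expanded sphere (r + probe) is sampled with a fixed
    Fibonacci lattice; a point is exposed iff it lies outside every other
    atom's expanded sphere.  SASA_i = exposed fraction × 4π(r_i + probe)².
    """
    if n_points < 50:
        raise ValueError("n_points < 50 gives unusable resolution")
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if np.any(radii <= 0):
        raise ValueError("radii must be positive")
    n = coords.shape[0]
    sel = np.arange(n) if sel is None else np.asarray(sel, dtype=int)
    sphere = _fibonacci_sphere(n_points)
    expanded = radii + probe
    out = np.zeros(sel.size)
    for k, i in enumerate(sel):
        points = coords[i] + expanded[i] * sphere
        buried = np.zeros(n_points, dtype=bool)
        d_atoms = np.linalg.norm(coords - coords[i], axis=1)
        neighbors = np.flatnonzero(
            (d_atoms < expanded + expanded[i]) & (np.arange(n) != i))
        for j in neighbors:
            buried |= (np.linalg.norm(points - coords[j], axis=1)
                       < expanded[j])
            if buried.all():
                break
        exposed = 1.0 - buried.mean()
        out[k] = exposed * 4.0 * np.pi * expanded[i] ** 2
    return out


def nonpolar_solvation(sasa_total: float, gamma: float = GAMMA_KJ_PER_A2,
                       beta: float = BETA_KJ) -> float:
    """Linear SASA model of nonpolar solvation: γ·SASA + β (kJ·mol⁻¹).

    For a binding Δ, evaluate on complex, receptor and ligand separately and
    take value(complex) − value(receptor) − value(ligand).
    """
    if sasa_total < 0:
        raise ValueError("SASA must be non-negative")
    return gamma * sasa_total + beta


def residue_total(e_vdw: float, e_ele: float, e_gb: float,
                  e_gbsur: float) -> float:
    """Total per-residue contribution: sum of the four decomposition terms."""
    return e_vdw + e_ele + e_gb + e_gbsur


def _frame_schedule(n_frames: int, equilibration_fraction: float,
                    max_frames: int) -> np.ndarray:
    """Evenly strided frames after an equilibration cutoff."""
    start = int(np.floor(equilibration_fraction * n_frames))
    start = min(start, n_frames - 1)
    available = np.arange(start, n_frames)
    if available.size <= max_frames:
        return available
    idx = np.linspace(0, available.size - 1, max_frames).round().astype(int)
    return available[np.unique(idx)]


def per_residue_decomposition(traj: Trajectory, receptor_sel, ligand_sel,
                              topology_table: TopologyTable,
                              solvation_table: pd.DataFrame | None = None,
                              dielectric: float = 1.0,
                              equilibration_fraction: float = 0.1,
                              max_frames: int = 180) -> pd.DataFrame:
    """Residue-by-residue receptor–ligand interaction energies.

    Frames are sampled evenly after discarding the first 10 % of the
    trajectory (at most ``max_frames`` of them, mirroring an every-0.5 ns
    schedule).  Per residue and frame, e_vdw/e_ele are the Coulomb/LJ cross
    terms of that residue's atoms with the ligand; e_gb/e_gbsur come from an
    optional per-residue solvation table (columns ``residue_index``,
    ``e_gb``, ``e_gbsur``; zero and flagged when absent); e_tot is their
    sum.  Output rows are ranked by mean e_tot ascending (strongest binders
    first), with mean ± sd columns per component.
    """
    receptor_sel = np.asarray(receptor_sel, dtype=int)
    ligand_sel = np.asarray(ligand_sel, dtype=int)
    q = topology_table.align(traj.topology, "charge")
    sig = topology_table.align(traj.topology, "lj_sigma")
    eps = topology_table.align(traj.topology, "lj_epsilon")

    residue_keys: list[tuple[str, int]] = []
    residue_of_atom = np.empty(receptor_sel.size, dtype=int)
    index_of = {}
    for k, i in enumerate(receptor_sel):
        a = traj.topology[i]
        key = (a.chain, a.residue_index)
        if key not in index_of:
            index_of[key] = len(residue_keys)
            residue_keys.append(key)
        residue_of_atom[k] = index_of[key]

    frames = _frame_schedule(traj.n_frames, equilibration_fraction,
                             max_frames)
    n_res = len(residue_keys)
    per_frame_ele = np.empty((frames.size, n_res))
    per_frame_vdw = np.empty((frames.size, n_res))
    for fi, f in enumerate(frames):
        coords = traj.xyz[f]
        ele, vdw = _pair_energies(
            coords[receptor_sel], coords[ligand_sel],
            q[receptor_sel], q[ligand_sel], sig[receptor_sel],
            sig[ligand_sel], eps[receptor_sel], eps[ligand_sel],
            dielectric, None)
        ele_atom = ele.sum(axis=1)
        vdw_atom = vdw.sum(axis=1)
        per_frame_ele[fi] = np.bincount(residue_of_atom, weights=ele_atom,
                                        minlength=n_res)
        per_frame_vdw[fi] = np.bincount(residue_of_atom, weights=vdw_atom,
                                        minlength=n_res)

    gb = np.zeros(n_res)
    gbsur = np.zeros(n_res)
    solvation_supplied = solvation_table is not None
    if solvation_supplied:
        required = {"residue_index", "e_gb", "e_gbsur"}
        if not required.issubset(solvation_table.columns):
            raise SchemaError(
                f"solvation table needs columns {sorted(required)}")
        lookup = {int(r.residue_index): (float(r.e_gb), float(r.e_gbsur))
                  for r in solvation_table.itertuples(index=False)}
        for k, (_, resid) in enumerate(residue_keys):
            if resid not in lookup:
                raise TableParseError(
                    f"solvation table lacks residue {resid}")
            gb[k], gbsur[k] = lookup[resid]

    df = pd.DataFrame({
        "chain": [c for c, _ in residue_keys],
        "residue_index": [r for _, r in residue_keys],
        "e_vdw": per_frame_vdw.mean(axis=0),
        "e_vdw_sd": per_frame_vdw.std(axis=0),
        "e_ele": per_frame_ele.mean(axis=0),
        "e_ele_sd": per_frame_ele.std(axis=0),
        "e_gb": gb,
        "e_gbsur": gbsur,
    })
    df["e_tot"] = df["e_vdw"] + df["e_ele"] + df["e_gb"] + df["e_gbsur"]
    df["e_tot_sd"] = np.sqrt(per_frame_vdw.var(axis=0)
                             + per_frame_ele.var(axis=0))
    df["solvation_supplied"] = solvation_supplied
    df = df.sort_values("e_tot", kind="stable").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    df.attrs["frames_used"] = frames
    return df


_COMPONENT_COLUMNS = ["vdw", "ele", "polar_solv", "nonpolar_solv",
                      "entropy_term"]


@dataclass
class ComponentSeries:
    table: pd.DataFrame          # per-frame components (+ derived columns)
    mean: EnergyComponents       # ledger applied to the component means
    sd: dict                     # per-component standard deviation


def load_component_table(text: str,
                         temperature: float = 300.0) -> ComponentSeries:
    """Ingest a per-frame energy-component CSV and apply the ledger.

    Required columns: ``frame`` plus the five components; ΔH and ΔG_bind are
    reconstructed from the components regardless of any provided totals.
    """
    try:
        df = pd.read_csv(io.StringIO(text))
    except Exception as exc:
        raise TableParseError(f"cannot parse component table: {exc}") from exc
    missing = [c for c in ["frame"] + _COMPONENT_COLUMNS
               if c not in df.columns]
    if missing:
        raise SchemaError(f"component table missing columns: {missing}")
    for col in _COMPONENT_COLUMNS:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise TableParseError(
                f"non-numeric value in column {col!r} at row {row + 1}")
        df[col] = converted
    df["enthalpy"] = df[_COMPONENT_COLUMNS[:4]].sum(axis=1)
    df["binding"] = df["enthalpy"] - df["entropy_term"]
    mean = binding_free_energy(
        *(float(df[c].mean()) for c in _COMPONENT_COLUMNS),
        temperature=temperature)
    sd = {c: float(df[c].std(ddof=0)) for c in _COMPONENT_COLUMNS}
    return ComponentSeries(table=df, mean=mean, sd=sd)
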