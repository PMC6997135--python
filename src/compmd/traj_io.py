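"""Structure and trajectory I/O.

Trajectories are multi-model PDB files sharing one topology; per-atom force
field parameters (partial charges, Lennard-Jones parameters, van der Waals
radii) come from a plain TSV table keyed by ``(chain, residue_index,
atom_name)``.  Units are Å for coordinates, elementary charges for partial
charges and kJ·mol⁻¹ for Lennard-Jones well depths.  Atom indices are 0-based
internally; residue indices are kept exactly as printed in the source file.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

import biotite.structure as struc
import biotite.structure.io.pdb as biotite_pdb
import numpy as np
import pandas as pd

from .errors import (
    DuplicateKeyError,
    EmptyStructureError,
    FormatOverflowError,
    MissingParameterError,
    ModelMismatchError,
    SchemaError,
    TableParseError,
)

__all__ = [
    "AtomRecord",
    "Frame",
    "Trajectory",
    "TopologyTable",
    "read_pdb",
    "write_pdb",
    "read_topology_table",
    "select_atoms",
]

_KNOWN_ELEMENTS = {
    "H", "HE", "LI", "BE", "B", "C", "N", "O", "F", "NE", "NA", "MG", "AL",
    "SI", "P", "S", "CL", "AR", "K", "CA", "MN", "FE", "CO", "NI", "CU",
    "ZN", "SE", "BR", "I",
}

# Default vdW radii (Å) used when no topology table is supplied.
ELEMENT_VDW = {
    "C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8, "H": 1.2, "FE": 2.0,
    "P": 1.8, "SE": 1.9, "ZN": 1.39,
}

ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "FE": 55.845, "SE": 78.971, "ZN": 65.38, "NA": 22.990,
    "MG": 24.305, "CL": 35.45, "K": 39.098, "CA": 40.078,
}


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the shared topology, as printed in the source file."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_index: int
    chain: str
    occupancy: float = 1.0
    b_factor: float = 0.0

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"


@dataclass
class Frame:
    """One conformation: per-atom coordinates in Å, optional time in ns."""

    coordinates: np.ndarray
    time: float | None = None

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]


@dataclass
class Trajectory:
    """An ordered sequence of frames sharing one topology.

    ``xyz`` has shape ``(n_frames, n_atoms, 3)``; ``times`` (ns), when
    present, must strictly increase.
    """

    topology: list[AtomRecord]
    xyz: np.ndarray
    times: np.ndarray | None = None

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.ndim == 2:
            self.xyz = self.xyz[None]
        if self.xyz.ndim != 3 or self.xyz.shape[2] != 3:
            raise ValueError("xyz must have shape (n_frames, n_atoms, 3)")
        if self.xyz.shape[0] < 1:
            raise ValueError("trajectory needs at least one frame")
        if self.xyz.shape[1] != len(self.topology):
            raise ValueError(
                f"coordinate count {self.xyz.shape[1]} does not match "
                f"topology atom count {len(self.topology)}"
            )
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("coordinates must be finite")
        if self.times is not None:
            self.times = np.asarray(self.times, dtype=float)
            if self.times.shape != (self.xyz.shape[0],):
                raise ValueError("times must have one entry per frame")
            if np.any(np.diff(self.times) <= 0):
                raise ValueError("frame times must strictly increase")

    @property
    def n_frames(self) -> int:
        return self.xyz.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.xyz.shape[1]

    def __len__(self) -> int:
        return self.n_frames

    def frame(self, i: int) -> Frame:
        t = None if self.times is None else float(self.times[i])
        return Frame(self.xyz[i], time=t)

    @property
    def frames(self) -> list[Frame]:
        return [self.frame(i) for i in range(self.n_frames)]

    def residues(self) -> list[tuple[str, int, str]]:
        """Ordered unique ``(chain, residue_index, residue_name)`` triples."""
        seen: dict[tuple[str, int], str] = {}
        for a in self.topology:
            seen.setdefault((a.chain, a.residue_index), a.residue_name)
        return [(c, r, n) for (c, r), n in seen.items()]

    def select(self, expr: str) -> np.ndarray:
        return select_atoms(self, expr)


def _element_from_name(name: str) -> str:
    """Guess an element symbol from a PDB atom name (fallback heuristic)."""
    stripped = name.strip()
    if not stripped:
        return ""
    two = re.sub(r"[^A-Za-z]", "", stripped[:2]).upper()
    if len(two) == 2 and two in _KNOWN_ELEMENTS and two not in ("CA", "CO"):
        # Two-letter elements (FE, CL, ...) but never mistake CA/CO atom names
        # for calcium/cobalt inside amino-acid residues.
        return two
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    return ""


def _scan_model_atom_counts(text: str) -> list[tuple[int, int]]:
    """Per-MODEL raw ATOM/HETATM line counts, as (model_number, count)."""
    counts: list[tuple[int, int]] = []
    current = None
    n = 0
    for line in text.splitlines():
        rec = line[:6].strip()
        if rec == "MODEL":
            if current is not None:
                counts.append((current, n))
            try:
                current = int(line.split()[1])
            except (IndexError, ValueError):
                current = len(counts) + 1
            n = 0
        elif rec == "ENDMDL":
            counts.append((current if current is not None else 1, n))
            current = None
            n = 0
        elif rec in ("ATOM", "HETATM"):
            n += 1
    if current is not None or (not counts and n):
        counts.append((current if current is not None else 1, n))
    return counts


def read_pdb(text: str) -> Trajectory:
    """Parse PDB content into a :class:`Trajectory`.

    One frame per MODEL block (a single frame if there are none).  Alternate
    locations are resolved to the highest-occupancy conformer, ties going to
    the first one encountered.  TER/END records are tolerated.
    """
    if not any(line[:6].strip() in ("ATOM", "HETATM")
               for line in text.splitlines()):
        raise EmptyStructureError("no ATOM/HETATM records in PDB content")

    counts = _scan_model_atom_counts(text)
    if len(counts) > 1:
        ref_model, ref_n = counts[0]
        for model, n in counts[1:]:
            if n != ref_n:
                raise ModelMismatchError(
                    f"MODEL {model} has {n} ATOM/HETATM records, "
                    f"but MODEL {ref_model} has {ref_n}"
                )

    pdb_file = biotite_pdb.PDBFile.read(io.StringIO(text))
    try:
        structure = pdb_file.get_structure(
            model=None,
            altloc="occupancy",
            extra_fields=["b_factor", "occupancy", "atom_id"],
        )
    except Exception as exc:  # biotite signals inconsistent models
        raise ModelMismatchError(str(exc)) from exc

    topology = []
    for i in range(structure.array_length()):
        element = str(structure.element[i]).upper()
        if element not in _KNOWN_ELEMENTS:
            element = _element_from_name(str(structure.atom_name[i]))
        topology.append(AtomRecord(
            serial=int(structure.atom_id[i]),
            name=str(structure.atom_name[i]),
            element=element,
            residue_name=str(structure.res_name[i]),
            residue_index=int(structure.res_id[i]),
            chain=str(structure.chain_id[i]) or "A",
            occupancy=float(structure.occupancy[i]),
            b_factor=float(structure.b_factor[i]),
        ))
    return Trajectory(topology=topology, xyz=structure.coord.copy())


def write_pdb(traj: Trajectory) -> str:
    """Serialize a trajectory as fixed-column PDB text.

    Multi-frame input emits MODEL/ENDMDL blocks numbered from 1; output is
    bit-stable for identical input.
    """
    if np.any(np.abs(traj.xyz) >= 10000.0):
        raise FormatOverflowError(
            "coordinate magnitude >= 10,000 Å cannot be written in PDB "
            "fixed columns"
        )
    n = traj.n_atoms
    template = struc.AtomArray(n)
    template.coord = traj.xyz[0]
    template.set_annotation("atom_id", np.array(
        [a.serial for a in traj.topology], dtype=int))
    template.set_annotation("atom_name", np.array(
        [a.name for a in traj.topology], dtype="U6"))
    template.set_annotation("element", np.array(
        [a.element for a in traj.topology], dtype="U2"))
    template.set_annotation("res_name", np.array(
        [a.residue_name for a in traj.topology], dtype="U5"))
    template.set_annotation("res_id", np.array(
        [a.residue_index for a in traj.topology], dtype=int))
    template.set_annotation("chain_id", np.array(
        [a.chain for a in traj.topology], dtype="U4"))
    template.set_annotation("occupancy", np.array(
        [a.occupancy for a in traj.topology], dtype=float))
    template.set_annotation("b_factor", np.array(
        [a.b_factor for a in traj.topology], dtype=float))
    template.set_annotation("hetero", np.zeros(n, dtype=bool))

    pdb_file = biotite_pdb.PDBFile()
    if traj.n_frames == 1:
        pdb_file.set_structure(template)
    else:
        stack = struc.stack([template] * traj.n_frames)
        stack.coord = traj.xyz.copy()
        pdb_file.set_structure(stack)
    buf = io.StringIO()
    pdb_file.write(buf)
    text = buf.getvalue()
    if not text.rstrip().endswith("END"):
        text = text.rstrip("\n") + "\nEND\n"
    return text


_TOPOLOGY_COLUMNS = [
    "chain", "residue_index", "atom_name",
    "charge", "lj_sigma", "lj_epsilon", "vdw_radius",
]


@dataclass
class TopologyTable:
    """Per-atom force-field parameters keyed by (chain, residue_index, name).

    ``charge`` in elementary charges, ``lj_sigma``/``vdw_radius`` in Å,
    ``lj_epsilon`` in kJ·mol⁻¹.
    """

    table: pd.DataFrame
    _index: dict[tuple[str, int, str], int] = field(default_factory=dict)

    def __post_init__(self):
        if not self._index:
            self._index = {
                (str(r.chain), int(r.residue_index), str(r.atom_name)): i
                for i, r in enumerate(self.table.itertuples(index=False))
            }

    def __len__(self) -> int:
        return len(self.table)

    def lookup(self, chain: str, residue_index: int, atom_name: str) -> pd.Series:
        key = (chain, residue_index, atom_name)
        if key not in self._index:
            raise MissingParameterError(
                f"no parameters for atom {atom_name} of residue "
                f"{residue_index} chain {chain}"
            )
        return self.table.iloc[self._index[key]]

    def align(self, topology: list[AtomRecord], column: str) -> np.ndarray:
        """Per-atom parameter column aligned to a topology's atom order."""
        values = np.empty(len(topology))
        for i, atom in enumerate(topology):
            values[i] = self.lookup(atom.chain, atom.residue_index,
                                    atom.name)[column]
        return values


def read_topology_table(text: str) -> TopologyTable:
    """Parse the whitespace/tab-delimited per-atom parameter table."""
    try:
        df = pd.read_csv(io.StringIO(text), sep=r"\s+", dtype=str)
    except Exception as exc:
        raise TableParseError(f"cannot parse topology table: {exc}") from exc
    missing = [c for c in _TOPOLOGY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"topology table missing columns: {missing}")
    numeric = ["charge", "lj_sigma", "lj_epsilon", "vdw_radius"]
    for col in numeric:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise TableParseError(
                f"non-numeric value {df[col].iloc[row]!r} in column "
                f"{col!r} at row {row + 1}"
            )
        df[col] = converted
    df["residue_index"] = pd.to_numeric(df["residue_index"], errors="raise",
                                        downcast="integer").astype(int)
    for col, ok, rule in [
        ("lj_sigma", df["lj_sigma"] > 0, "must be > 0"),
        ("lj_epsilon", df["lj_epsilon"] >= 0, "must be >= 0"),
        ("vdw_radius", df["vdw_radius"] > 0, "must be > 0"),
    ]:
        if not ok.all():
            row = int(np.flatnonzero(~ok.to_numpy())[0])
            raise TableParseError(f"{col} {rule} (violated at row {row + 1})")
    keys = list(zip(df["chain"], df["residue_index"], df["atom_name"]))
    if len(set(keys)) != len(keys):
        seen = set()
        for k in keys:
            if k in seen:
                raise DuplicateKeyError(f"duplicate topology key {k}")
            seen.add(k)
    return TopologyTable(table=df.reset_index(drop=True))


# re-exported here because selection is part of the I/O surface
from .selection import select_atoms  # noqa: E402
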