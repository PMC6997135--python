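"""Residue contact maps and contact-based conformational-change statistics.

A contact exists between two residues when their minimum heavy-atom distance
is below a cutoff (4.5 Å by default) and the residues are at least
``neighbor_exclusion`` apart in sequence.  Comparing the contact maps of two
snapshots yields common and snapshot-specific contacts and two derived
statistics: contact similarity (common over all observed contacts — a
conservation measure) and reduction rate (signed change in specific contacts
relative to the initial total — positive for relaxation/expansion, negative
for compaction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import CompmdError
from .traj_io import Trajectory

__all__ = [
    "ContactMap",
    "ContactComparison",
    "contact_map",
    "compare_maps",
    "contact_similarity",
    "reduction_rate",
    "segment_specific_fraction",
    "PROTEIN_RESIDUES",
]

PROTEIN_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "HID", "HIE", "HIP", "CYX", "ASH", "GLH", "LYN",
}


class IncompatibleMapsError(CompmdError):
    """Contact maps built with different parameters cannot be compared."""


class UndefinedStatisticError(CompmdError):
    """Similarity/reduction statistics are undefined for these counts."""


@dataclass
class ContactMap:
    """Set of unordered residue contacts of one snapshot.

    ``residue_ids`` are the ordered ``(chain, residue_index)`` pairs of the
    residue universe; ``contacts`` hold index pairs into that list with
    ``i < j``.  ``min_distances`` records the realizing heavy-atom distance.
    """

    residue_ids: list[tuple[str, int]]
    contacts: frozenset  # of (i, j) position pairs, i < j
    cutoff: float
    neighbor_exclusion: int
    min_distances: dict = field(default_factory=dict)
    skipped_residues: int = 0

    def __len__(self) -> int:
        return len(self.contacts)

    def as_resid_pairs(self) -> frozenset:
        """Contacts as unordered (residue_index, residue_index) pairs."""
        ids = self.residue_ids
        return frozenset(
            tuple(sorted((ids[i][1], ids[j][1]))) for i, j in self.contacts)

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"res_i": self.residue_ids[i][1], "res_j": self.residue_ids[j][1],
             "chain_i": self.residue_ids[i][0],
             "chain_j": self.residue_ids[j][0],
             "min_distance": self.min_distances.get((i, j), np.nan)}
            for i, j in sorted(self.contacts)
        ]
        return pd.DataFrame(
            rows, columns=["res_i", "res_j", "chain_i", "chain_j",
                           "min_distance"])


@dataclass
class ContactComparison:
    common: int
    specific_first: int
    specific_last: int
    similarity: float
    reduction_rate: float

    @property
    def total_first(self) -> int:
        return self.common + self.specific_first

    @property
    def total_last(self) -> int:
        return self.common + self.specific_last


def contact_map(traj: Trajectory, frame: int = 0, cutoff: float = 4.5,
                neighbor_exclusion: int = 2, heavy_only: bool = True,
                include_non_protein: bool = True,
                ca_only: bool = False) -> ContactMap:
    """Residue contact map of one frame.

    A pair (i, j) is a contact iff the minimum heavy-atom distance between
    the residues is strictly below ``cutoff`` and their separation in the
    ordered residue list is at least ``neighbor_exclusion``.  Candidate atom
    pairs are found with a KD-tree, which gives results identical to the
    all-pairs computation.  ``ca_only`` restricts distances to Cα atoms;
    ``include_non_protein=False`` drops heteroresidues (ligands, cofactors).
    """
    coords = traj.xyz[frame]
    atoms = traj.topology

    keep = np.ones(len(atoms), dtype=bool)
    if heavy_only and not ca_only:
        keep &= np.array([a.is_heavy for a in atoms])
    if ca_only:
        keep &= np.array([a.name == "CA" and a.element == "C" for a in atoms])
    if not include_non_protein:
        keep &= np.array([a.residue_name in PROTEIN_RESIDUES for a in atoms])

    residue_ids: list[tuple[str, int]] = []
    position: dict[tuple[str, int], int] = {}
    for a in atoms:
        if include_non_protein or a.residue_name in PROTEIN_RESIDUES:
            key = (a.chain, a.residue_index)
            if key not in position:
                position[key] = len(residue_ids)
                residue_ids.append(key)

    atom_idx = np.flatnonzero(keep)
    skipped = 0
    present = set()
    for i in atom_idx:
        present.add((atoms[i].chain, atoms[i].residue_index))
    skipped = len(residue_ids) - len(present)

    res_pos = np.array([position[(atoms[i].chain, atoms[i].residue_index)]
                        for i in atom_idx])
    pts = coords[atom_idx]
    tree = cKDTree(pts)
    pairs = tree.query_pairs(r=cutoff, output_type="ndarray")

    contacts: dict[tuple[int, int], float] = {}
    if pairs.size:
        d = np.linalg.norm(pts[pairs[:, 0]] - pts[pairs[:, 1]], axis=1)
        strict = d < cutoff  # KD-tree query includes the boundary
        pi = res_pos[pairs[strict, 0]]
        pj = res_pos[pairs[strict, 1]]
        dv = d[strict]
        for a, b, dist in zip(pi, pj, dv):
            if a == b or abs(int(a) - int(b)) < neighbor_exclusion:
                continue
            key = (min(int(a), int(b)), max(int(a), int(b)))
            if key not in contacts or dist < contacts[key]:
                contacts[key] = float(dist)
    return ContactMap(residue_ids=residue_ids,
                      contacts=frozenset(contacts),
                      cutoff=float(cutoff),
                      neighbor_exclusion=int(neighbor_exclusion),
                      min_distances=contacts,
                      skipped_residues=skipped)


def contact_similarity(common: int, specific_first: int,
                       specific_last: int) -> float:
    """Common contacts over all contacts (common + both specific sets)."""
    if min(common, specific_first, specific_last) < 0:
        raise ValueError("contact counts must be non-negative")
    denominator = common + specific_first + specific_last
    if denominator == 0:
        raise UndefinedStatisticError(
            "similarity undefined when no contacts exist")
    return common / denominator


def reduction_rate(specific_first: int, specific_last: int,
                   total_first: int) -> float:
    """(initial-specific − final-specific) / initial total contacts.

    Positive values indicate relaxation/expansion, negative compaction.
    """
    if total_first <= 0:
        raise UndefinedStatisticError(
            "reduction rate undefined without initial contacts")
    return (specific_first - specific_last) / total_first


def compare_maps(first: ContactMap, last: ContactMap) -> ContactComparison:
    """Common/specific contact statistics of two snapshots."""
    if first.cutoff != last.cutoff or \
            first.neighbor_exclusion != last.neighbor_exclusion:
        raise IncompatibleMapsError(
            "contact maps built with different cutoff/exclusion settings")
    if first.residue_ids != last.residue_ids:
        raise IncompatibleMapsError(
            "contact maps do not share a residue universe")
    common = len(first.contacts & last.contacts)
    specific_first = len(first.contacts - last.contacts)
    specific_last = len(last.contacts - first.contacts)
    return ContactComparison(
        common=common,
        specific_first=specific_first,
        specific_last=specific_last,
        similarity=contact_similarity(common, specific_first, specific_last),
        reduction_rate=reduction_rate(specific_first, specific_last,
                                      common + specific_first),
    )


def segment_specific_fraction(first: ContactMap, last: ContactMap,
                              segment_size: int = 50) -> pd.DataFrame:
    """Per-segment share of snapshot-specific contacts.

    The residue index range is divided into consecutive ``segment_size``
    blocks (the final segment absorbs the remainder, mirroring a 1–50 …
    351–403 split of a 403-residue chain).  For each snapshot, a segment's
    value is the number of that snapshot's specific contacts with at least
    one endpoint in the segment, divided by the snapshot's total contact
    count; contacts spanning two segments count once in each.
    """
    if segment_size < 1:
        raise ValueError("segment_size must be >= 1")
    if first.residue_ids != last.residue_ids:
        raise IncompatibleMapsError(
            "contact maps do not share a residue universe")
    resids = [r for _, r in first.residue_ids]
    lo, hi = min(resids), max(resids)
    n_res = hi - lo + 1
    n_segments = max(1, n_res // segment_size)
    bounds = []
    for s in range(n_segments):
        start = lo + s * segment_size
        stop = (start + segment_size - 1) if s < n_segments - 1 else hi
        bounds.append((start, stop))

    specific = {
        "first": first.contacts - last.contacts,
        "last": last.contacts - first.contacts,
    }
    totals = {"first": len(first.contacts), "last": len(last.contacts)}
    ids = first.residue_ids

    rows = []
    for (start, stop) in bounds:
        row = {"segment_start": start, "segment_stop": stop}
        for which in ("first", "last"):
            count = sum(
                1 for i, j in specific[which]
                if start <= ids[i][1] <= stop or start <= ids[j][1] <= stop)
            row[f"fraction_{which}"] = (
                count / totals[which] if totals[which] else 0.0)
        rows.append(row)
    return pd.DataFrame(rows)
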