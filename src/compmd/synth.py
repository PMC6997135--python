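"""Synthetic structures and trajectories with known ground truth.

Every generator is a pure function of its arguments: randomness comes only
from an explicit seed through :func:`numpy.random.default_rng`, never from OS
entropy, so fixtures are bit-reproducible.  The generators emulate the
features of MD ensembles the analysis stages care about — two-basin
conformational mixtures, channel-lining rings with analytically known
constriction radii, prescribed hydrogen-bond occupancy, uniform particle sets
for RDF baselines — without any force-field sampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .traj_io import AtomRecord, Frame, Trajectory

__all__ = [
    "FixtureSpec",
    "make_helix",
    "make_two_state_ensemble",
    "make_pore_cylinder",
    "make_hbond_trajectory",
    "make_uniform_gas",
    "make_contact_pair",
]


@dataclass
class FixtureSpec:
    """Parameters of the two-state conformational ensemble fixture.

    ``populations`` are the stationary fractions of the ground and displaced
    state; ``displacement`` (Å) rigidly shifts the last ``segment_residues``
    residues of a ``n_res``-residue helix along ``axis``; isotropic Gaussian
    noise of width ``noise_sigma`` (Å) is added to every atom coordinate.
    """

    seed: int = 0
    n_frames: int = 1000
    noise_sigma: float = 0.3
    populations: tuple[float, float] = (0.7, 0.3)
    displacement: float = 5.0
    n_res: int = 24
    segment_residues: int = 6
    axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    dt_ns: float = 0.001

    def __post_init__(self):
        if len(self.populations) != 2:
            raise ValueError("two-state fixture needs exactly 2 populations")
        if abs(sum(self.populations) - 1.0) > 1e-9:
            raise ValueError("populations must sum to 1")
        if min(self.populations) < 0:
            raise ValueError("populations must be non-negative")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.displacement <= 0:
            raise ValueError("displacement must be > 0")
        if not 1 <= self.segment_residues < self.n_res:
            raise ValueError("segment_residues must lie inside the helix")


# Cylindrical backbone geometry of an ideal right-handed α-helix:
# (radius Å, phase offset deg, rise offset Å) per backbone atom.
_HELIX_RISE = 1.5
_HELIX_TWIST = 100.0
_BACKBONE = {
    "N": (1.56, -28.0, -0.86, "N"),
    "CA": (2.3, 0.0, 0.0, "C"),
    "C": (2.0, 28.0, 0.72, "C"),
    "O": (2.49, 28.0, 1.85, "O"),
}


def make_helix(n_res: int, chain: str = "A", start_resid: int = 1,
               residue_name: str = "ALA") -> Trajectory:
    """Single-frame ideal α-helix backbone (N, CA, C, O per residue).

    CA atoms trace a 2.3 Å-radius helix with 1.5 Å rise and 100° twist per
    residue, so consecutive CA–CA distances are ≈3.8 Å.  Deterministic.
    """
    if n_res < 2:
        raise ValueError("a helix needs at least 2 residues")
    topology: list[AtomRecord] = []
    coords = []
    serial = 1
    for i in range(n_res):
        phi0 = i * _HELIX_TWIST
        z0 = i * _HELIX_RISE
        for name, (r, dphi, dz, element) in _BACKBONE.items():
            phi = math.radians(phi0 + dphi)
            coords.append((r * math.cos(phi), r * math.sin(phi), z0 + dz))
            topology.append(AtomRecord(
                serial=serial, name=name, element=element,
                residue_name=residue_name, residue_index=start_resid + i,
                chain=chain))
            serial += 1
    return Trajectory(topology=topology, xyz=np.asarray(coords)[None])


@dataclass
class TwoStateEnsemble:
    trajectory: Trajectory
    state_labels: np.ndarray          # 0 = ground, 1 = displaced, per frame
    displaced_atoms: np.ndarray       # indices of the rigidly moved atoms
    spec: FixtureSpec


def make_two_state_ensemble(spec: FixtureSpec) -> TwoStateEnsemble:
    """Two-basin conformational ensemble around an ideal helix.

    Frames are the helix base structure with the terminal segment rigidly
    displaced by 0 or ``spec.displacement`` Å along ``spec.axis`` (state
    drawn i.i.d. per ``spec.populations``), plus isotropic Gaussian noise on
    all atoms.  The per-frame state labels are returned alongside.
    """
    base = make_helix(spec.n_res)
    xyz0 = base.xyz[0]
    first_moved = spec.n_res - spec.segment_residues
    displaced_atoms = np.flatnonzero(np.array(
        [a.residue_index - 1 >= first_moved for a in base.topology]))
    axis = np.asarray(spec.axis, dtype=float)
    axis = axis / np.linalg.norm(axis)

    rng = np.random.default_rng(spec.seed)
    labels = rng.choice(2, size=spec.n_frames, p=list(spec.populations))
    xyz = np.broadcast_to(xyz0, (spec.n_frames,) + xyz0.shape).copy()
    xyz[:, displaced_atoms, :] += (
        labels[:, None, None] * spec.displacement * axis)
    if spec.noise_sigma > 0:
        xyz += rng.normal(0.0, spec.noise_sigma, size=xyz.shape)
    times = np.arange(spec.n_frames) * spec.dt_ns if spec.n_frames > 1 else None
    traj = Trajectory(topology=base.topology, xyz=xyz, times=times)
    return TwoStateEnsemble(trajectory=traj, state_labels=labels,
                            displaced_atoms=displaced_atoms, spec=spec)


@dataclass
class PoreCylinderFixture:
    trajectory: Trajectory
    atom_radii: np.ndarray            # per-atom vdW radii (all == atom_vdw)
    ring_z: np.ndarray                # axial position of each ring plane (Å)
    analytic_radii: np.ndarray        # exact probe radius at each ring plane


def make_pore_cylinder(ring_radii, atoms_per_ring: int = 12,
                       atom_vdw: float = 1.5, spacing: float = 4.0,
                       wall_circles: int = 1,
                       circle_spacing: float = 2.0) -> PoreCylinderFixture:
    """Stacked rings of pseudo-atoms centered on the z-axis.

    At the plane of ring *k*, the on-axis probe radius is known in closed
    form: ``min_j sqrt(r_j² + (z_k − z_j)²) − atom_vdw`` over all rings *j*
    (equal to ``ring_radii[k] − atom_vdw`` whenever neighboring rings do not
    intrude), which serves as the pore-profiling oracle.  ``wall_circles``
    adds concentric circles at ``circle_spacing`` increments in each ring
    plane (angularly staggered) to thicken the channel wall, so that narrow
    constrictions cannot be bypassed radially through open space outside a
    thin ring.
    """
    ring_radii = np.asarray(ring_radii, dtype=float)
    if np.any(ring_radii <= atom_vdw):
        raise ValueError("every ring radius must exceed the atom vdW radius")
    if atoms_per_ring < 3:
        raise ValueError("need at least 3 atoms per ring")
    if wall_circles < 1:
        raise ValueError("need at least one circle per ring")
    topology: list[AtomRecord] = []
    coords = []
    serial = 1
    base_angles = np.linspace(0.0, 2.0 * np.pi, atoms_per_ring,
                              endpoint=False)
    for k, r in enumerate(ring_radii):
        z = k * spacing
        atom_counter = 1
        for c in range(wall_circles):
            radius = r + c * circle_spacing
            angles = base_angles + c * np.pi / atoms_per_ring
            for a in angles:
                coords.append((radius * np.cos(a), radius * np.sin(a), z))
                topology.append(AtomRecord(
                    serial=serial, name=f"P{atom_counter}", element="C",
                    residue_name="RNG", residue_index=k + 1, chain="A"))
                serial += 1
                atom_counter += 1
    ring_z = np.arange(len(ring_radii)) * spacing
    # closed-form on-axis probe radius per plane: nearest inner circle of
    # any ring (outer wall circles are strictly farther from the axis)
    dz = ring_z[:, None] - ring_z[None, :]
    analytic = np.min(np.sqrt(ring_radii[None, :]**2 + dz**2),
                      axis=1) - atom_vdw
    traj = Trajectory(topology=topology, xyz=np.asarray(coords)[None])
    return PoreCylinderFixture(
        trajectory=traj,
        atom_radii=np.full(len(topology), float(atom_vdw)),
        ring_z=ring_z,
        analytic_radii=analytic,
    )


@dataclass
class HBondFixture:
    trajectory: Trajectory
    state_labels: np.ndarray          # 1 = bonded geometry, 0 = broken
    donor: int = 0                    # topology indices of the triple
    hydrogen: int = 1
    acceptor: int = 2


# bonded geometry: H···A 2.9 Å at a 165° donor–H–acceptor angle;
# broken geometry: 4.5 Å at 120° — fails both criterion thresholds.
_HB_ON = (2.9, 165.0)
_HB_OFF = (4.5, 120.0)


def make_hbond_trajectory(p_on: float, n_frames: int,
                          seed: int = 0) -> HBondFixture:
    """Donor–H–acceptor triple toggling between bonded and broken geometry.

    Each frame is independently "on" with probability ``p_on`` (Bernoulli,
    seeded), so the recovered occupancy has a known binomial distribution.
    """
    if not 0.0 <= p_on <= 1.0:
        raise ValueError("p_on must be a fraction in [0, 1]")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    labels = (rng.random(n_frames) < p_on).astype(int)

    topology = [
        AtomRecord(serial=1, name="N", element="N", residue_name="DON",
                   residue_index=1, chain="A"),
        AtomRecord(serial=2, name="H1", element="H", residue_name="DON",
                   residue_index=1, chain="A"),
        AtomRecord(serial=3, name="O", element="O", residue_name="ACC",
                   residue_index=2, chain="A"),
    ]
    donor = np.array([0.0, 0.0, 0.0])
    hydrogen = np.array([1.01, 0.0, 0.0])

    def acceptor_at(d, angle_deg):
        # angle at H between H->donor (-x) and H->acceptor
        theta = math.radians(180.0 - angle_deg)
        return hydrogen + d * np.array([math.cos(theta), math.sin(theta), 0.0])

    frames = {0: np.stack([donor, hydrogen, acceptor_at(*_HB_OFF)]),
              1: np.stack([donor, hydrogen, acceptor_at(*_HB_ON)])}
    xyz = np.stack([frames[s] for s in labels])
    return HBondFixture(
        trajectory=Trajectory(topology=topology, xyz=xyz),
        state_labels=labels,
    )


def make_uniform_gas(n: int, box: float, seed: int = 0) -> Frame:
    """``n`` points uniform in a cubic box of side ``box`` Å (ideal gas)."""
    if n < 2:
        raise ValueError("need at least 2 particles")
    if box <= 0:
        raise ValueError("box must be > 0")
    rng = np.random.default_rng(seed)
    return Frame(rng.uniform(0.0, box, size=(n, 3)))


@dataclass
class ContactPairFixture:
    """Two fixed 6-residue toy conformations with enumerated contact sets.

    Each residue carries two heavy atoms (CA, and CB displaced by +1 Å in z,
    so residue–residue minimum distances equal the in-plane CA–CA
    distances).  With a 4.5 Å cutoff and sequence-neighbor exclusion of 2
    (|i−j| ≥ 2), the ground-truth contact sets, enumerated by exhaustive
    pairwise distances, are::

        frame A: (1,4) (2,6) (3,5) (4,6)
        frame B: (1,3) (1,4) (3,5)

    giving 2 common contacts, 2 specific to A and 1 specific to B.
    """

    frame_a: Trajectory
    frame_b: Trajectory
    contacts_a: frozenset = frozenset()
    contacts_b: frozenset = frozenset()
    cutoff: float = 4.5
    neighbor_exclusion: int = 2


_CONTACT_CA = {
    "A": [(0.0, 0.0), (3.8, 0.0), (7.6, 0.0), (0.0, 4.0), (7.6, 4.0),
          (3.8, 4.2)],
    "B": [(0.0, 0.0), (3.8, 0.0), (4.2, 0.5), (0.0, 4.0), (6.0, 4.0),
          (3.8, 7.0)],
}
_CONTACTS_A = frozenset({(1, 4), (2, 6), (3, 5), (4, 6)})
_CONTACTS_B = frozenset({(1, 3), (1, 4), (3, 5)})


def _contact_structure(key: str) -> Trajectory:
    topology: list[AtomRecord] = []
    coords = []
    serial = 1
    for i, (x, y) in enumerate(_CONTACT_CA[key]):
        for name, dz in (("CA", 0.0), ("CB", 1.0)):
            coords.append((x, y, dz))
            topology.append(AtomRecord(
                serial=serial, name=name, element="C", residue_name="ALA",
                residue_index=i + 1, chain="A"))
            serial += 1
    return Trajectory(topology=topology, xyz=np.asarray(coords)[None])


def make_contact_pair() -> ContactPairFixture:
    """Two toy conformations whose 4.5 Å contact sets are known exactly."""
    return ContactPairFixture(
        frame_a=_contact_structure("A"),
        frame_b=_contact_structure("B"),
        contacts_a=_CONTACTS_A,
        contacts_b=_CONTACTS_B,
    )
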