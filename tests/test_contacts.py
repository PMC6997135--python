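import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from compmd.contacts import (
    IncompatibleMapsError,
    UndefinedStatisticError,
    compare_maps,
    contact_map,
    contact_similarity,
    reduction_rate,
    segment_specific_fraction,
)
from compmd.synth import make_contact_pair, make_helix
from compmd.traj_io import AtomRecord, Trajectory


def all_pairs_contact_oracle(traj, cutoff=4.5, neighbor_exclusion=2):
    """Exhaustive heavy-atom minimum-distance contact enumeration."""
    coords = traj.xyz[0]
    atoms = traj.topology
    residues = []
    pos = {}
    for a in atoms:
        key = (a.chain, a.residue_index)
        if key not in pos:
            pos[key] = len(residues)
            residues.append(key)
    contacts = set()
    for i in range(len(atoms)):
        if not atoms[i].is_heavy:
            continue
        for j in range(i + 1, len(atoms)):
            if not atoms[j].is_heavy:
                continue
            pi = pos[(atoms[i].chain, atoms[i].residue_index)]
            pj = pos[(atoms[j].chain, atoms[j].residue_index)]
            if pi == pj or abs(pi - pj) < neighbor_exclusion:
                continue
            if np.linalg.norm(coords[i] - coords[j]) < cutoff:
                contacts.add((min(pi, pj), max(pi, pj)))
    return contacts


def random_structure(rng, n_res=20, atoms_per_res=3, spread=12.0):
    topology = []
    coords = []
    serial = 1
    for r in range(n_res):
        center = rng.uniform(0, spread, 3)
        for k in range(atoms_per_res):
            coords.append(center + rng.normal(0, 1.0, 3))
            topology.append(AtomRecord(
                serial=serial, name=f"C{k}", element="C",
                residue_name="ALA", residue_index=r + 1, chain="A"))
            serial += 1
    return Trajectory(topology=topology, xyz=np.asarray(coords)[None])


class TestContactMap:
    def test_fixture_ground_truth(self):
        fx = make_contact_pair()
        cm = contact_map(fx.frame_a, 0)
        assert cm.as_resid_pairs() == fx.contacts_a
        cm_b = contact_map(fx.frame_b, 0)
        assert cm_b.as_resid_pairs() == fx.contacts_b

    def test_matches_all_pairs_oracle_on_random_structures(self, rng):
        for _ in range(100):
            traj = random_structure(rng)
            cm = contact_map(traj, 0)
            assert set(cm.contacts) == all_pairs_contact_oracle(traj)

    def test_far_residues_never_contact(self):
        helix = make_helix(2)
        xyz = helix.xyz.copy()
        xyz[0, 4:, :] += 50.0  # second residue far away
        traj = Trajectory(topology=helix.topology, xyz=xyz)
        assert len(contact_map(traj, 0).contacts) == 0

    def test_sequence_neighbors_excluded_regardless_of_distance(self):
        helix = make_helix(3)
        cm = contact_map(helix, 0, cutoff=20.0, neighbor_exclusion=2)
        for i, j in cm.contacts:
            assert abs(i - j) >= 2

    def test_cutoff_monotonicity(self, rng):
        traj = random_structure(rng)
        small = contact_map(traj, 0, cutoff=3.5)
        large = contact_map(traj, 0, cutoff=6.0)
        assert small.contacts <= large.contacts


class TestDerivedStatistics:
    def test_apo_printed_counts(self):
        assert contact_similarity(430, 135, 126) == pytest.approx(0.6223,
                                                                  abs=5e-5)
        assert reduction_rate(135, 126, 565) == pytest.approx(0.0159,
                                                              abs=5e-5)

    def test_complex_printed_counts(self):
        assert contact_similarity(460, 125, 151) == pytest.approx(0.6250,
                                                                  abs=5e-5)
        assert reduction_rate(125, 151, 585) == pytest.approx(-0.0444,
                                                              abs=5e-5)

    def test_degenerate_statistics(self):
        assert contact_similarity(0, 5, 5) == 0.0
        assert reduction_rate(7, 7, 100) == 0.0
        with pytest.raises(UndefinedStatisticError):
            contact_similarity(0, 0, 0)
        with pytest.raises(UndefinedStatisticError):
            reduction_rate(1, 2, 0)

    @given(common=st.integers(0, 500), sf=st.integers(0, 500),
           sl=st.integers(0, 500))
    def test_similarity_bounded_and_totals_consistent(self, common, sf, sl):
        if common + sf + sl == 0:
            return
        s = contact_similarity(common, sf, sl)
        assert 0.0 <= s <= 1.0


class TestCompareMaps:
    def test_identical_maps(self):
        fx = make_contact_pair()
        cm = contact_map(fx.frame_a, 0)
        result = compare_maps(cm, cm)
        assert result.specific_first == result.specific_last == 0
        assert result.similarity == 1.0
        assert result.total_first == len(cm.contacts)

    def test_fixture_pair_counts_match_set_algebra(self):
        fx = make_contact_pair()
        first = contact_map(fx.frame_a, 0)
        last = contact_map(fx.frame_b, 0)
        result = compare_maps(first, last)
        assert result.common == len(fx.contacts_a & fx.contacts_b)
        assert result.specific_first == len(fx.contacts_a - fx.contacts_b)
        assert result.specific_last == len(fx.contacts_b - fx.contacts_a)
        assert result.total_first == len(fx.contacts_a)
        assert result.total_last == len(fx.contacts_b)

    def test_random_maps_match_set_oracle(self, rng):
        traj_a = random_structure(rng, n_res=30)
        traj_b = random_structure(rng, n_res=30)
        traj_b = Trajectory(topology=traj_a.topology, xyz=traj_b.xyz)
        first = contact_map(traj_a, 0)
        last = contact_map(traj_b, 0)
        result = compare_maps(first, last)
        a, b = set(first.contacts), set(last.contacts)
        assert result.common == len(a & b)
        assert result.specific_first == len(a - b)
        assert result.specific_last == len(b - a)

    def test_different_cutoffs_rejected(self):
        fx = make_contact_pair()
        with pytest.raises(IncompatibleMapsError):
            compare_maps(contact_map(fx.frame_a, 0, cutoff=4.5),
                         contact_map(fx.frame_b, 0, cutoff=5.0))


class TestSegmentFractions:
    def test_identical_maps_give_zero_everywhere(self):
        fx = make_contact_pair()
        cm = contact_map(fx.frame_a, 0)
        table = segment_specific_fraction(cm, cm, segment_size=3)
        assert (table["fraction_first"] == 0).all()
        assert (table["fraction_last"] == 0).all()

    def test_fixture_fractions_match_counting_oracle(self):
        fx = make_contact_pair()
        first = contact_map(fx.frame_a, 0)
        last = contact_map(fx.frame_b, 0)
        table = segment_specific_fraction(first, last, segment_size=3)
        # residues 1..6 -> two segments: 1-3 and 4-6
        spec_first = fx.contacts_a - fx.contacts_b   # {(2,6),(4,6)}
        spec_last = fx.contacts_b - fx.contacts_a    # {(1,3)}
        for seg_idx, (lo, hi) in enumerate([(1, 3), (4, 6)]):
            exp_first = sum(1 for i, j in spec_first
                            if lo <= i <= hi or lo <= j <= hi) / len(
                                fx.contacts_a)
            exp_last = sum(1 for i, j in spec_last
                           if lo <= i <= hi or lo <= j <= hi) / len(
                               fx.contacts_b)
            assert table["fraction_first"][seg_idx] == pytest.approx(
                exp_first)
            assert table["fraction_last"][seg_idx] == pytest.approx(exp_last)

    def test_final_segment_absorbs_remainder(self):
        helix = make_helix(11)
        cm = contact_map(helix, 0)
        table = segment_specific_fraction(cm, cm, segment_size=5)
        assert list(table["segment_start"]) == [1, 6]
        assert list(table["segment_stop"]) == [5, 11]
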