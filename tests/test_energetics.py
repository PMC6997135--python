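import numpy as np
import pandas as pd
import pytest

from compmd.energetics import (
    COULOMB_CONSTANT,
    binding_free_energy,
    coulomb_lj_interaction,
    load_component_table,
    nonpolar_solvation,
    per_residue_decomposition,
    residue_total,
    shrake_rupley_sasa,
)
from compmd.errors import ClashError, SchemaError, TableParseError
from compmd.traj_io import AtomRecord, Trajectory, read_topology_table


def make_pair_system(rng=None, n_receptor=6, n_ligand=4, n_frames=1):
    """Random two-molecule system with a matching topology table."""
    rng = rng or np.random.default_rng(0)
    topology = []
    rows = ["chain residue_index atom_name charge lj_sigma lj_epsilon "
            "vdw_radius"]
    serial = 1
    for count, chain, resid_base in [(n_receptor, "A", 1), (n_ligand, "B", 90)]:
        for k in range(count):
            resid = resid_base + k // 3
            name = f"C{serial}"
            topology.append(AtomRecord(
                serial=serial, name=name, element="C", residue_name="ALA",
                residue_index=resid, chain=chain))
            rows.append(
                f"{chain} {resid} {name} {rng.uniform(-0.8, 0.8):.4f} "
                f"{rng.uniform(3.0, 3.8):.4f} {rng.uniform(0.2, 0.8):.4f} "
                f"1.7")
            serial += 1
    n = n_receptor + n_ligand
    xyz = np.empty((n_frames, n, 3))
    for f in range(n_frames):
        xyz[f, :n_receptor] = rng.uniform(0, 6, size=(n_receptor, 3))
        xyz[f, n_receptor:] = rng.uniform(8, 13, size=(n_ligand, 3))
    traj = Trajectory(topology=topology, xyz=xyz)
    table = read_topology_table("\n".join(rows) + "\n")
    return traj, table, np.arange(n_receptor), np.arange(n_receptor, n)


class TestCoulombLj:
    def test_zero_charges_zero_electrostatics(self):
        traj, table, rec, lig = make_pair_system()
        table.table["charge"] = 0.0
        ele, vdw = coulomb_lj_interaction(traj, rec, lig, table)
        assert ele == 0.0
        assert vdw != 0.0

    def test_unit_charge_pair_closed_form(self):
        topology = [
            AtomRecord(serial=1, name="C1", element="C", residue_name="ALA",
                       residue_index=1, chain="A"),
            AtomRecord(serial=2, name="C2", element="C", residue_name="ALA",
                       residue_index=2, chain="B"),
        ]
        traj = Trajectory(topology=topology,
                          xyz=np.array([[[0.0, 0, 0], [3.0, 0, 0]]]))
        table = read_topology_table(
            "chain residue_index atom_name charge lj_sigma lj_epsilon "
            "vdw_radius\n"
            "A 1 C1 1.0 3.0 0.0 1.7\n"
            "B 2 C2 -1.0 3.0 0.0 1.7\n")
        ele, vdw = coulomb_lj_interaction(traj, [0], [1], table)
        assert ele == pytest.approx(-COULOMB_CONSTANT / 3.0, rel=1e-12)
        assert ele == pytest.approx(-463.118, abs=5e-4)
        assert vdw == 0.0

    def test_matches_double_loop_oracle(self, rng):
        traj, table, rec, lig = make_pair_system(rng, 10, 10)
        ele, vdw = coulomb_lj_interaction(traj, rec, lig, table)
        q = table.align(traj.topology, "charge")
        sig = table.align(traj.topology, "lj_sigma")
        eps = table.align(traj.topology, "lj_epsilon")
        coords = traj.xyz[0]
        ele_o = vdw_o = 0.0
        for i in rec:
            for j in lig:
                r = np.linalg.norm(coords[i] - coords[j])
                ele_o += COULOMB_CONSTANT * q[i] * q[j] / r
                s = 0.5 * (sig[i] + sig[j])
                e = np.sqrt(eps[i] * eps[j])
                vdw_o += 4 * e * ((s / r) ** 12 - (s / r) ** 6)
        assert ele == pytest.approx(ele_o, abs=1e-9)
        assert vdw == pytest.approx(vdw_o, abs=1e-9)

    def test_clash_rejected(self):
        traj, table, rec, lig = make_pair_system()
        traj.xyz[0, lig[0]] = traj.xyz[0, rec[0]] + 0.01
        with pytest.raises(ClashError):
            coulomb_lj_interaction(traj, rec, lig, table)


class TestSasa:
    def test_isolated_atom_matches_sphere_area(self):
        coords = np.array([[0.0, 0.0, 0.0]])
        for r in (1.2, 1.7, 2.0):
            sasa = shrake_rupley_sasa(coords, np.array([r]))
            exact = 4 * np.pi * (r + 1.4) ** 2
            assert sasa[0] == pytest.approx(exact, rel=0.005)

    def test_distant_atoms_are_additive(self):
        coords = np.array([[0.0, 0, 0], [100.0, 0, 0]])
        radii = np.array([1.7, 1.5])
        sasa = shrake_rupley_sasa(coords, radii)
        for k in range(2):
            alone = shrake_rupley_sasa(coords[k:k + 1], radii[k:k + 1])
            assert sasa[k] == pytest.approx(alone[0], rel=1e-9)

    def test_buried_atom_has_zero_area(self):
        coords = np.array([[0.0, 0, 0], [0.1, 0, 0]])
        radii = np.array([1.0, 5.0])
        sasa = shrake_rupley_sasa(coords, radii)
        assert sasa[0] == 0.0

    def test_point_count_convergence(self, rng):
        coords = rng.uniform(0, 6, size=(12, 3))
        radii = np.full(12, 1.7)
        coarse = shrake_rupley_sasa(coords, radii, n_points=960).sum()
        fine = shrake_rupley_sasa(coords, radii, n_points=4000).sum()
        assert abs(coarse - fine) / fine < 0.01

    def test_resolution_floor(self):
        with pytest.raises(ValueError):
            shrake_rupley_sasa(np.zeros((1, 3)), np.array([1.0]), n_points=10)


class TestLedger:
    def test_printed_worked_values(self):
        # polar + nonpolar driving forces reproduce the enthalpy, and the
        # enthalpy/entropy split reproduces the binding free energy
        components = binding_free_energy(
            vdw=-56.4, ele=15.93, polar_solv=0.0, nonpolar_solv=0.0,
            entropy_term=-19.46)
        assert components.enthalpy == pytest.approx(-40.47, abs=1e-9)
        assert components.binding == pytest.approx(-21.01, abs=1e-9)
        assert components.polar_total == pytest.approx(15.93)
        assert components.nonpolar_total == pytest.approx(-56.4)

    def test_zero_ledger(self):
        components = binding_free_energy(0, 0, 0, 0, 0)
        assert components.enthalpy == 0.0
        assert components.binding == 0.0

    def test_invariants_enforced_at_construction(self):
        from compmd.energetics import EnergyComponents
        with pytest.raises(ValueError):
            EnergyComponents(vdw=1, ele=1, polar_solv=1, nonpolar_solv=1,
                             entropy_term=0, enthalpy=5, binding=5)

    def test_nonpolar_solvation_linear_model(self):
        assert nonpolar_solvation(0.0) == pytest.approx(3.849)
        assert nonpolar_solvation(1000.0) == pytest.approx(26.549, abs=1e-9)


class TestResidueDecomposition:
    def test_residue_totals_from_printed_component_means(self):
        assert residue_total(-1.63, -11.59, 8.03, -0.16) == pytest.approx(
            -5.35, abs=0.005)
        assert residue_total(-2.4, -1.31, 1.46, -0.12) == pytest.approx(
            -2.37, abs=0.005)

    def test_sum_rule_partitions_whole_interaction(self, rng):
        traj, table, rec, lig = make_pair_system(rng, 9, 5, n_frames=5)
        df = per_residue_decomposition(traj, rec, lig, table,
                                       equilibration_fraction=0.0)
        frames = df.attrs["frames_used"]
        ele_sum = df["e_ele"].sum()
        vdw_sum = df["e_vdw"].sum()
        totals = [coulomb_lj_interaction(traj, rec, lig, table, frame=f)
                  for f in frames]
        assert ele_sum == pytest.approx(
            np.mean([t[0] for t in totals]), abs=1e-6)
        assert vdw_sum == pytest.approx(
            np.mean([t[1] for t in totals]), abs=1e-6)

    def test_neutral_ligand_gives_zero_totals(self, rng):
        traj, table, rec, lig = make_pair_system(rng)
        lig_names = {traj.topology[i].name for i in lig}
        mask = table.table["atom_name"].isin(lig_names)
        table.table.loc[mask, ["charge", "lj_epsilon"]] = 0.0
        df = per_residue_decomposition(traj, rec, lig, table,
                                       equilibration_fraction=0.0)
        np.testing.assert_allclose(df["e_tot"], 0.0, atol=1e-12)

    def test_ranking_ascending_and_solvation_join(self, rng):
        traj, table, rec, lig = make_pair_system(rng, 9, 5)
        resids = sorted({traj.topology[i].residue_index for i in rec})
        solv = pd.DataFrame({"residue_index": resids,
                             "e_gb": [0.5] * len(resids),
                             "e_gbsur": [-0.1] * len(resids)})
        df = per_residue_decomposition(traj, rec, lig, table,
                                       solvation_table=solv,
                                       equilibration_fraction=0.0)
        assert list(df["e_tot"]) == sorted(df["e_tot"])
        assert (df["e_gb"] == 0.5).all()
        np.testing.assert_allclose(
            df["e_tot"],
            df["e_vdw"] + df["e_ele"] + df["e_gb"] + df["e_gbsur"])


COMPONENT_CSV = """\
frame,vdw,ele,polar_solv,nonpolar_solv,entropy_term
0,-60.0,10.0,8.0,-2.0,-20.0
1,-56.0,14.0,6.0,-2.0,-19.0
2,-58.0,12.0,7.0,-2.0,-19.5
"""


class TestComponentTable:
    def test_mean_ledger_matches_arithmetic_oracle(self):
        series = load_component_table(COMPONENT_CSV)
        assert series.mean.vdw == pytest.approx(-58.0)
        assert series.mean.enthalpy == pytest.approx(-58 + 12 + 7 - 2)
        assert series.mean.binding == pytest.approx(
            series.mean.enthalpy + 19.5)
        assert series.sd["vdw"] == pytest.approx(np.std([-60, -56, -58]))

    def test_constant_rows_have_zero_sd(self):
        text = ("frame,vdw,ele,polar_solv,nonpolar_solv,entropy_term\n"
                + "\n".join(f"{i},-1.0,2.0,0.5,-0.25,3.0" for i in range(4)))
        series = load_component_table(text)
        assert all(v == 0.0 for v in series.sd.values())
        assert series.mean.enthalpy == pytest.approx(1.25)

    def test_enthalpy_reconstructed_from_components(self):
        series = load_component_table(COMPONENT_CSV)
        np.testing.assert_allclose(
            series.table["enthalpy"],
            series.table[["vdw", "ele", "polar_solv",
                          "nonpolar_solv"]].sum(axis=1))

    def test_missing_column_and_bad_cell(self):
        with pytest.raises(SchemaError):
            load_component_table("frame,vdw\n0,1.0\n")
        with pytest.raises(TableParseError, match="row 2"):
            load_component_table(COMPONENT_CSV.replace("14.0", "oops"))
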