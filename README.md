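# compmd

Comparative analysis of molecular-dynamics trajectories: what changes in a
protein's conformational ensemble when a ligand binds?  `compmd` is aimed at
computational structural biologists who have two ensembles of the same
protein — typically apo vs. inhibitor-bound — and want the standard
comparative readouts as a tested, scriptable Python library with a thin CLI:

- **Descriptors** — superposed RMSD (Kabsch), RMSF about the iterated mean
  structure, B = (8π²/3)·RMSF², radius of gyration.
- **Conformational clustering** — frames linked when pairwise RMSD ≤ a
  threshold (2.4 Å coarse / 1.5 Å fine presets); clusters are connected
  components of the link graph; cumulative cluster count over time measures
  sampling convergence.
- **Contact statistics** — residue contacts at a 4.5 Å minimum heavy-atom
  distance; for two snapshots, contact similarity
  `common / (common + specific₁ + specific₂)` and reduction rate
  `(specific₁ − specific₂) / total₁`, plus per-50-residue-segment fractions.
- **Free-energy landscapes** — PCA of superposed Cα coordinates,
  ΔG(X) = −k_B T ln P(X) over (PC1, PC2), basin extraction with occupancies
  and time intervals, non-Gaussianity reporting.
- **Hydrogen bonds** — geometric criterion (H···A < 3.5 Å, donor–H–acceptor
  angle > 135°), occupancy statistics, side-chain fold/stretch
  classification, radial distribution functions.
- **Pore profiles** — maximal probe radius along a channel axis with
  blocked / single-file / bulk water classification (1.15 / 2.30 Å).
- **Binding free-energy bookkeeping** — ΔG_bind = ΔH − TΔS with
  ΔH = ΔE_VDW + ΔE_ELE + ΔG_polar + ΔG_nonpolar; vacuum Coulomb/LJ cross
  terms and Shrake–Rupley SASA computed here, PB/GB and entropy terms
  accepted as inputs; per-residue decomposition with key-residue ranking.

Trajectories are multi-model PDB files; per-atom parameters come from a
plain TSV table.  A seeded synthetic-data module (`compmd.synth`) generates
two-basin ensembles, pore cylinders with closed-form radius profiles,
hydrogen-bond trajectories with prescribed occupancy, and uniform-gas RDF
baselines, so the whole pipeline is testable without downloading anything.

## Worked example

Recover the two-state thermodynamics of a synthetic ensemble, and evaluate
the two kinds of printed worked values the package reproduces exactly:

```python
from compmd.synth import FixtureSpec, make_two_state_ensemble
from compmd import fel
from compmd.contacts import contact_similarity, reduction_rate
from compmd.energetics import binding_free_energy

sim = make_two_state_ensemble(FixtureSpec(seed=7, n_frames=20000,
                                          populations=(0.7, 0.3)))
traj = sim.trajectory
model = fel.pca(traj, traj.select("calpha"))
grid = fel.fel_grid(model.projections[:, :2], temperature=300.0)
basins = fel.find_basins(grid, depth_cut=10.0)
print(f"PC1 explains {model.eigenvalues[0] / model.eigenvalues.sum():.1%} "
      f"of the coordinate variance")
for i, b in enumerate(basins, 1):
    print(f"basin {i}: occupancy {b.occupancy:.3f}, "
          f"G = {b.free_energy:.2f} kJ/mol")

print(f"contact similarity {100 * contact_similarity(430, 135, 126):.2f}%, "
      f"reduction rate {100 * reduction_rate(135, 126, 565):.2f}%")

ledger = binding_free_energy(vdw=-56.4, ele=15.93, polar_solv=0.0,
                             nonpolar_solv=0.0, entropy_term=-19.46)
print(f"dH = {ledger.enthalpy:.2f}, TdS = {ledger.entropy_term:.2f}, "
      f"dG_bind = {ledger.binding:.2f} kJ/mol")
```

prints

```
PC1 explains 64.9% of the coordinate variance
basin 1: occupancy 0.684, G = 0.95 kJ/mol
basin 2: occupancy 0.292, G = 3.07 kJ/mol
contact similarity 62.23%, reduction rate 1.59%
dH = -40.47, TdS = -19.46, dG_bind = -21.01 kJ/mol
```

The basin occupancies recover the generating 0.7/0.3 populations, and their
free-energy gap (3.07 − 0.95 = 2.12 kJ·mol⁻¹) matches the Boltzmann value
−k_B·T·ln(0.3/0.7) = 2.11 kJ·mol⁻¹ at 300 K.  The contact statistics are the
conservation (similarity) and compaction/relaxation (reduction rate) of a
residue-contact network between two snapshots; the ledger line assembles a
binding free energy from its enthalpic components and the entropy term.

The same stages run from the shell — `compmd simulate` emits seeded
synthetic trajectories, and `compmd compare --config config.yaml` runs the
full two-system pipeline into CSV tables plus a machine-readable
`report.json` (schema shipped with the package):

```sh
compmd simulate --kind two-state --seed 7 --n-frames 2000 --out traj.pdb
compmd rmsd --traj traj.pdb --out rmsd.csv
compmd fel --traj traj.pdb --out pca.csv
```

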