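# Methods

`compmd` implements the analysis layer of a comparative molecular-dynamics
study: given two conformational ensembles of the same protein (typically an
apo system and an inhibitor complex), it quantifies how binding changes the
conformational distribution, the residue-contact network, hydrogen bonding,
channel geometry, and the binding thermodynamics ledger.  This note records
the models, the parameters that matter, and the numerical choices, in the
package's own terms.

## Trajectory model and units

A trajectory is an ordered set of frames sharing one topology.  The on-disk
format is multi-model PDB (one frame per MODEL block); binary MD formats are
deliberately out of scope so that every fixture is plain text and
bit-reproducible.  Units throughout: Å for lengths, kJ·mol⁻¹ for energies,
ns for time, elementary charges for partial charges, degrees for angles.
Atom indices are 0-based internally; residue indices stay as printed in the
source file.  Alternate locations resolve to the highest-occupancy
conformer (ties → first).  Per-atom force-field parameters (charge, LJ σ/ε,
vdW radius) come from a TSV table keyed by `(chain, residue_index,
atom_name)`.

## Superposition and descriptors

RMSD is always computed after optimal rigid-body superposition (Kabsch, SVD
with the reflection branch corrected to det +1): RMSD = √(Σδᵢ²/N) over the
fitted selection.  RMSF is measured about the ensemble mean structure with
the superposition iterated twice so the reference is self-consistent; an
optional `fit_sel` restricts the fit to a rigid core, which matters whenever
a mobile segment would otherwise drag the reference frame (on elongated
structures a rigidly jumping tail can inflate the apparent fluctuation of
genuinely static atoms more than its own).  B-factors follow
B = (8π²/3)·RMSF².  The radius of gyration defaults to unit masses
(geometric Rg); element masses from a built-in table are optional, since the
weighting convention is rarely stated in application papers and the
difference is below the reporting precision for proteins.

## Conformational clustering

Two frames are linked when their pairwise superposed RMSD is ≤ a threshold.
The pairwise indicator is not transitive, so it does not define a partition
by itself; clusters are defined as connected components of the indicator
graph — single-linkage at the threshold, the minimal completion of the
pairwise rule.  (The source description of the rule contains an obvious typo
— both indicator values "indicate the same cluster" — which we resolve in
favor of the inequality itself.)  Presets: 2.4 Å for a coarse partition,
1.5 Å for fine time-dependent cluster counting.  The representative of a
cluster is its lowest-energy member when per-frame energies are supplied,
else the medoid.  The time-dependent curve counts clusters on growing
trajectory prefixes; a plateau indicates converged sampling.

## Contact statistics

A residue contact exists when the minimum heavy-atom distance between two
residues is < 4.5 Å.  Sequence neighbors (|i−j| < 2 positions) are excluded
by default: they are trivially always in contact and would swamp the
statistics; the exclusion is a visible parameter, not a hidden constant.
Candidate atom pairs come from a KD-tree, provably identical to the
all-pairs enumeration (tested on 100 random structures).  Comparing the
first and last snapshot yields common and snapshot-specific contacts and two
statistics:

- contact similarity = common / (common + specific_first + specific_last),
  a conservation measure in [0, 1];
- reduction rate = (specific_first − specific_last) / total_first, positive
  for relaxation/expansion, negative for compaction.

Per-segment fractions divide the residue range into 50-residue blocks (the
final block absorbs the remainder, e.g. 351–403 for a 403-residue chain);
a contact spanning two segments counts once in each, matching the
"at least one endpoint" reading.

## Hydrogen bonds, side-chain states, RDF

A donor–H···acceptor triple is bonded in a frame iff the H···A distance is
< 3.5 Å and the donor–H–acceptor angle (vertex at the hydrogen) is > 135°;
both thresholds are configurable and both inequalities strict.  Donors are
N/O/S heavy atoms with a hydrogen within 1.2 Å (a covalent-proximity rule —
the fixtures carry no CONECT records); acceptors are N/O.  Occupancy
("frequency") is the fraction of bonded frames; mean distance/angle are
taken over bonded frames only.  The two-state fold/stretch classifier for
side-chain geometry takes mandatory angle/distance split values: they are
residue-specific and must be read off the observed distributions, so no
silent default exists.

g(r) normalizes the pair-distance histogram by shell volume 4πr²dr and mean
pair density |A||B|/V (|A|(|A|−1)/V for identical groups).  With an
orthorhombic `box`, distances use the minimum-image convention and V = box³;
without one, a normalization volume must be supplied and no periodicity is
assumed.  The periodic path exists because a finite non-periodic uniform gas
is *not* flat: its pair-distance density falls short of 4πr²/V by ≈(3/2)(r/L)
already, which would be mistaken for structure.

## PCA and free-energy landscapes

PCA diagonalizes the covariance of superposed, mass-unweighted Cartesian
Cα coordinates (population convention, 1/N).  Eigenvector signs follow a
deterministic rule (largest-magnitude component positive) so projections are
stable across runs.  The free-energy surface over (PC1, PC2) is the
Boltzmann inversion ΔG(X) = −k_B·T·ln P(X) with k_B = 0.0083145
kJ·mol⁻¹·K⁻¹ and T = 300 K by default, shifted so the sampled minimum is
zero.  Bins never visited are "unsampled" (NaN), never an infinite energy:
the inversion diverges at P = 0 and downstream arithmetic must not meet
infinities.  Default grid: 50×50 over the projection range padded 2 % per
side — appropriate for ≥10⁴ frames; with sparser sampling the bin count
should be reduced to keep tens of counts per occupied bin.

Basins are 8-connected regions of bins with ΔG ≤ depth_cut.  Regions
holding < 1 % of the total probability (`min_occupancy`) are discarded as
sampling noise — at finite sampling, isolated sparsely-hit bins would
otherwise each count as a basin.  Each basin reports its member frames, the
contiguous time intervals covering ≥80 % of them, its occupancy ΣP, and an
occupancy-based basin free energy −k_B·T·ln ΣP; basin ΔΔG computed from
occupancies has the same expectation as the difference of bin minima but a
far smaller variance.  Non-Gaussianity of a projection is reported (never
thresholded) as excess kurtosis and Sarle's bimodality coefficient
b = (skew²+1)/kurtosis.

## Pore profiling

At stations spaced `step` (default 0.25 Å) along a channel axis, the largest
probe sphere not overlapping any atom's vdW sphere is
max over the perpendicular plane of minᵢ(|p−xᵢ|−rᵢ), found by a 0.5 Å
coarse grid within `search_radius` (default 5 Å) of the axis followed by a
deterministic pattern search halved to 0.05 Å.  A deterministic optimizer
replaces stochastic annealing so profiles are bit-reproducible; a dense-grid
oracle bounds its error at 0.1 Å in tests.  Radii classify water passage
using the conventional 1.15 Å effective water radius: < 1.15 Å blocked,
1.15–2.30 Å single-file, > 2.30 Å bulk (two waters abreast).  The nearest
residue at a station is the residue of the atom realizing the minimum.  The
axis is either two endpoints or "auto" (principal axis of a channel-lining
selection).  vdW radii resolve explicit array → topology table → built-in
element table (C 1.7, N 1.55, O 1.52, S 1.8, H 1.2, Fe 2.0 Å).

## Energetics

The ledger is ΔG_bind = ΔH − TΔS with ΔH = ΔE_VDW + ΔE_ELE + ΔG_polar +
ΔG_nonpolar; its two identities are enforced at construction.  Vacuum cross
terms: Coulomb with f = 1389.35458 kJ·mol⁻¹·Å·e⁻² and Lennard-Jones with
Lorentz–Berthelot combination (σ arithmetic, ε geometric), no cutoff by
default.  Polar solvation (PB/GB) and the entropy term TΔS are accepted as
externally computed inputs: reimplementing continuum solvers or normal-mode
analysis is out of proportion to the bookkeeping they feed, and their
absence is flagged rather than silently zeroed.  Nonpolar solvation is the
linear SASA model γ·SASA + β with γ = 0.0227 kJ·mol⁻¹·Å⁻² and β = 3.849
kJ·mol⁻¹ (the common 0.00542 kcal·mol⁻¹·Å⁻² / 0.92 kcal·mol⁻¹ converted).
SASA uses the point-sampling (Shrake–Rupley) construction on a fixed
Fibonacci lattice (960 points; isolated-sphere error < 0.5 %, chosen for
determinism and a closed-form oracle).

Per-residue decomposition restricts the cross terms to each receptor
residue's atoms versus the ligand, samples frames evenly after discarding
the first 10 % (at most 180 frames, mirroring an every-0.5 ns schedule on a
100 ns run), joins optional per-residue GB/GBSUR tables, and ranks residues
by mean total contribution ascending.  The residue sums partition the
whole-receptor interaction exactly (tested to 1e-6).

## Synthetic data: what it emulates and what it does not

Fixtures are pure functions of their arguments; all randomness flows through
an explicit seed.  They emulate exactly the features each stage measures:

- **Two-state ensemble** (defaults: populations 0.7/0.3, 5 Å rigid
  displacement of the 6 terminal residues of a 24-residue ideal helix,
  0.3 Å isotropic Gaussian noise): a two-basin conformational mixture whose
  populations, displaced atoms and state labels are known.  Defaults are the
  study conditions for the parameter-recovery tests; 0.3 Å is a typical
  per-atom thermal width, 5 Å a typical loop-scale motion.
- **Pore cylinder**: rings of pseudo-atoms on the z-axis; the on-axis probe
  radius per ring plane is the closed form min_j √(r_j² + Δz²) − r_vdW.
  Optional concentric wall circles thicken the wall, because with a single
  thin ring the true in-plane maximum can lie radially *outside* a narrow
  ring flanked by wide ones — open space, not channel.
- **H-bond trajectory**: a donor–H–acceptor triple toggling between a
  bonded geometry (2.9 Å, 165°) and a broken one (4.5 Å, 120°) with
  Bernoulli per-frame states, so occupancy has a known binomial law.
- **Uniform gas** in a cubic box for the RDF baseline; **contact pair**, two
  fixed 6-residue conformations whose 4.5 Å contact sets are enumerated in
  the fixture's documentation and re-derived exhaustively in tests.

None of these sample a physical force field, include solvent, or have side
chains.  Passing tests therefore demonstrate that the *estimators* recover
known ground truth at the stated statistical precision — not that any
biological conclusion about a real system is reproduced.  Trajectory-scale
quantities of the original study (cluster percentages, absolute contact
counts, pore radii of a real protein, Table 2 frequencies, absolute ΔG
values) depend on the original MD trajectories and are intentionally not
targets; only the printed worked values, which are exactly recomputable from
in-text inputs, are asserted.

## Problem sizes in the test suite

Parameter-recovery tests run at the sizes their error bounds need: 10⁵
frames for the FEL ΔΔG recovery (±0.15 kJ·mol⁻¹ band), 2000–5000 frames for
binomial/χ-moment recoveries, ≤200 frames for O(n²) clustering oracles.
The full suite runs in about a minute on one CPU.

## Known limitations

- Single-linkage clustering chains: states closer than the threshold at
  any point merge; this is the defined behavior, not an artifact.
- The pore optimizer searches one plane per station; tunnels that curve
  faster than `search_radius` per `step` need a piecewise axis.
- No periodic-boundary handling outside `rdf`; trajectories are assumed
  whole and unwrapped.
- H-bond donor assignment is proximity-based (1.2 Å) and will mispair
  hydrogens in structures with unphysically close heteroatoms.
- B-factor comparison assumes isotropic, harmonic fluctuation.
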