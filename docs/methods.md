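# Methods

This note records the model, its assumptions, the numerical choices and
the open design decisions of `rhodosim`, in the order a user meets them.

## Resolution and mapping

The protein (opsin) is reduced to one interaction center per residue,
placed on the Cα and carrying the full residue mass (standard average
residue masses; 110 amu for unknown residue names).  The photoactive
site — chromophore, the linking lysine side chain, the active-site
water — is kept at united-atom resolution: one center per heavy atom
(C/N/O/S) whose mass includes its saturating hydrogens (defaults: C →
14.027 amu, N → 15.015, O → 16.0, water O → 18.015; all overridable in
the parameter table).  A residue selected *per atom* (the lysine side
chain) keeps its backbone CG bead; a residue selected whole (chromophore,
water) contributes no CG bead.  Centers are ordered CG first, then UA, so
the chromophore region occupies the last indices.  At bacteriorhodopsin
composition — 228 modelled residues, a 24-center united-atom chain
(20-carbon chromophore + 4-carbon lysine side chain) and one water —
this convention yields 253 centers, with the united-atom block at
indices 229–253 (1-based).

Assumptions: solvent and membrane are implicit; electrostatics,
hydrophobicity and hydrogen bonding are folded into the non-bonded Morse
description rather than treated as separate term classes; there is no
protonation-state logic.

## Force field

Three blocks (CG-CG, UA-UA, UA-CG), each split into bonded terms and
non-bonded terms; the non-bonded part is split again into local and
non-local by the reference-structure distance.

| term | form | defaults |
|---|---|---|
| bond | ½·k·(r−r₀)² | CG k = 50, UA/interface k = 300 kcal·mol⁻¹·Å⁻² |
| angle | ½·k·(θ−θ₀)² | CG helix/sheet/coil k = 30/20/10, UA k = 60 kcal·mol⁻¹·rad⁻² |
| dihedral | k·(1−cos(φ−φ₀)) | CG helix/sheet/coil k = 5/1/0.5, UA k = 2 kcal·mol⁻¹ |
| local Morse | D[(1−e^{−a(r−r_min)})²−1], r_min = reference distance | D = 1.0, a = 1.0 Å⁻¹ |
| non-local Morse (CG pairs) | same form, generic r_min = 5.5 Å | D = 0.2 |
| non-local LJ (UA pairs) | 4ε[(σ/r)¹²−(σ/r)⁶] | ε = 0.12, σ = 3.4 Å |
| hydrogen-bond Morse | Morse form, r_min = reference distance | D = 4.0 |
| tether | ½·K_teth·|r−r_ref|² | K_teth = 1.0 kcal·mol⁻¹·Å⁻², calibrated |

Dihedrals use the cosine form (periodic, minimum at the reference value)
rather than a harmonic in φ: isomerization passes through the full angle
range and must not see a 2π discontinuity.  The signed dihedral follows
the IUPAC convention (cis = 0°, trans = 180°, range (−180°, 180°]),
cross-checked against an independent trajectory-analysis library.

Topology: CG bonds join consecutive residues of a chain; angles and
dihedrals are all 3- and 4-paths of the bond graph.  UA connectivity is
detected by heavy-atom distance (≤ 1.8 Å) plus explicit links (the
Schiff-base bond UA→CG), which also generate the interface bonded terms.
Non-bonded pairs exclude 1-2 and 1-3 neighbours; reference distance ≤
6.5 Å → local, ≤ 12 Å → non-local, beyond → absent.  These cutoffs are
configuration keys, not measurements: the stated defaults are a Cα
contact-shell radius and a conventional outer cutoff.  Non-local terms
are switched to zero with a C¹ smoothstep over the final 1 Å so forces
stay continuous; local terms are permanent contacts of the reference
topology and are never truncated, so the term list is fixed (no neighbour
lists) and the Hamiltonian is strictly conservative.

Hydrogen-bond terms are assigned to pairs, within the local cutoff, of a
water oxygen or a united-atom nitrogen (the Schiff base) with a polar
partner (polar residue bead, or UA N/O).

Equilibrium values (r₀, θ₀, φ₀, local r_min) are measured in the
reference structure of each state, which makes that structure an exact
stationary point of the bonded + local potential (verified to
≤ 10⁻⁶ kcal·mol⁻¹·Å⁻¹).  The CG angle/dihedral stiffness is keyed by the
secondary-structure label of the central residue(s): H only if all
central beads are helical, E if all strand, else C.

Membrane exposure: a CG bead is flagged when its coordinate along the
membrane normal (z by default) is inside the slab *and* its radial
distance from the bundle axis is above a percentile (default 60) of the
in-slab radii.  Only flagged beads are tethered.  `calibrate_tether`
scans a stiffness grid with short thermalized runs and picks the K
minimizing the mean squared RMSF deviation from a target profile
(experimental B-factors via B = 8π²⟨Δr²⟩, or an external atomistic
profile); for a free bead the scan reproduces the equipartition closed
form ⟨Δr²⟩ = 3k_BT/K.

## Multi-stability

For each A→B pair the builder selects the homologous terms whose
equilibrium parameter changes beyond per-kind thresholds (bonds 0.2 Å,
angles 10°, dihedrals 20°, biased pair minima 1.0 Å; terms present in
only one state are always selected and paired with a zero-stiffness
copy).  Each selected pair becomes

E(x) = (a + b − √((a−b)² + ε²))/2, a = u_A(x), b = u_B(x) − δ.

Properties used as invariants: E ≤ min(a, b) with gap ≤ ε/2; E → min(a,b)
pointwise as ε → 0; the combination is C¹ through the crossing.  δ is
derived from the experimental free-energy difference ΔG_AB = G_B − G_A of
the transition: with n selected terms, each receives δ = −ΔG_AB/n, so the
minimized end states of the combined force field differ by ΔG_AB exactly
(verified by a minimization oracle to within ε).  The uniform split is
the minimal assumption — nothing in the procedure distinguishes the
selected terms — and is deliberately the only choice; barrier heights are
never parameterized, only emergent.  Chains of states are handled as
pairwise bistable force fields applied segment by segment, never as one
many-well surface.

## Dynamics

Velocity Verlet, default dt = 1 fs; unit system kcal·mol⁻¹/Å/fs/amu with
the single conversion constant 1 kcal·mol⁻¹ = 4.184×10⁻⁴ amu·Å²·fs⁻²
(exact, since 1 amu·Å²·fs⁻² = 10⁷ J·mol⁻¹), pinned by a harmonic-
oscillator period test at 0.1%.  Temperature control is Berendsen
rescaling every step, λ = √(1 + (dt/τ)(T_target/T_inst − 1)), with
τ = 1 fs for ground-state (strong-coupling) runs and τ = 50 fs otherwise;
a zero-kinetic-energy state with a positive target reseeds velocities
from Maxwell–Boltzmann.  Initial velocities are Maxwell–Boltzmann at the
leg temperature, from a seeded generator; trajectories are bit-
reproducible per (seed, protocol, force field) on a fixed platform.

Equilibration is annealing: L-BFGS minimization on the analytic gradient,
then staged NVT legs at 10, 20, 50, 100, 200, 300 K.  Desk-scale default
legs are 1 ps (the protocol's shape, not its production length — the
full-scale schedule uses 1 ns legs, and leg duration is a config value).

Photocycle protocol: ordered segments, each with its own force field —
single-state for equilibrium segments, bistable for transitions.  The
photo-triggered first step proceeds from an electronically excited,
barrier-less configuration and is therefore modelled as a direct swap of
the product-state force field onto the thermalized reactant.  Absolute
energies of different force fields are not comparable, so per-segment
potential traces are aligned pairwise by evaluating both force fields on
the shared splice frame and offsetting the later trace.

Coarse-grained kinetics is accelerated (degrees of freedom are
eliminated; no friction correction is applied), which lets low barriers
be crossed spontaneously in short runs.  High barriers are steered: a
harmonic restraint whose target advances along the linear Cartesian
interpolation between the end states.  Two operationalizations are
provided.  The *projection* mode restrains the scalar coordinate
s = (x−x_A)·(x_B−x_A)/|x_B−x_A|²; it is appropriate for quasi-1-D paths
but can be defeated by soft-mode escape — unrestrained directions (e.g. a
rigid translation of the ligand) satisfy the projection while the
intended internal coordinate never moves, which is exactly what happens
for a rotational dihedral flip.  The *targeted* mode (targeted-dynamics
form) restrains the full selected displacement to the interpolated path
point and is robust for such transitions; the steered runs of the
validation suite use it.  The restraint is dropped once every double-well
term sits in its B-parent well within a tolerance of max(ε, k_BT).

## Analysis

RMSD and RMSF use the standard formulas, with optional least-squares
rigid superposition (Kabsch/SVD).  Superposition before RMSF/PCA is a
flag, default on; for tethered simulations the lab frame is physical and
superposition off is equally meaningful, so outputs label the mode.
B = 8π²·RMSF² and its inverse are exposed as a strict bijection.

PCA diagonalises the 3N×3N covariance of the flattened coordinates about
their mean (population convention, divisor T); frames are projected onto
the first ten modes by default.  Invariants: eigenvalues descending and
non-negative, modes orthonormal, Σλ = trace of the covariance, projection
variance = eigenvalue, full-mode reconstruction exact.

Free-energy landscapes are Boltzmann inversions of the 2-D histogram of
(PC1, PC2): F = −k_BT ln(ρ/ρ_max), 50×50 bins by default spanning the
data range padded 5%, empty bins masked, populated minimum at zero.

Metastable minima are counted by a flooding/persistence scan of the
landscape grid (8-neighbour connectivity): bins are visited in order of
increasing F, basins merge where they touch, and a basin survives as a
minimum only if the ridge separating it from a deeper basin exceeds
`min_depth` (default 0.5 kcal·mol⁻¹).  Two statistical safeguards matter
on finite samples: empty bins are treated as passable high ground at the
top populated F level, so isolated fringe bins cannot survive as basins
of their own; and each basin's required persistence is raised by the
Poisson noise floor k_BT/√n of its minimum bin (the standard error of a
log-histogram estimate).  Both are properties of the estimator, not of
the physics.

## Synthetic fixtures: what they do and do not show

`make_helix_bundle` produces ideal α-helices (rise 1.5 Å/residue, 100°
twist, 2.3 Å helix radius) packed on a circle with 10 Å axis spacing and
smooth Bézier-arc loops; every 7th residue is serine so hydrogen-bond
terms have polar partners.  `make_two_state_pair` threads a linear
united-atom chain (1.5 Å bonds, 120° angles, all dihedrals trans) through
the bundle axis, bonds its head to the nearest helix bead (the toy
Schiff linkage), optionally places a single water bead, and generates
state B by rotating one chosen ligand dihedral (default 180°) and adding
Gaussian background noise of chosen RMS to the non-ligand beads.

These fixtures reproduce the *geometric and topological* features the
model assumes — helix bundle, threaded conjugated tail, covalent
UA–CG link, two reference states differing by an internal rotation — and
therefore exercise every term type and every stage of the pipeline.
They deliberately omit sequence realism, the β-ionone ring, realistic
loop geometry and any electrostatic specificity.  Passing tests on them
validates the machinery (energies, forces, integration, multi-stability,
analysis), not the biological accuracy of any particular rhodopsin
parameterization; runs on real reference structures enter through
`read_pdb` and an active-site selection and use the same code path.

Study conditions fixed once for the fixture transition tests: simulated
temperature 300 K, ΔG_AB = −10 kcal·mol⁻¹ for the constructed A→B flip —
the magnitude of a photoproduct's instability relative to the ground
state — under which the flip completes spontaneously in 10–30 ps of
simulated time; the high-barrier steering contrast stiffens the ligand
torsion to k = 10 kcal·mol⁻¹ (barrier ≈ 9.75 kcal·mol⁻¹ ≈ 16 k_BT),
which does not cross unaided in 10⁵ steps.

## Problem sizes and determinism

The validation suite and the reproduction script run desk-scale systems:
a two-helix, 24-residue bundle with a 6-bead ligand (30 centers, ~370
terms) for most dynamical checks, a one-helix variant (13 centers) for
the 10⁵-step microcanonical drift and steering runs, and a
7-helix, 253-center bacteriorhodopsin-composition model for the counting
convention.  Equilibrium statistics use 10⁴–5×10⁴ steps; these sizes are
the package's chosen defaults for its own validation, and every physical
default scales up unchanged.  All stochastic elements (initial
velocities, fixture noise, thermostat reseeds) flow from explicit integer
seeds.

## Known limitations

- Berendsen rescaling does not generate a strict canonical ensemble; it
  is used for consistency of the protocol, and equipartition checks pass
  at the 5–10% level appropriate to it.
- The local/non-local cutoffs, exposure percentile and all stiffness
  defaults are stated conventions, not fitted values; any quantitative
  application should calibrate them (the tether scan automates one case).
- Steering in projection mode can be defeated by soft modes (see above);
  targeted mode is the robust choice for rotational transitions.
- Landscape minima counts on short, time-correlated trajectories are
  binning-sensitive; the persistence criterion suppresses sampling noise
  but cannot define basins the sampling has not resolved.
- No explicit electrostatics, protonation logic, membrane particles or
  Nosé–Hoover/Langevin thermostats; periodic boundaries are absent
  (systems are tethered or free clusters).
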