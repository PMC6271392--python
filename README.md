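# rhodosim

Hybrid united-atom / coarse-grained (UA/CG), multi-stable molecular
dynamics of the rhodopsin photocycle.

Rhodopsins are seven-transmembrane-helix photoreceptors whose function —
proton pumping in bacteriorhodopsin, the first step of vision in the
mammalian pigment — is triggered by *cis–trans* photoisomerization of a
retinal chromophore bound to a lysine side chain through a Schiff base.
The photocycle traverses a closed sequence of spectrally distinct
structural states separated by barriers of widely different heights, so
its time scales run from femtoseconds (the isomerization itself) to
milliseconds.  No single-resolution simulation covers that range.

`rhodosim` implements a classical multi-scale answer for structural
modellers and method developers: the opsin is a minimalist coarse-grained
chain (one bead per residue, on the Cα) while the photoactive site —
chromophore, linking lysine side chain, active-site water — keeps
quasi-atomistic *united-atom* resolution (one center per heavy atom with
its hydrogens folded in).  Membrane and solvent are implicit.  States are
coupled by double-well force fields so that the entire cycle, including
spontaneous barrier crossings, is accessible to plain dynamics on a
single CPU.

## The model

The potential is split into three blocks,

```
U = U_CG-CG + U_UA-UA + U_UA-CG
```

each a sum of bond, angle, dihedral and non-bonded terms.  Non-bonded
pairs are partitioned by a cutoff on the *reference-structure* distance
into **local** terms (Morse wells centered on the reference separation —
the structure bias) and **non-local** terms (generic Morse for CG pairs,
Lennard-Jones for UA pairs, smoothly switched off at the outer cutoff).
Hydrogen bonds of the active-site water and the Schiff-base nitrogen get
dedicated, deeper Morse terms.  Membrane confinement is a harmonic tether
`U_teth = ½·K_teth·Δr²` on the membrane-exposed beads, with `K_teth`
calibrated against a target RMSF profile.

Equilibrium parameters are *measured* in the reference structure of each
state; stiffnesses come from an editable table keyed by block and, for
CG angles/dihedrals, by secondary structure.

A transition A→B replaces each interaction `u(x)` that changes
appreciably between the two states by the smoothed minimum of its two
parameterizations,

```
E(x) = ( u_A + (u_B − δ) − √((u_A − (u_B − δ))² + ε²) ) / 2
```

`ε` (default 0.5 kcal/mol) only rounds the cusp where the wells cross;
`δ` is assigned from the experimental free-energy difference of the
transition, split uniformly over the selected terms so that the minimized
end states differ by exactly ΔG.  **No parameter controls the barrier —
barrier heights are emergent.**  Dynamics is velocity Verlet (1 fs step)
with a Berendsen thermostat; equilibration is minimization followed by
staged heating (10→300 K).  The photo-triggered first transition is
modelled as a direct force-field swap on the thermalized reactant
(barrier-less excited-state step); transitions with barriers too high for
the coarse-graining-accelerated kinetics can be steered along a linear
reaction path.  Analysis covers RMSD/RMSF, B-factors (`B = 8π²⟨Δr²⟩`),
PCA essential dynamics, Boltzmann-inverted free-energy landscapes
`F = −k_B·T·ln(ρ/ρ_max)` over the first two principal components, and
metastable-minimum counting.

## Worked example

Everything is testable without downloads through the synthetic fixture
generator (a helix bundle with a toy all-*trans* ligand threaded through
it).  The following builds a two-state pair, couples the states with
ΔG(A→B) = −10 kcal/mol, and watches the flip happen spontaneously:

```python
import numpy as np
import rhodosim as rs

spec = rs.FixtureSpec(n_helices=2, residues_per_helix=10, loop_length=4,
                      ligand_length=6, seed=1, perturbation=0.05,
                      flip_dihedral_index=2, flip_angle_deg=180.0)
A, B, topo = rs.make_two_state_pair(spec)
params = rs.ParameterTable()
mA = rs.map_to_multiscale(A, topo["active_site"], links=topo["links"], params=params)
mB = rs.map_to_multiscale(B, topo["active_site"], links=topo["links"], params=params)
tsA = rs.parameterize_from_reference(rs.build_topology(mA, params=params), mA, params)
tsB = rs.parameterize_from_reference(rs.build_topology(mB, params=params), mB, params)
dw = rs.build_bistable_ff(tsA, tsB, deltaG_AB=-10.0, epsilon=0.5)

quad = tuple(mA.center_index("R", 1, f"C{i}") for i in (3, 4, 5, 6))
state = rs.SimulationState.from_model(mA, T_K=300.0, seed=4)
result = rs.run_photocycle(
    [rs.Segment(tsA, 2000, label="A", tau_fs=1.0),
     rs.Segment(dw, 30000, label="A->B", kind="transition")],
    state, stride=100)
phi = [rs.dihedral(f, *quad) for f in result.trajectory.frames]
print(f"dihedral: start {phi[0]:.0f} deg -> end {phi[-1]:.0f} deg")
print(f"double wells: {dw.n_double_well()}")
```

prints

```
dihedral: start 180 deg -> end -17 deg
double wells: 11
```

i.e. the ligand dihedral leaves the all-*trans* well (180°) and ends in
the *cis* well (0° ± thermal fluctuation of ~30° at 300 K); eleven terms
(the flipped dihedral plus the contacts of the rotated tail bead) were
promoted to double wells.  The same machinery runs on real PDB structures
via `rs.read_pdb` and an active-site selection such as
`["A:216:CB", "A:216:CG", "A:216:CD", "A:216:CE", "R:300", "W:402"]`.

A command-line layer wraps the pipeline:

```
rhodosim fixtures  --config cfg.yaml --out fx/
rhodosim build     --config cfg.yaml --out model/
rhodosim run       --config cfg.yaml --model-dir model/ --out run/ --seed 1
rhodosim photocycle --config cfg.yaml --out pc/ --seed 1
rhodosim analyze   --traj run/traj.xyz --out analysis/
rhodosim dump-defaults
```

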