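"""Synthetic structures with the geometry the multi-scale model assumes.

Real rhodopsins are seven-transmembrane-helix bundles with a conjugated
polyene chromophore threaded through the bundle and tied to one helix by
a covalent (Schiff-base) linkage.  The generators here emulate exactly
those geometric features — ideal α-helices packed on a circle, smooth
connecting loops, a linear united-atom ligand with alternating 180°
dihedrals through the bundle axis, an optional single-bead water — so
every stage of the pipeline (mapping, topology, parameterization,
double-well construction, dynamics, analysis) is testable without any
structure download.  No sequence or retinal-specific realism is
attempted: the point is to exercise the same term types.

All outputs are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UsageError
from .structure_io import Atom, Structure

__all__ = ["FixtureSpec", "make_helix_bundle", "make_two_state_pair"]

HELIX_RISE = 1.5  # Å per residue
HELIX_TWIST = np.deg2rad(100.0)  # per residue
HELIX_RADIUS = 2.3  # Å
PACK_SPACING = 10.0  # Å between adjacent helix axes
LIGAND_BOND = 1.5  # Å
LIGAND_ANGLE = np.deg2rad(120.0)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic two-state fixture."""

    n_helices: int = 7
    residues_per_helix: int = 20
    loop_length: int = 5
    ligand_length: int = 8
    seed: int = 0
    perturbation: float = 0.1  # Å RMS per-bead noise between states
    flip_dihedral_index: int = 2
    flip_angle_deg: float = 180.0
    include_water: bool = False

    def validate(self) -> None:
        if min(self.n_helices, self.residues_per_helix, self.ligand_length) < 1:
            raise UsageError("all fixture counts must be >= 1")
        if self.loop_length < 1 and self.n_helices > 1:
            raise UsageError("loop_length must be >= 1 for multi-helix bundles")
        if self.perturbation < 0:
            raise UsageError("perturbation must be non-negative")


def _helix_axis_positions(n_helices: int) -> np.ndarray:
    if n_helices == 1:
        return np.zeros((1, 2))
    R = PACK_SPACING / (2.0 * np.sin(np.pi / n_helices))
    ang = 2.0 * np.pi * np.arange(n_helices) / n_helices
    return np.stack([R * np.cos(ang), R * np.sin(ang)], axis=1)


def _ideal_helix(n_res: int, axis_xy: np.ndarray, ascending: bool) -> np.ndarray:
    i = np.arange(n_res)
    phase = HELIX_TWIST * i
    z = HELIX_RISE * i if ascending else HELIX_RISE * (n_res - 1 - i)
    x = axis_xy[0] + HELIX_RADIUS * np.cos(phase)
    y = axis_xy[1] + HELIX_RADIUS * np.sin(phase)
    return np.stack([x, y, z], axis=1)


def _loop_arc(p0: np.ndarray, p1: np.ndarray, n: int, bulge: float = 4.0) -> np.ndarray:
    """n interior points on a quadratic Bézier arc bowing outward from the origin."""
    mid = 0.5 * (p0 + p1)
    out = mid[:2]
    nrm = np.linalg.norm(out)
    direction = out / nrm if nrm > 1e-9 else np.array([1.0, 0.0])
    ctrl = mid + np.array([*(bulge * direction), np.sign(mid[2] + 1e-9) * bulge])
    t = (np.arange(1, n + 1) / (n + 1))[:, None]
    return (1 - t) ** 2 * p0 + 2 * t * (1 - t) * ctrl + t**2 * p1


def make_helix_bundle(spec: FixtureSpec) -> Structure:
    """Cα-trace helix bundle: ideal helices on a circle, loops as arcs.

    Residues are numbered continuously along the chain; every 7th
    residue is serine (a polar bead, so hydrogen-bond terms have
    partners), the rest alanine.  Helix residues carry an H label.
    """
    spec.validate()
    axes = _helix_axis_positions(spec.n_helices)
    coords: list[np.ndarray] = []
    ss: dict[tuple[str, int], str] = {}
    helix_ranges: list[tuple[int, int]] = []
    resi = 0
    for h in range(spec.n_helices):
        helix = _ideal_helix(spec.residues_per_helix, axes[h], ascending=h % 2 == 0)
        start = resi + 1
        for p in helix:
            resi += 1
            coords.append(p)
            ss[("A", resi)] = "H"
        helix_ranges.append((start, resi))
        if h < spec.n_helices - 1:
            nxt = _ideal_helix(
                spec.residues_per_helix, axes[h + 1], ascending=(h + 1) % 2 == 0
            )
            for p in _loop_arc(helix[-1], nxt[0], spec.loop_length):
                resi += 1
                coords.append(p)
                ss[("A", resi)] = "C"

    atoms = []
    for r, p in enumerate(coords, start=1):
        name = "SER" if r % 7 == 0 else "ALA"
        atoms.append(
            Atom(
                name="CA",
                element="C",
                residue_name=name,
                residue_index=r,
                chain_id="A",
                xyz=tuple(float(x) for x in p),
            )
        )
    s = Structure(atoms=atoms, secondary_structure=ss, source_id="fixture-bundle")
    s.validate()
    return s


def _ligand_coords(spec: FixtureSpec, z_center: float) -> np.ndarray:
    """Planar zig-zag chain along z through the bundle axis (all-trans)."""
    n = spec.ligand_length
    dz = LIGAND_BOND * np.sin(LIGAND_ANGLE / 2.0)
    dx = LIGAND_BOND * np.cos(LIGAND_ANGLE / 2.0)
    i = np.arange(n)
    x = dx * (i % 2)
    z = z_center + dz * (i - (n - 1) / 2.0)
    return np.stack([x, np.zeros(n), z], axis=1)


def make_two_state_pair(spec: FixtureSpec):
    """Two-state fixture: (Structure A, Structure B, ligand topology).

    State A is the bundle plus a linear united-atom ligand threaded
    through it and covalently linked to the nearest helix bead (the
    toy Schiff linkage).  State B is a copy with ligand dihedral
    ``flip_dihedral_index`` rotated by ``flip_angle_deg`` about its
    central bond and Gaussian noise of RMS ``perturbation`` Å on every
    non-ligand bead.

    The topology dict carries the active-site selection, the explicit
    link specs, and the ligand dihedral quadruples as atom-name specs.
    """
    spec.validate()
    if spec.ligand_length < 4:
        raise UsageError("ligand_length must be >= 4 to define a dihedral")
    n_dihedrals = spec.ligand_length - 3
    if not 0 <= spec.flip_dihedral_index < n_dihedrals:
        raise UsageError(
            f"flip_dihedral_index {spec.flip_dihedral_index} out of range "
            f"[0, {n_dihedrals})"
        )
    rng = np.random.default_rng(spec.seed)

    bundle = make_helix_bundle(spec)
    bz = bundle.coords[:, 2]
    lig = _ligand_coords(spec, z_center=float(0.5 * (bz.min() + bz.max())))

    lig_atoms = [
        Atom(
            name=f"C{i + 1}",
            element="C",
            residue_name="RET",
            residue_index=1,
            chain_id="R",
            xyz=tuple(float(x) for x in p),
            hetero=True,
        )
        for i, p in enumerate(lig)
    ]
    atoms = list(bundle.atoms) + lig_atoms
    extra = []
    if spec.include_water:
        w = lig[len(lig) // 2] + np.array([2.8, 0.0, 0.0])
        extra.append(
            Atom(
                name="O",
                element="O",
                residue_name="HOH",
                residue_index=1,
                chain_id="W",
                xyz=tuple(float(x) for x in w),
                hetero=True,
            )
        )
    atoms += extra

    # Schiff-base link: ligand head bead to the nearest helix Cα
    head = lig[0]
    d = np.linalg.norm(bundle.coords - head, axis=1)
    link_res = int(np.argmin(d)) + 1
    link = (f"R:1:C1", f"A:{link_res}:CA")

    A = Structure(
        atoms=atoms,
        secondary_structure=dict(bundle.secondary_structure),
        source_id="fixture-state-A",
    )

    # State B: dihedral flip + background noise
    coords_B = A.coords.copy()
    n_bundle = len(bundle.atoms)
    d0 = spec.flip_dihedral_index
    j = n_bundle + d0 + 1
    k = n_bundle + d0 + 2
    axis = coords_B[k] - coords_B[j]
    axis = axis / np.linalg.norm(axis)
    theta = np.deg2rad(spec.flip_angle_deg)
    Kmat = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    R = np.eye(3) + np.sin(theta) * Kmat + (1 - np.cos(theta)) * (Kmat @ Kmat)
    moving = np.arange(k + 1, n_bundle + spec.ligand_length)
    coords_B[moving] = (coords_B[moving] - coords_B[k]) @ R.T + coords_B[k]

    if spec.perturbation > 0:
        non_ligand = np.ones(len(atoms), dtype=bool)
        non_ligand[n_bundle: n_bundle + spec.ligand_length] = False
        noise = rng.normal(
            0.0, spec.perturbation / np.sqrt(3.0), size=(int(non_ligand.sum()), 3)
        )
        coords_B[non_ligand] += noise

    B = A.with_coords(coords_B)
    B.source_id = "fixture-state-B"

    dihedral_specs = [
        tuple(f"R:1:C{i + 1}" for i in range(d, d + 4)) for d in range(n_dihedrals)
    ]
    topology = {
        "active_site": [f"R:1"] + (["W:1"] if spec.include_water else []),
        "links": [link],
        "ligand_atom_indices": list(range(n_bundle, n_bundle + spec.ligand_length)),
        "dihedral_specs": dihedral_specs,
        "flip_dihedral_index": spec.flip_dihedral_index,
        "n_bundle_atoms": n_bundle,
    }
    return A, B, topology
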