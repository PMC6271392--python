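"""Build the hybrid UA/CG model and its reference-parameterized force field.

The opsin is represented at one bead per amino acid, placed on the Cα
and carrying the full residue mass; the photoactive site (retinal, the
linking lysine side chain, the active-site water) is represented at
united-atom resolution — one center per heavy atom (C/N/O) carrying the
heavy-atom mass plus its saturating hydrogens.  Solvent and membrane are
implicit: the membrane's confining effect is a harmonic tether on the
membrane-exposed opsin beads.

Parameterization follows the reference-structure philosophy: every
bonded term's equilibrium value is *measured* in the reference
structure, while stiffnesses and well depths come from an editable
parameter table keyed by block (CG/UA/interface) and, for the CG angle
and dihedral terms, by the secondary structure of the central
residue(s).  Non-bonded pairs are split by reference distance into
*local* terms (Morse wells biased to the reference separation) and
*non-local* terms (generic Morse for CG pairs, Lennard-Jones for UA
pairs) and the hydrogen bonds of the active-site water and Schiff-base
nitrogen get their own deeper Morse terms.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import BuildError, ConfigurationError, UsageError
from .forcefield import InteractionTerm, TermSet, dihedral_angles
from .structure_io import Atom, Structure, Trajectory

__all__ = [
    "Center",
    "MultiScaleModel",
    "Selection",
    "ParameterTable",
    "DEFAULT_PARAMETERS",
    "map_to_multiscale",
    "build_topology",
    "parameterize_from_reference",
    "flag_membrane_exposed",
    "add_tethers",
    "calibrate_tether",
]

# Average residue masses (amu, residue = amino acid minus water).
RESIDUE_MASSES = {
    "GLY": 57.05, "ALA": 71.08, "SER": 87.08, "PRO": 97.12, "VAL": 99.13,
    "THR": 101.10, "CYS": 103.14, "LEU": 113.16, "ILE": 113.16, "ASN": 114.10,
    "ASP": 115.09, "GLN": 128.13, "LYS": 128.17, "GLU": 129.12, "MET": 131.19,
    "HIS": 137.14, "PHE": 147.18, "ARG": 156.19, "TYR": 163.18, "TRP": 186.21,
}
DEFAULT_RESIDUE_MASS = 110.0

POLAR_RESIDUES = {
    "SER", "THR", "TYR", "ASN", "GLN", "ASP", "GLU", "LYS", "ARG", "HIS", "TRP",
}

#: Editable parameter table: every energetic constant of the force field.
#: Energies kcal·mol⁻¹, lengths Å, angle stiffnesses per rad², masses amu.
DEFAULT_PARAMETERS = {
    # CG (opsin) bonded
    "cg.bond.k": 50.0,
    "cg.angle.k.H": 30.0,
    "cg.angle.k.E": 20.0,
    "cg.angle.k.C": 10.0,
    "cg.dihedral.k.H": 5.0,
    "cg.dihedral.k.E": 1.0,
    "cg.dihedral.k.C": 0.5,
    # UA (active site) bonded — stiffer, from united-atom force fields
    "ua.bond.k": 300.0,
    "ua.angle.k": 60.0,
    "ua.dihedral.k": 2.0,
    # interface bonded terms (Schiff-base linkage to the opsin bead)
    "interface.bond.k": 300.0,
    "interface.angle.k": 60.0,
    "interface.dihedral.k": 2.0,
    # non-bonded
    "local.morse.D": 1.0,
    "local.morse.a": 1.0,
    "nonlocal.morse.D": 0.2,
    "nonlocal.morse.a": 1.0,
    "nonlocal.morse.rmin": 5.5,
    "ua.lj.eps": 0.12,
    "ua.lj.sigma": 3.4,
    "hbond.morse.D": 4.0,
    "hbond.morse.a": 1.0,
    # membrane tether
    "tether.k": 1.0,
    # geometry
    "cutoff.local": 6.5,
    "cutoff.nonlocal": 12.0,
    "switch.width": 1.0,
    "ua.bond.detect": 1.8,
    # united-atom masses (heavy atom + saturating hydrogens)
    "mass.ua.C": 14.027,
    "mass.ua.N": 15.015,
    "mass.ua.O": 16.0,
    "mass.ua.S": 32.06,
    "mass.ua.water": 18.015,
}


class ParameterTable:
    """Dict-like table of force-field constants with strict lookups."""

    def __init__(self, overrides: dict | None = None):
        self._values = dict(DEFAULT_PARAMETERS)
        if overrides:
            for k in overrides:
                if k not in self._values:
                    raise ConfigurationError(f"unknown parameter key {k!r}")
            self._values.update(overrides)

    def get(self, key: str) -> float:
        try:
            return float(self._values[key])
        except KeyError:
            raise ConfigurationError(f"missing force-field constant {key!r}") from None

    def as_dict(self) -> dict:
        return dict(self._values)


@dataclass(frozen=True)
class Center:
    """One interaction center of the multi-scale model."""

    kind: str  # "CG" | "UA"
    element: str  # UA heavy-atom element; "" for CG beads
    chain_id: str
    residue_index: int
    residue_name: str
    atom_name: str  # source atom ("CA" for CG beads)
    mass: float  # amu
    ss: str = "C"  # secondary-structure label of the residue (CG beads)


@dataclass
class MultiScaleModel:
    """Centers, masses, reference coordinates and topology metadata."""

    centers: list[Center]
    reference_coords: np.ndarray  # (N, 3) Å
    active_site: "Selection"
    links: list[tuple[int, int]] = field(default_factory=list)  # explicit bonds
    membrane_exposed: np.ndarray | None = None  # bool per center (CG only)
    source_id: str = ""

    def __post_init__(self):
        self.reference_coords = np.asarray(self.reference_coords, dtype=float)
        if self.reference_coords.shape != (len(self.centers), 3):
            raise UsageError("reference_coords incongruent with centers")
        if any(c.mass <= 0 for c in self.centers):
            raise UsageError("all center masses must be positive")
        if self.membrane_exposed is None:
            self.membrane_exposed = np.zeros(len(self.centers), dtype=bool)

    @property
    def n_centers(self) -> int:
        return len(self.centers)

    @property
    def masses(self) -> np.ndarray:
        return np.array([c.mass for c in self.centers])

    @property
    def is_cg(self) -> np.ndarray:
        return np.array([c.kind == "CG" for c in self.centers])

    def block_of(self, i: int, j: int, *more: int) -> str:
        kinds = {self.centers[x].kind for x in (i, j, *more)}
        if kinds == {"CG"}:
            return "CG-CG"
        if kinds == {"UA"}:
            return "UA-UA"
        return "UA-CG"

    def center_index(self, chain_id: str, residue_index: int, atom_name: str) -> int:
        for i, c in enumerate(self.centers):
            if (c.chain_id, c.residue_index, c.atom_name) == (
                chain_id, residue_index, atom_name,
            ):
                return i
        raise UsageError(f"no center {chain_id}:{residue_index}:{atom_name}")


class Selection:
    """Active-site selection: list of ``chain:residue[:atom]`` specs."""

    def __init__(self, specs: list[str] | None):
        self._residues: set[tuple[str, int]] = set()
        self._atoms: set[tuple[str, int, str]] = set()
        for spec in specs or []:
            parts = str(spec).split(":")
            if len(parts) == 2:
                self._residues.add((parts[0], int(parts[1])))
            elif len(parts) == 3:
                self._atoms.add((parts[0], int(parts[1]), parts[2]))
            else:
                raise UsageError(f"bad selection spec {spec!r} (chain:resi[:atom])")

    def __bool__(self) -> bool:
        return bool(self._residues or self._atoms)

    def matches(self, a: Atom) -> bool:
        if (a.chain_id, a.residue_index) in self._residues:
            return True
        return (a.chain_id, a.residue_index, a.name) in self._atoms

    def covers_whole_residue(self, chain_id: str, residue_index: int) -> bool:
        return (chain_id, residue_index) in self._residues

    def specs(self) -> list[str]:
        out = [f"{c}:{r}" for c, r in sorted(self._residues)]
        out += [f"{c}:{r}:{a}" for c, r, a in sorted(self._atoms)]
        return out


def _ua_mass(a: Atom, params: ParameterTable) -> float:
    if a.is_water:
        return params.get("mass.ua.water")
    key = f"mass.ua.{a.element.upper()}"
    try:
        return params.get(key)
    except ConfigurationError:
        raise ConfigurationError(
            f"no united-atom mass for element {a.element!r} (key {key})"
        ) from None


def map_to_multiscale(
    s: Structure,
    active_site: Selection | list[str] | None = None,
    links: list[tuple[str, str]] | None = None,
    params: ParameterTable | None = None,
) -> MultiScaleModel:
    """Map a structure onto CG beads (Cα) plus UA centers (active site).

    Every residue with no atom in the active-site selection contributes
    one CG bead at its Cα carrying the residue mass; every heavy atom
    inside the selection contributes one UA center.  A residue selected
    per-atom (e.g. a lysine side chain) keeps its backbone CG bead.
    CG beads come first in center order, then the UA centers.

    ``links`` are explicit covalent bonds given as pairs of
    ``chain:residue:atom`` specs — e.g. the Schiff-base linkage between
    the retinal chain and the opsin bead — and may join UA to CG.
    """
    if not s.atoms:
        raise UsageError("empty structure")
    s.validate()
    params = params or ParameterTable()
    if not isinstance(active_site, Selection):
        active_site = Selection(active_site)

    if active_site:
        matched = [a for a in s.atoms if active_site.matches(a)]
        if not matched:
            raise UsageError("active-site selection matches no atoms")

    centers: list[Center] = []
    coords: list[tuple[float, float, float]] = []

    # CG pass: one bead per residue not fully swallowed by the selection
    residue_atoms: dict[tuple[str, int], list[Atom]] = {}
    for a in s.atoms:
        residue_atoms.setdefault((a.chain_id, a.residue_index), []).append(a)

    for (chain, resi), atoms in residue_atoms.items():
        if all(active_site.matches(a) for a in atoms):
            continue  # fully united-atom residue (retinal, water)
        ca = next((a for a in atoms if a.name == "CA"), None)
        if ca is None:
            raise BuildError(f"residue {chain}:{resi} has no CA atom for its CG bead")
        name = atoms[0].residue_name.upper()
        centers.append(
            Center(
                kind="CG",
                element="",
                chain_id=chain,
                residue_index=resi,
                residue_name=name,
                atom_name="CA",
                mass=RESIDUE_MASSES.get(name, DEFAULT_RESIDUE_MASS),
                ss=s.ss_label(chain, resi),
            )
        )
        coords.append(ca.xyz)

    # UA pass: heavy atoms of the selection, in structure order
    for a in s.atoms:
        if active_site.matches(a):
            centers.append(
                Center(
                    kind="UA",
                    element=a.element.upper(),
                    chain_id=a.chain_id,
                    residue_index=a.residue_index,
                    residue_name=a.residue_name.upper(),
                    atom_name=a.name,
                    mass=_ua_mass(a, params),
                    ss="C",
                )
            )
            coords.append(a.xyz)

    model = MultiScaleModel(
        centers=centers,
        reference_coords=np.array(coords),
        active_site=active_site,
        source_id=s.source_id,
    )
    for spec_a, spec_b in links or []:
        ia = model.center_index(*_split_spec(spec_a))
        ib = model.center_index(*_split_spec(spec_b))
        model.links.append((ia, ib))
    return model


def _split_spec(spec: str) -> tuple[str, int, str]:
    parts = str(spec).split(":")
    if len(parts) != 3:
        raise UsageError(f"link spec must be chain:resi:atom, got {spec!r}")
    return parts[0], int(parts[1]), parts[2]


# ---------------------------------------------------------------------------
# Topology
# ---------------------------------------------------------------------------

def _bond_list(m: MultiScaleModel, detect_cut: float) -> list[tuple[int, int]]:
    bonds: set[tuple[int, int]] = set()
    # CG chain: consecutive residues within a chain
    cg = [(i, c) for i, c in enumerate(m.centers) if c.kind == "CG"]
    for (i, ci), (j, cj) in zip(cg, cg[1:]):
        if ci.chain_id == cj.chain_id and cj.residue_index == ci.residue_index + 1:
            bonds.add((i, j))
    # UA covalent connectivity by distance
    ua_idx = [i for i, c in enumerate(m.centers) if c.kind == "UA"]
    X = m.reference_coords
    for a, b in itertools.combinations(ua_idx, 2):
        if np.linalg.norm(X[a] - X[b]) <= detect_cut:
            bonds.add((min(a, b), max(a, b)))
    for a, b in m.links:
        bonds.add((min(a, b), max(a, b)))
    return sorted(bonds)


def _neighbor_map(n: int, bonds) -> list[set[int]]:
    nb: list[set[int]] = [set() for _ in range(n)]
    for a, b in bonds:
        nb[a].add(b)
        nb[b].add(a)
    return nb


def _is_hbond_pair(m: MultiScaleModel, i: int, j: int) -> bool:
    def hb_center(c: Center) -> bool:
        return c.kind == "UA" and (
            c.element in ("N", "O") and (c.residue_name in ("HOH", "WAT") or c.element == "N")
            or (c.element == "O" and c.residue_name in ("HOH", "WAT"))
        )

    def polar_partner(c: Center) -> bool:
        if c.kind == "CG":
            return c.residue_name in POLAR_RESIDUES
        return c.element in ("N", "O")

    ci, cj = m.centers[i], m.centers[j]
    return (hb_center(ci) and polar_partner(cj)) or (hb_center(cj) and polar_partner(ci))


def build_topology(
    m: MultiScaleModel,
    cutoff_local: float = 6.5,
    cutoff_nonlocal: float = 12.0,
    params: ParameterTable | None = None,
) -> TermSet:
    """Enumerate all interaction terms from the reference geometry.

    Bonds, angles and dihedrals follow the covalent/pseudo-covalent
    graph (CG chain, UA distance-detected connectivity, explicit links).
    Non-bonded pairs exclude 1-2 and 1-3 neighbours and are partitioned
    exhaustively by reference distance: (0, cutoff_local] → local,
    (cutoff_local, cutoff_nonlocal] → non-local.  The returned TermSet
    is a parameter *skeleton* (unit stiffness, unit well depth) — pass
    it through :func:`parameterize_from_reference` for real constants.
    """
    if cutoff_local > cutoff_nonlocal:
        raise UsageError("cutoff_local must not exceed cutoff_nonlocal")
    params = params or ParameterTable()
    X = m.reference_coords
    bonds = _bond_list(m, params.get("ua.bond.detect"))
    nb = _neighbor_map(m.n_centers, bonds)

    terms: list[InteractionTerm] = []
    for a, b in bonds:
        r0 = float(np.linalg.norm(X[a] - X[b]))
        terms.append(
            InteractionTerm("bond", (a, b), {"k": 1.0, "r0": r0}, m.block_of(a, b))
        )

    angles = set()
    for j in range(m.n_centers):
        for i, k in itertools.combinations(sorted(nb[j]), 2):
            angles.add((i, j, k))
    for i, j, k in sorted(angles):
        th0 = _measure_angle(X, i, j, k)
        terms.append(
            InteractionTerm(
                "angle", (i, j, k), {"k": 1.0, "theta0": th0}, m.block_of(i, j, k)
            )
        )

    dihedrals = set()
    for j, k in bonds:
        for i in nb[j] - {k}:
            for l in nb[k] - {j, i}:
                tup = (i, j, k, l)
                if tup[::-1] < tup:
                    tup = tup[::-1]
                dihedrals.add(tup)
    for tup in sorted(dihedrals):
        phi0 = float(dihedral_angles(X, np.array([tup]))[0])
        terms.append(
            InteractionTerm("dihedral", tup, {"k": 1.0, "phi0": phi0}, m.block_of(*tup))
        )

    # Non-bonded pairs: exclude 1-2 and 1-3
    excluded = {tuple(sorted(b)) for b in bonds}
    for j in range(m.n_centers):
        for i, k in itertools.combinations(sorted(nb[j]), 2):
            excluded.add((i, k))
    D = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=-1)
    for i in range(m.n_centers):
        for j in range(i + 1, m.n_centers):
            if (i, j) in excluded:
                continue
            r = D[i, j]
            if r <= cutoff_local:
                kind = "hbond-morse" if _is_hbond_pair(m, i, j) else "morse"
                terms.append(
                    InteractionTerm(
                        kind,
                        (i, j),
                        {"D": 1.0, "a": 1.0, "rmin": float(r)},
                        m.block_of(i, j),
                        locality="local",
                    )
                )
            elif r <= cutoff_nonlocal:
                block = m.block_of(i, j)
                if block == "UA-UA":
                    terms.append(
                        InteractionTerm(
                            "lj",
                            (i, j),
                            {"eps": 1.0, "sigma": 3.4},
                            block,
                            locality="nonlocal",
                        )
                    )
                else:
                    terms.append(
                        InteractionTerm(
                            "morse",
                            (i, j),
                            {"D": 1.0, "a": 1.0, "rmin": float(r)},
                            block,
                            locality="nonlocal",
                        )
                    )
    return TermSet(terms)


def _measure_angle(X, i, j, k) -> float:
    u = X[i] - X[j]
    v = X[k] - X[j]
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.arccos(np.clip(c, -1.0, 1.0)))


def _cg_ss_key(m: MultiScaleModel, centers: tuple[int, ...]) -> str:
    """Secondary-structure key of the central residue(s): H only if all
    central beads are helical, E if all strand, else C."""
    if len(centers) == 3:
        mid = [centers[1]]
    else:
        mid = [centers[1], centers[2]]
    labels = {m.centers[i].ss for i in mid}
    if labels == {"H"}:
        return "H"
    if labels == {"E"}:
        return "E"
    return "C"


def parameterize_from_reference(
    ts: TermSet,
    m: MultiScaleModel,
    params: ParameterTable | None = None,
) -> TermSet:
    """Fill in elastic constants and well depths from the parameter table.

    Equilibrium values are re-measured from the model's reference
    coordinates (bond lengths, angles, dihedrals, local Morse minima);
    constants are keyed by block and, for CG angles/dihedrals, by the
    secondary-structure label of the central residue(s).  UA-UA
    non-local pairs get the tabulated Lennard-Jones parameters, other
    non-local pairs a generic shallow Morse well; all non-local terms
    are smoothly switched off at the non-local cutoff.
    """
    params = params or ParameterTable()
    X = m.reference_coords
    r_off = params.get("cutoff.nonlocal")
    r_on = r_off - params.get("switch.width")

    out: list[InteractionTerm] = []
    for t in ts:
        if hasattr(t, "parent_a"):
            out.append(t)  # already double-well: leave untouched
            continue
        c = t.centers
        if t.kind == "bond":
            r0 = float(np.linalg.norm(X[c[0]] - X[c[1]]))
            if t.block == "CG-CG":
                k = params.get("cg.bond.k")
            elif t.block == "UA-UA":
                k = params.get("ua.bond.k")
            else:
                k = params.get("interface.bond.k")
            out.append(InteractionTerm("bond", c, {"k": k, "r0": r0}, t.block))
        elif t.kind == "angle":
            th0 = _measure_angle(X, *c)
            if t.block == "CG-CG":
                k = params.get(f"cg.angle.k.{_cg_ss_key(m, c)}")
            elif t.block == "UA-UA":
                k = params.get("ua.angle.k")
            else:
                k = params.get("interface.angle.k")
            out.append(InteractionTerm("angle", c, {"k": k, "theta0": th0}, t.block))
        elif t.kind == "dihedral":
            phi0 = float(dihedral_angles(X, np.array([c]))[0])
            if t.block == "CG-CG":
                k = params.get(f"cg.dihedral.k.{_cg_ss_key(m, c)}")
            elif t.block == "UA-UA":
                k = params.get("ua.dihedral.k")
            else:
                k = params.get("interface.dihedral.k")
            out.append(InteractionTerm("dihedral", c, {"k": k, "phi0": phi0}, t.block))
        elif t.kind == "hbond-morse":
            rmin = float(np.linalg.norm(X[c[0]] - X[c[1]]))
            out.append(
                InteractionTerm(
                    "hbond-morse",
                    c,
                    {
                        "D": params.get("hbond.morse.D"),
                        "a": params.get("hbond.morse.a"),
                        "rmin": rmin,
                    },
                    t.block,
                    locality="local",
                )
            )
        elif t.kind == "morse" and t.locality == "local":
            rmin = float(np.linalg.norm(X[c[0]] - X[c[1]]))
            out.append(
                InteractionTerm(
                    "morse",
                    c,
                    {
                        "D": params.get("local.morse.D"),
                        "a": params.get("local.morse.a"),
                        "rmin": rmin,
                    },
                    t.block,
                    locality="local",
                )
            )
        elif t.kind == "morse":
            out.append(
                InteractionTerm(
                    "morse",
                    c,
                    {
                        "D": params.get("nonlocal.morse.D"),
                        "a": params.get("nonlocal.morse.a"),
                        "rmin": params.get("nonlocal.morse.rmin"),
                        "r_on": r_on,
                        "r_off": r_off,
                    },
                    t.block,
                    locality="nonlocal",
                )
            )
        elif t.kind == "lj":
            out.append(
                InteractionTerm(
                    "lj",
                    c,
                    {
                        "eps": params.get("ua.lj.eps"),
                        "sigma": params.get("ua.lj.sigma"),
                        "r_on": r_on,
                        "r_off": r_off,
                    },
                    t.block,
                    locality="nonlocal",
                )
            )
        elif t.kind == "tether":
            out.append(t)
        else:  # pragma: no cover - exhaustive over KINDS
            raise ConfigurationError(f"no parameterization rule for kind {t.kind!r}")
    return TermSet(out)


# ---------------------------------------------------------------------------
# Membrane exposure and tethers
# ---------------------------------------------------------------------------

def flag_membrane_exposed(
    m: MultiScaleModel,
    slab_z_range: tuple[float, float],
    percentile: float = 60.0,
    axis: str = "z",
) -> MultiScaleModel:
    """Flag CG beads exposed to the membrane.

    A bead is exposed when its reference coordinate along the membrane
    normal lies inside the slab *and* its radial distance from the
    bundle axis is above the given percentile of the in-slab radii
    (outer shell of the helix bundle).  Only flagged beads receive
    tether terms.
    """
    lo, hi = slab_z_range
    if not hi > lo:
        raise UsageError("empty membrane slab")
    ax = {"x": 0, "y": 1, "z": 2}[axis]
    X = m.reference_coords
    z = X[:, ax]
    radial_dims = [d for d in range(3) if d != ax]
    center = X[:, radial_dims].mean(axis=0)
    radii = np.linalg.norm(X[:, radial_dims] - center, axis=1)

    in_slab = (z >= lo) & (z <= hi) & m.is_cg
    flags = np.zeros(m.n_centers, dtype=bool)
    if in_slab.any():
        thr = np.percentile(radii[in_slab], percentile)
        flags[in_slab & (radii >= thr)] = True
    m.membrane_exposed = flags
    return m


def add_tethers(ts: TermSet, m: MultiScaleModel, k_teth: float) -> TermSet:
    """Return a new TermSet with harmonic tethers on the flagged beads.

    Anchors are the reference coordinates (Δr is the displacement of
    the bead from its starting position).  Existing tethers are
    replaced, so the calibration scan can reuse one topology.
    """
    if k_teth < 0:
        raise UsageError("k_teth must be non-negative")
    base = [t for t in ts if getattr(t, "kind", None) != "tether"]
    out = TermSet(base)
    for i in np.nonzero(m.membrane_exposed)[0]:
        out.add(
            InteractionTerm(
                "tether",
                (int(i),),
                {"k": k_teth, "anchor": tuple(m.reference_coords[i])},
                "CG-CG",
            )
        )
    return out


def calibrate_tether(
    m: MultiScaleModel,
    ts: TermSet,
    target_rmsf: np.ndarray,
    T_K: float = 300.0,
    grid: list[float] | None = None,
    n_steps: int = 20000,
    dt_fs: float = 1.0,
    tau_fs: float = 50.0,
    stride: int = 10,
    equil_fraction: float = 0.25,
    seed: int = 0,
) -> tuple[float, pd.DataFrame]:
    """Scan tether stiffnesses against a target RMSF profile.

    For each candidate K_teth a short thermalized run is performed and
    the per-bead RMSF (no superposition — the system is tethered) is
    compared with the target over the flagged beads; the K minimizing
    the mean squared deviation wins.  Returns (best K, scan table).
    """
    from .analysis import rmsf as _rmsf
    from .dynamics import SimulationState, run_md

    if not grid:
        raise UsageError("tether grid must be non-empty")
    if any(k <= 0 for k in grid):
        raise UsageError("tether stiffness candidates must be positive")
    target_rmsf = np.asarray(target_rmsf, dtype=float)
    flagged = np.nonzero(m.membrane_exposed)[0]
    n_cg = int(m.is_cg.sum())
    if target_rmsf.shape != (n_cg,):
        raise UsageError(
            f"target RMSF profile has length {target_rmsf.shape}, expected ({n_cg},)"
        )
    cg_idx = np.nonzero(m.is_cg)[0]
    cg_pos = {int(i): p for p, i in enumerate(cg_idx)}

    rows = []
    for K in grid:
        ts_k = add_tethers(ts, m, K)
        state = SimulationState.from_model(m, T_K=T_K, seed=seed)
        _, traj, _ = run_md(
            state, ts_k, n_steps=n_steps, dt_fs=dt_fs, T_target_K=T_K,
            tau_fs=tau_fs, stride=stride,
        )
        skip = int(traj.n_frames * equil_fraction)
        prof = _rmsf(Trajectory(traj.frames[skip:], traj.dt_fs), superpose=False)
        sim = np.array([prof[i] for i in flagged])
        tgt = np.array([target_rmsf[cg_pos[int(i)]] for i in flagged])
        mse = float(np.mean((sim - tgt) ** 2)) if len(flagged) else np.inf
        rows.append({"k_teth": K, "mse": mse})
    table = pd.DataFrame(rows)
    best = float(table.loc[table["mse"].idxmin(), "k_teth"])
    return best, table
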