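"""Energy and force evaluation for the hybrid UA/CG force field.

The total potential is a sum over typed terms, formally split into three
blocks — intra-opsin (CG-CG), intra-active-site (UA-UA) and interface
(UA-CG) — each of which decomposes into bonded terms (bond, angle,
dihedral) and non-bonded terms, the latter partitioned into *local*
(reference-biased Morse wells at the reference separation) and
*non-local* (generic Morse or Lennard-Jones) parts by a cutoff radius.
Membrane confinement enters as harmonic tethers on exposed beads,
U_teth = ½·K_teth·|Δr|².

Functional forms (energies in kcal·mol⁻¹, lengths in Å, angles in rad):

=============  =====================================================
bond, angle    ½·k·(x − x₀)²
dihedral       k·(1 − cos(φ − φ₀))        (periodic, minimum at φ₀)
morse          D·[(1 − e^{−a(r − r_min)})² − 1]
lj             4ε[(σ/r)¹² − (σ/r)⁶]
tether         ½·K_teth·|r − anchor|²
hbond-morse    same form as morse (deeper well, separate term class)
=============  =====================================================

Non-local pair terms are smoothly switched to zero over a 1 Å window
below the non-local cutoff so forces stay continuous; local terms are
permanent contacts of the reference topology and are not truncated.

Double-well terms (see :mod:`rhodosim.multistable`) are evaluated here
as a smoothed minimum of two parent terms; the force is the convex
combination of the parent forces with weights ∂E/∂u_A and ∂E/∂u_B.

Evaluation is vectorised: a :class:`TermSet` lazily compiles its terms
into per-kind index/parameter arrays, so the per-step cost of dynamics
is a handful of numpy kernels rather than a Python loop over terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .errors import EvaluationError, ParseError, UsageError

__all__ = [
    "InteractionTerm",
    "TermSet",
    "EnergyBreakdown",
    "term_energy",
    "total_energy",
    "forces",
    "energy_and_forces",
]

BLOCKS = ("CG-CG", "UA-UA", "UA-CG")
PAIR_KINDS = ("bond", "morse", "lj", "hbond-morse")
KINDS = ("bond", "angle", "dihedral", "morse", "lj", "tether", "hbond-morse")

_ARITY = {
    "bond": 2,
    "angle": 3,
    "dihedral": 4,
    "morse": 2,
    "lj": 2,
    "tether": 1,
    "hbond-morse": 2,
}

_PARAM_KEYS = {
    "bond": ("k", "r0"),
    "angle": ("k", "theta0"),
    "dihedral": ("k", "phi0"),
    "morse": ("D", "a", "rmin"),
    "lj": ("eps", "sigma"),
    "tether": ("k",),
    "hbond-morse": ("D", "a", "rmin"),
}


@dataclass(frozen=True)
class InteractionTerm:
    """One potential term acting on a tuple of interaction centers.

    ``params`` holds kind-specific scalars (see module docstring); a
    tether additionally carries its 3-vector ``anchor``.  Pair terms may
    carry ``r_on``/``r_off`` for smooth truncation.  ``block`` labels
    the three-way split and ``locality`` the local/non-local split of
    non-bonded terms.
    """

    kind: str
    centers: tuple[int, ...]
    params: dict
    block: str = ""
    locality: str = ""

    def __post_init__(self):
        if self.kind not in KINDS:
            raise UsageError(f"unknown term kind {self.kind!r}")
        if len(self.centers) != _ARITY[self.kind]:
            raise UsageError(
                f"{self.kind} term needs {_ARITY[self.kind]} centers, "
                f"got {len(self.centers)}"
            )
        if len(set(self.centers)) != len(self.centers):
            raise UsageError(f"repeated center index in {self.kind} term {self.centers}")
        for key in _PARAM_KEYS[self.kind]:
            if key not in self.params:
                raise UsageError(f"{self.kind} term missing parameter {key!r}")
            v = float(self.params[key])
            if not np.isfinite(v):
                raise UsageError(f"{self.kind} parameter {key}={v} not finite")
        if self.kind == "tether" and "anchor" not in self.params:
            raise UsageError("tether term missing 'anchor'")


def _is_double_well(t) -> bool:
    return hasattr(t, "parent_a") and hasattr(t, "parent_b")


# ---------------------------------------------------------------------------
# Vectorised kind evaluators
# ---------------------------------------------------------------------------

def _switch(r: np.ndarray, r_on: np.ndarray, r_off: np.ndarray):
    """C¹ smoothstep from 1 at r_on to 0 at r_off; (S, dS/dr)."""
    S = np.ones_like(r)
    dS = np.zeros_like(r)
    active = np.isfinite(r_off)
    if not active.any():
        return S, dS
    width = np.ones_like(r)
    width[active] = r_off[active] - r_on[active]
    t = np.zeros_like(r)
    t[active] = np.clip((r[active] - r_on[active]) / width[active], 0.0, 1.0)
    S[active] = 1.0 - t[active] ** 2 * (3.0 - 2.0 * t[active])
    dS[active] = -6.0 * t[active] * (1.0 - t[active]) / width[active]
    return S, dS


def _pair_geometry(coords, idx):
    d = coords[idx[:, 0]] - coords[idx[:, 1]]
    r = np.sqrt(np.einsum("ij,ij->i", d, d))
    if np.any(r < 1e-9):
        raise EvaluationError("zero interparticle distance in pair term")
    return d, r


def _acc_pair_force(F, idx, d, r, dEdr):
    fvec = -(dEdr / r)[:, None] * d
    np.add.at(F, idx[:, 0], fvec)
    np.add.at(F, idx[:, 1], -fvec)


def _eval_bond(coords, idx, P, weights=None, F=None):
    d, r = _pair_geometry(coords, idx)
    e = 0.5 * P["k"] * (r - P["r0"]) ** 2
    if F is not None:
        g = P["k"] * (r - P["r0"])
        if weights is not None:
            g = g * weights
        _acc_pair_force(F, idx, d, r, g)
    return e


def _eval_morse(coords, idx, P, weights=None, F=None):
    d, r = _pair_geometry(coords, idx)
    x = np.exp(-P["a"] * (r - P["rmin"]))
    e0 = P["D"] * ((1.0 - x) ** 2 - 1.0)
    S, dS = _switch(r, P.get("r_on", np.full_like(r, np.inf)),
                    P.get("r_off", np.full_like(r, np.inf)))
    e = e0 * S
    if F is not None:
        g = 2.0 * P["D"] * P["a"] * x * (1.0 - x) * S + e0 * dS
        if weights is not None:
            g = g * weights
        _acc_pair_force(F, idx, d, r, g)
    return e


def _eval_lj(coords, idx, P, weights=None, F=None):
    d, r = _pair_geometry(coords, idx)
    sr6 = (P["sigma"] / r) ** 6
    e0 = 4.0 * P["eps"] * (sr6 * sr6 - sr6)
    S, dS = _switch(r, P.get("r_on", np.full_like(r, np.inf)),
                    P.get("r_off", np.full_like(r, np.inf)))
    e = e0 * S
    if F is not None:
        g = 4.0 * P["eps"] * (-12.0 * sr6 * sr6 + 6.0 * sr6) / r * S + e0 * dS
        if weights is not None:
            g = g * weights
        _acc_pair_force(F, idx, d, r, g)
    return e


def _eval_angle(coords, idx, P, weights=None, F=None):
    u = coords[idx[:, 0]] - coords[idx[:, 1]]
    v = coords[idx[:, 2]] - coords[idx[:, 1]]
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    if np.any(nu < 1e-9) or np.any(nv < 1e-9):
        raise EvaluationError("zero bond length in angle term")
    uh = u / nu[:, None]
    vh = v / nv[:, None]
    c = np.clip(np.einsum("ij,ij->i", uh, vh), -1.0, 1.0)
    theta = np.arccos(c)
    e = 0.5 * P["k"] * (theta - P["theta0"]) ** 2
    if F is not None:
        s = np.sqrt(np.clip(1.0 - c * c, 1e-12, None))
        dEdth = P["k"] * (theta - P["theta0"])
        if weights is not None:
            dEdth = dEdth * weights
        dth_di = (c[:, None] * uh - vh) / (nu * s)[:, None]
        dth_dk = (c[:, None] * vh - uh) / (nv * s)[:, None]
        np.add.at(F, idx[:, 0], -dEdth[:, None] * dth_di)
        np.add.at(F, idx[:, 2], -dEdth[:, None] * dth_dk)
        np.add.at(F, idx[:, 1], dEdth[:, None] * (dth_di + dth_dk))
    return e


def dihedral_angles(coords: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Signed dihedrals (rad, IUPAC convention: cis = 0) for index rows i,j,k,l."""
    b1 = coords[idx[:, 1]] - coords[idx[:, 0]]
    b2 = coords[idx[:, 2]] - coords[idx[:, 1]]
    b3 = coords[idx[:, 3]] - coords[idx[:, 2]]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2, axis=1)
    if np.any(nb2 < 1e-9):
        raise EvaluationError("zero central bond in dihedral term")
    m = np.cross(n1, b2 / nb2[:, None])
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", m, n2)
    if np.any((np.abs(x) < 1e-18) & (np.abs(y) < 1e-18)):
        raise EvaluationError("collinear atoms in dihedral term")
    return np.arctan2(-y, x)


def _eval_dihedral(coords, idx, P, weights=None, F=None):
    phi = dihedral_angles(coords, idx)
    e = P["k"] * (1.0 - np.cos(phi - P["phi0"]))
    if F is not None:
        b1 = coords[idx[:, 1]] - coords[idx[:, 0]]
        b2 = coords[idx[:, 2]] - coords[idx[:, 1]]
        b3 = coords[idx[:, 3]] - coords[idx[:, 2]]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        nb2 = np.linalg.norm(b2, axis=1)
        n1sq = np.einsum("ij,ij->i", n1, n1)
        n2sq = np.einsum("ij,ij->i", n2, n2)
        if np.any(n1sq < 1e-18) or np.any(n2sq < 1e-18):
            raise EvaluationError("collinear atoms in dihedral term")
        dEdphi = P["k"] * np.sin(phi - P["phi0"])
        if weights is not None:
            dEdphi = dEdphi * weights
        dphi_di = -(nb2 / n1sq)[:, None] * n1
        dphi_dl = (nb2 / n2sq)[:, None] * n2
        c12 = np.einsum("ij,ij->i", b1, b2) / (nb2 * nb2)
        c32 = np.einsum("ij,ij->i", b3, b2) / (nb2 * nb2)
        dphi_dj = -(1.0 + c12)[:, None] * dphi_di + c32[:, None] * dphi_dl
        dphi_dk = c12[:, None] * dphi_di - (1.0 + c32)[:, None] * dphi_dl
        np.add.at(F, idx[:, 0], -dEdphi[:, None] * dphi_di)
        np.add.at(F, idx[:, 1], -dEdphi[:, None] * dphi_dj)
        np.add.at(F, idx[:, 2], -dEdphi[:, None] * dphi_dk)
        np.add.at(F, idx[:, 3], -dEdphi[:, None] * dphi_dl)
    return e


def _eval_tether(coords, idx, P, weights=None, F=None):
    d = coords[idx[:, 0]] - P["anchor"]
    e = 0.5 * P["k"] * np.einsum("ij,ij->i", d, d)
    if F is not None:
        g = np.asarray(P["k"], dtype=float)
        if weights is not None:
            g = g * weights
        np.add.at(F, idx[:, 0], -g[:, None] * d)
    return e


_EVAL: dict[str, Callable] = {
    "bond": _eval_bond,
    "angle": _eval_angle,
    "dihedral": _eval_dihedral,
    "morse": _eval_morse,
    "lj": _eval_lj,
    "tether": _eval_tether,
    "hbond-morse": _eval_morse,
}


# ---------------------------------------------------------------------------
# Compilation
# ---------------------------------------------------------------------------

class _Group:
    """All single-well terms of one kind, as flat arrays."""

    __slots__ = ("kind", "idx", "P", "block_codes")

    def __init__(self, kind, terms):
        self.kind = kind
        self.idx = np.array([t.centers for t in terms], dtype=np.intp)
        self.P = _pack_params(kind, terms)
        self.block_codes = np.array(
            [BLOCKS.index(t.block) if t.block in BLOCKS else 0 for t in terms],
            dtype=np.intp,
        )

    def evaluate(self, coords, F=None):
        return _EVAL[self.kind](coords, self.idx, self.P, weights=None, F=F)


class _DWGroup:
    """All double-well terms with parents of one kind."""

    __slots__ = ("kind", "idx", "PA", "PB", "delta", "eps", "block_codes")

    def __init__(self, kind, dw_terms):
        self.kind = kind
        self.idx = np.array([t.parent_a.centers for t in dw_terms], dtype=np.intp)
        self.PA = _pack_params(kind, [t.parent_a for t in dw_terms])
        self.PB = _pack_params(kind, [t.parent_b for t in dw_terms])
        self.delta = np.array([t.delta for t in dw_terms], dtype=float)
        self.eps = np.array([t.epsilon for t in dw_terms], dtype=float)
        self.block_codes = np.array(
            [BLOCKS.index(t.parent_a.block) if t.parent_a.block in BLOCKS else 0
             for t in dw_terms],
            dtype=np.intp,
        )

    def evaluate(self, coords, F=None):
        fn = _EVAL[self.kind]
        eA = fn(coords, self.idx, self.PA)
        eB = fn(coords, self.idx, self.PB)
        b = eB - self.delta
        d = eA - b
        s = np.sqrt(d * d + self.eps * self.eps)
        e = 0.5 * (eA + b - s)
        if F is not None:
            wA = 0.5 * (1.0 - d / s)
            wB = 0.5 * (1.0 + d / s)
            fn(coords, self.idx, self.PA, weights=wA, F=F)
            fn(coords, self.idx, self.PB, weights=wB, F=F)
        return e


def _pack_params(kind, terms):
    P = {}
    for key in _PARAM_KEYS[kind]:
        P[key] = np.array([float(t.params[key]) for t in terms])
    if kind in PAIR_KINDS:
        n = len(terms)
        P["r_on"] = np.array([float(t.params.get("r_on", np.inf)) for t in terms])
        P["r_off"] = np.array([float(t.params.get("r_off", np.inf)) for t in terms])
        if not np.isfinite(P["r_off"]).any():
            P.pop("r_on")
            P.pop("r_off")
    if kind == "tether":
        P["anchor"] = np.array([list(map(float, t.params["anchor"])) for t in terms])
    return P


@dataclass
class EnergyBreakdown:
    """Total potential energy with its three-block and per-kind decompositions."""

    total: float
    by_block: dict[str, float]
    by_kind: dict[str, float]


class TermSet:
    """An ordered collection of interaction terms (single- or double-well).

    The set compiles itself lazily into vectorised per-kind groups; any
    mutation invalidates the cache.  Terms may be plain
    :class:`InteractionTerm` or duck-typed double-well terms carrying
    ``parent_a``/``parent_b``/``delta``/``epsilon``.
    """

    def __init__(self, terms: Iterable = ()):  # noqa: D401
        self.terms: list = list(terms)
        self._compiled = None
        self._check_no_duplicate_bonded()

    def _check_no_duplicate_bonded(self):
        seen = set()
        for t in self.terms:
            base = t.parent_a if _is_double_well(t) else t
            if base.kind in ("bond", "angle", "dihedral"):
                key = (base.kind, base.centers)
                if key in seen:
                    raise UsageError(f"duplicate bonded term {key}")
                seen.add(key)

    def add(self, term) -> None:
        self.terms.append(term)
        self._compiled = None

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms)

    def subset(self, predicate) -> "TermSet":
        """New TermSet with the terms for which ``predicate(term)`` is true."""
        return TermSet([t for t in self.terms if predicate(t)])

    def bonded_and_local(self) -> "TermSet":
        def keep(t):
            base = t.parent_a if _is_double_well(t) else t
            if base.kind in ("bond", "angle", "dihedral", "tether"):
                return True
            return base.locality == "local" or base.kind == "hbond-morse"

        return self.subset(keep)

    def n_double_well(self) -> int:
        return sum(1 for t in self.terms if _is_double_well(t))

    def compiled(self):
        if self._compiled is None:
            singles: dict[str, list] = {}
            dws: dict[str, list] = {}
            for t in self.terms:
                if _is_double_well(t):
                    dws.setdefault(t.parent_a.kind, []).append(t)
                else:
                    singles.setdefault(t.kind, []).append(t)
            groups = [_Group(k, ts) for k, ts in singles.items()]
            groups += [_DWGroup(k, ts) for k, ts in dws.items()]
            self._compiled = groups
        return self._compiled

    # -- serialization ------------------------------------------------------

    def to_text(self) -> str:
        """Plain-text force-field file: one term per line.

        Units: kcal·mol⁻¹, Å; angle equilibria in radians.
        """
        lines = [
            "# rhodosim force field v1",
            "# units: kcal/mol, Angstrom, radian",
        ]
        for t in self.terms:
            if _is_double_well(t):
                a, b = t.parent_a, t.parent_b
                parts = ["dw", a.kind, " ".join(map(str, a.centers))]
                parts.append(f"delta={t.delta:.10g}")
                parts.append(f"eps={t.epsilon:.10g}")
                parts.append(_fmt_params(a, prefix="A."))
                parts.append(_fmt_params(b, prefix="B."))
                parts.append(f"block={a.block or '-'}")
                parts.append(f"locality={a.locality or '-'}")
            else:
                parts = [t.kind, " ".join(map(str, t.centers))]
                parts.append(_fmt_params(t))
                parts.append(f"block={t.block or '-'}")
                parts.append(f"locality={t.locality or '-'}")
            lines.append(" ".join(p for p in parts if p))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "TermSet":
        from .multistable import DoubleWellTerm  # local import: avoids a cycle

        terms = []
        for line_no, raw in enumerate(text.splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            try:
                if tokens[0] == "dw":
                    kind = tokens[1]
                    arity = _ARITY[kind]
                    centers = tuple(int(x) for x in tokens[2:2 + arity])
                    kv = _parse_kv(tokens[2 + arity:])
                    block = kv.pop("block", "-")
                    block = "" if block == "-" else block
                    locality = kv.pop("locality", "-")
                    locality = "" if locality == "-" else locality
                    delta = float(kv.pop("delta"))
                    eps = float(kv.pop("eps"))
                    pa = {k[2:]: _coerce(v) for k, v in kv.items() if k.startswith("A.")}
                    pb = {k[2:]: _coerce(v) for k, v in kv.items() if k.startswith("B.")}
                    terms.append(
                        DoubleWellTerm(
                            parent_a=InteractionTerm(kind, centers, pa, block, locality),
                            parent_b=InteractionTerm(kind, centers, pb, block, locality),
                            delta=delta,
                            epsilon=eps,
                        )
                    )
                else:
                    kind = tokens[0]
                    arity = _ARITY[kind]
                    centers = tuple(int(x) for x in tokens[1:1 + arity])
                    kv = _parse_kv(tokens[1 + arity:])
                    block = kv.pop("block", "-")
                    block = "" if block == "-" else block
                    locality = kv.pop("locality", "-")
                    locality = "" if locality == "-" else locality
                    params = {k: _coerce(v) for k, v in kv.items()}
                    terms.append(InteractionTerm(kind, centers, params, block, locality))
            except (KeyError, ValueError, IndexError) as exc:
                raise ParseError(f"force-field line {line_no}: {exc}") from None
        return cls(terms)


def _fmt_params(t: InteractionTerm, prefix: str = "") -> str:
    out = []
    for k, v in t.params.items():
        if k == "anchor":
            out.append(f"{prefix}anchor={','.join(f'{x:.10g}' for x in v)}")
        elif np.isfinite(float(v)):
            out.append(f"{prefix}{k}={float(v):.10g}")
    return " ".join(out)


def _parse_kv(tokens: Sequence[str]) -> dict:
    kv = {}
    for tok in tokens:
        k, _, v = tok.partition("=")
        kv[k] = v
    return kv


def _coerce(v: str):
    if "," in v:
        return tuple(float(x) for x in v.split(","))
    return float(v)


# ---------------------------------------------------------------------------
# Public evaluation API
# ---------------------------------------------------------------------------

def term_energy(term, coords: np.ndarray) -> float:
    """Energy (kcal·mol⁻¹) of a single term at the given frame."""
    coords = np.asarray(coords, dtype=float)
    return float(TermSet([term]).compiled()[0].evaluate(coords).sum())


def total_energy(ts: TermSet, coords: np.ndarray) -> EnergyBreakdown:
    """Total potential energy and its block/kind decomposition."""
    coords = np.asarray(coords, dtype=float)
    by_block = {b: 0.0 for b in BLOCKS}
    by_kind: dict[str, float] = {}
    total = 0.0
    for g in ts.compiled():
        e = g.evaluate(coords)
        total += float(e.sum())
        by_kind[g.kind] = by_kind.get(g.kind, 0.0) + float(e.sum())
        for code in range(3):
            sel = g.block_codes == code
            if sel.any():
                by_block[BLOCKS[code]] += float(e[sel].sum())
    return EnergyBreakdown(total=total, by_block=by_block, by_kind=by_kind)


def forces(ts: TermSet, coords: np.ndarray) -> np.ndarray:
    """Analytic forces −∇U (kcal·mol⁻¹·Å⁻¹), shape (N, 3)."""
    return energy_and_forces(ts, coords)[1]


def energy_and_forces(ts: TermSet, coords: np.ndarray) -> tuple[float, np.ndarray]:
    """(total energy, forces) in one pass — the hot path for dynamics."""
    coords = np.asarray(coords, dtype=float)
    F = np.zeros_like(coords)
    total = 0.0
    for g in ts.compiled():
        total += float(g.evaluate(coords, F=F).sum())
    return total, F
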