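"""Double-well (multi-stable) force fields connecting two reference states.

A transition A→B of the photocycle is modelled by replacing, for every
single interaction u(x) that changes appreciably between the two state
parameterizations, the pair of homologous parent terms u_A(x), u_B(x)
with the smoothed-minimum interpolation

    E(x) = ( a + b − √((a − b)² + ε²) ) / 2,
    a = u_A(x),  b = u_B(x) − δ.

ε is a small smoothing energy whose only role is to round the cusp where
the two wells cross; δ shifts the B well and thereby sets the relative
stability of the two states.  δ is not a free parameter: it is assigned
from the experimentally known free-energy difference of the transition,
distributed uniformly over the selected terms so that the minimized
end-state energies of the combined force field differ by ΔG_AB = G_B −
G_A.  No parameter controls the barrier height — barriers are emergent.

Terms whose variation between the states is negligible (below per-kind
thresholds) pass through unchanged from state A.  For a chain of states
the bistable force fields are built pairwise and applied
segment-by-segment, never as a single many-well surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UsageError
from .forcefield import InteractionTerm, TermSet, term_energy

__all__ = [
    "DoubleWellTerm",
    "DEFAULT_CHANGE_THRESHOLDS",
    "double_well_energy",
    "select_changing_terms",
    "assign_delta",
    "build_bistable_ff",
]

#: Minimum equilibrium-parameter change for a term to become double-well:
#: bonds/pair minima in Å, angles/dihedrals in radians.
DEFAULT_CHANGE_THRESHOLDS = {
    "bond": 0.2,
    "angle": np.deg2rad(10.0),
    "dihedral": np.deg2rad(20.0),
    "morse": 1.0,
    "hbond-morse": 1.0,
    "lj": np.inf,  # generic non-local terms carry no reference bias
    "tether": np.inf,
}

#: Which parameter encodes a term's equilibrium geometry.
_EQUILIBRIUM_KEY = {
    "bond": "r0",
    "angle": "theta0",
    "dihedral": "phi0",
    "morse": "rmin",
    "hbond-morse": "rmin",
}

_PERIODIC_KEYS = {"phi0"}


@dataclass(frozen=True)
class DoubleWellTerm:
    """Smoothed-minimum combination of two parent terms on one center tuple."""

    parent_a: InteractionTerm
    parent_b: InteractionTerm
    delta: float  # kcal/mol, shift of the B well
    epsilon: float  # kcal/mol, cusp smoothing (> 0)

    def __post_init__(self):
        if self.parent_a.kind != self.parent_b.kind:
            raise UsageError("double-well parents must have the same kind")
        if self.parent_a.centers != self.parent_b.centers:
            raise UsageError("double-well parents must act on the same centers")
        if not self.epsilon > 0:
            raise UsageError("epsilon must be positive")

    @property
    def kind(self) -> str:
        return self.parent_a.kind

    @property
    def centers(self) -> tuple[int, ...]:
        return self.parent_a.centers


def double_well_energy(t: DoubleWellTerm, coords: np.ndarray) -> float:
    """Energy of one double-well term at a frame (kcal·mol⁻¹)."""
    a = term_energy(t.parent_a, coords)
    b = term_energy(t.parent_b, coords) - t.delta
    return 0.5 * (a + b - np.sqrt((a - b) ** 2 + t.epsilon**2))


def _param_change(ta: InteractionTerm, tb: InteractionTerm) -> float:
    key = _EQUILIBRIUM_KEY.get(ta.kind)
    if key is None:
        return 0.0
    da = float(ta.params[key])
    db = float(tb.params[key])
    if key in _PERIODIC_KEYS:
        return abs(float(np.angle(np.exp(1j * (da - db)))))
    return abs(da - db)


def select_changing_terms(
    ts_A: TermSet,
    ts_B: TermSet,
    thresholds: dict[str, float] | None = None,
) -> list[tuple[InteractionTerm, InteractionTerm]]:
    """Pairs of homologous terms whose equilibrium parameter differs most.

    Both TermSets must be built on the same topology (the same ordered
    center tuples per kind).  Terms present in only one state are also
    selected (paired with ``None``).  Everything else is left to pass
    through as a single-well term of state A.
    """
    thresholds = {**DEFAULT_CHANGE_THRESHOLDS, **(thresholds or {})}

    def key_of(t):
        return (t.kind, t.centers)

    map_A = {key_of(t): t for t in ts_A if not isinstance(t, DoubleWellTerm)}
    map_B = {key_of(t): t for t in ts_B if not isinstance(t, DoubleWellTerm)}
    bonded_keys_A = {k for k in map_A if k[0] in ("bond", "angle", "dihedral")}
    bonded_keys_B = {k for k in map_B if k[0] in ("bond", "angle", "dihedral")}
    if bonded_keys_A != bonded_keys_B:
        raise UsageError(
            "TermSets are not built on the same bonded topology; "
            f"{len(bonded_keys_A ^ bonded_keys_B)} unmatched bonded terms"
        )

    selected: list[tuple[InteractionTerm, InteractionTerm]] = []
    for key, ta in map_A.items():
        tb = map_B.get(key)
        if tb is None:
            selected.append((ta, None))
            continue
        thr = thresholds.get(ta.kind, np.inf)
        if _param_change(ta, tb) > thr:
            selected.append((ta, tb))
    for key, tb in map_B.items():
        if key not in map_A:
            selected.append((None, tb))
    return selected


def assign_delta(selected_count: int, deltaG_AB: float) -> float:
    """Per-term well shift δ realizing an end-state free-energy difference.

    ``deltaG_AB = G_B − G_A`` (kcal·mol⁻¹).  The interpolation uses
    b = u_B − δ, whose minimum sits at −δ relative to the A minimum, so
    each of the *n* selected terms receives δ = −ΔG_AB/n and the summed
    offset makes the minimized B end state sit at ΔG_AB above (or below)
    the A end state.
    """
    if selected_count < 1:
        raise UsageError("assign_delta requires at least one selected term")
    return -float(deltaG_AB) / selected_count


def build_bistable_ff(
    ts_A: TermSet,
    ts_B: TermSet,
    deltaG_AB: float = 0.0,
    epsilon: float = 0.5,
    thresholds: dict[str, float] | None = None,
) -> TermSet:
    """Combine two single-state TermSets into one bistable force field.

    Selected changing pairs become :class:`DoubleWellTerm`s with δ from
    :func:`assign_delta` and the given ε; all other terms are copied
    from state A.  A term present in only one state is paired with a
    flat-bottomed zero-stiffness copy of itself so the interpolation
    machinery applies uniformly.
    """
    if not epsilon > 0:
        raise UsageError("epsilon must be positive")
    selected = select_changing_terms(ts_A, ts_B, thresholds)
    if not selected:
        return TermSet([t for t in ts_A])
    delta = assign_delta(len(selected), deltaG_AB)

    def flat_copy(t: InteractionTerm) -> InteractionTerm:
        params = dict(t.params)
        for key in ("k", "D", "eps"):
            if key in params:
                params[key] = 0.0
        return InteractionTerm(t.kind, t.centers, params, t.block, t.locality)

    selected_keys = set()
    dw_terms = []
    for ta, tb in selected:
        if ta is None:
            ta = flat_copy(tb)
        if tb is None:
            tb = flat_copy(ta)
        selected_keys.add((ta.kind, ta.centers))
        dw_terms.append(DoubleWellTerm(ta, tb, delta=delta, epsilon=epsilon))

    out = []
    for t in ts_A:
        if isinstance(t, DoubleWellTerm):
            continue
        if (t.kind, t.centers) in selected_keys:
            continue
        out.append(t)
    # B-only terms were flat in A: nothing to drop for them.
    out.extend(dw_terms)
    return TermSet(out)
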