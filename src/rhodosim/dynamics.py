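"""Integration of the equations of motion and the photocycle protocols.

The integrator is velocity Verlet with a 1 fs default timestep; the
canonical ensemble is sampled with the Berendsen weak-coupling
thermostat, λ = √(1 + (dt/τ)(T_target/T_inst − 1)), applied every step
(τ = 1 fs strongly couples the ground-state runs; τ = 50 fs is used for
the other states).  Systems are equilibrated by annealing: a
minimization followed by staged heating at 10, 20, 50, 100, 200 and
300 K.

The photocycle is driven segment-by-segment: equilibrium segments run a
single-state force field; transition segments run the pairwise bistable
force field of the two states involved.  The photo-triggered first
transition is special — it proceeds from an electronically excited,
barrier-less configuration — and is modelled by directly swapping in the
product-state force field on the thermalized reactant.  Transitions over
barriers too high for spontaneous (coarse-graining-accelerated)
crossing are steered: a moving harmonic restraint on the projection of
the coordinates onto a linear reaction path drags the system until the
product well is reached.

Per-segment potential-energy traces are aligned pairwise by evaluating
both force fields on the shared splice frame, as absolute energies of
different force fields are not comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize

from .errors import IntegrationError, UsageError
from .forcefield import TermSet, energy_and_forces, term_energy
from .structure_io import Trajectory
from .units import KB_KCAL_MOL_K, KCAL_MOL_TO_INTERNAL, INTERNAL_TO_KCAL_MOL

__all__ = [
    "SimulationState",
    "SteerSpec",
    "Segment",
    "PhotocycleResult",
    "maxwell_boltzmann_velocities",
    "instantaneous_temperature",
    "verlet_step",
    "berendsen_rescale",
    "minimize",
    "run_md",
    "anneal",
    "DEFAULT_ANNEAL_TEMPS",
    "run_photocycle",
    "steer_along_path",
]

DEFAULT_ANNEAL_TEMPS = (10.0, 20.0, 50.0, 100.0, 200.0, 300.0)


@dataclass
class SimulationState:
    """Coordinates, velocities, masses and the RNG of one simulation."""

    coords: np.ndarray  # (N, 3) Å
    velocities: np.ndarray  # (N, 3) Å/fs
    masses: np.ndarray  # (N,) amu
    time_fs: float = 0.0
    rng: np.random.Generator = field(default_factory=lambda: np.random.default_rng(0))

    def __post_init__(self):
        self.coords = np.array(self.coords, dtype=float)
        self.velocities = np.array(self.velocities, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.coords.shape != self.velocities.shape or self.coords.shape[0] != len(
            self.masses
        ):
            raise UsageError("incongruent state array shapes")
        if np.any(self.masses <= 0):
            raise UsageError("masses must be positive")

    @classmethod
    def from_model(cls, model, T_K: float = 0.0, seed: int = 0) -> "SimulationState":
        rng = np.random.default_rng(seed)
        state = cls(
            coords=model.reference_coords.copy(),
            velocities=np.zeros_like(model.reference_coords),
            masses=model.masses,
            rng=rng,
        )
        if T_K > 0:
            state.velocities = maxwell_boltzmann_velocities(state.masses, T_K, rng)
        return state

    def copy(self) -> "SimulationState":
        return SimulationState(
            coords=self.coords.copy(),
            velocities=self.velocities.copy(),
            masses=self.masses.copy(),
            time_fs=self.time_fs,
            rng=self.rng,
        )

    def kinetic_energy(self) -> float:
        """Kinetic energy in kcal·mol⁻¹."""
        ke_internal = 0.5 * np.sum(self.masses[:, None] * self.velocities**2)
        return float(ke_internal * INTERNAL_TO_KCAL_MOL)

    def temperature(self) -> float:
        return instantaneous_temperature(self)


def maxwell_boltzmann_velocities(
    masses: np.ndarray, T_K: float, rng: np.random.Generator
) -> np.ndarray:
    """Velocities (Å/fs) drawn from the Maxwell–Boltzmann distribution."""
    kT = KB_KCAL_MOL_K * T_K * KCAL_MOL_TO_INTERNAL  # amu·Å²/fs²
    sigma = np.sqrt(kT / np.asarray(masses, dtype=float))
    return rng.normal(size=(len(masses), 3)) * sigma[:, None]


def instantaneous_temperature(state: SimulationState) -> float:
    """Equipartition temperature over 3N degrees of freedom (K)."""
    n_dof = 3 * len(state.masses)
    return 2.0 * state.kinetic_energy() / (n_dof * KB_KCAL_MOL_K)


def _accelerations(F: np.ndarray, masses: np.ndarray) -> np.ndarray:
    return F * KCAL_MOL_TO_INTERNAL / masses[:, None]


def verlet_step(
    state: SimulationState, ts: TermSet, dt_fs: float = 1.0
) -> SimulationState:
    """One velocity-Verlet step; returns the advanced state."""
    new = state.copy()
    _, F = energy_and_forces(ts, new.coords)
    if not np.isfinite(F).all():
        raise IntegrationError("non-finite force before step")
    new.velocities += 0.5 * dt_fs * _accelerations(F, new.masses)
    new.coords += dt_fs * new.velocities
    _, F = energy_and_forces(ts, new.coords)
    if not np.isfinite(F).all():
        raise IntegrationError("non-finite force after position update")
    new.velocities += 0.5 * dt_fs * _accelerations(F, new.masses)
    new.time_fs += dt_fs
    return new


def berendsen_rescale(
    state: SimulationState, T_target_K: float, tau_fs: float, dt_fs: float
) -> SimulationState:
    """Berendsen velocity rescaling toward the target temperature."""
    new = state.copy()
    T_inst = instantaneous_temperature(new)
    if T_inst <= 0.0:
        if T_target_K > 0.0:
            # documented behaviour: reseed from Maxwell-Boltzmann
            new.velocities = maxwell_boltzmann_velocities(
                new.masses, T_target_K, new.rng
            )
        return new
    lam = np.sqrt(1.0 + (dt_fs / tau_fs) * (T_target_K / T_inst - 1.0))
    new.velocities *= lam
    return new


# ---------------------------------------------------------------------------
# Minimization
# ---------------------------------------------------------------------------

def minimize(
    ts: TermSet,
    coords: np.ndarray,
    force_tol: float = 1e-4,
    max_iter: int = 2000,
) -> np.ndarray:
    """Relax coordinates to a local minimum (L-BFGS, analytic gradient)."""
    shape = np.asarray(coords).shape

    def fun(x):
        e, F = energy_and_forces(ts, x.reshape(shape))
        return e, -F.ravel()

    res = scipy.optimize.minimize(
        fun,
        np.asarray(coords, dtype=float).ravel(),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": force_tol, "ftol": 1e-12},
    )
    return res.x.reshape(shape)


# ---------------------------------------------------------------------------
# Molecular dynamics driver
# ---------------------------------------------------------------------------

@dataclass
class SteerSpec:
    """Moving harmonic restraint along a linear Cartesian reaction path.

    Two operationalizations of the pull are available:

    * ``mode="projection"`` restrains the scalar reaction coordinate
      s = (x − x_A)·(x_B − x_A)/|x_B − x_A|² over the selected centers
      with ½·k·(s − s_target)².  Cheap and appropriate when the path is
      essentially one collective degree of freedom.
    * ``mode="targeted"`` restrains the full selected displacement to
      the interpolated path point, ½·k·|x − ((1−s_t)·x_A + s_t·x_B)|²/L².
      This is the targeted-dynamics form; it is robust against soft-mode
      escape, where unrestrained directions satisfy the projection while
      the intended internal coordinate (e.g. a dihedral) never moves.

    The target s advances by ``rate`` per fs until it reaches 1.
    """

    start_coords: np.ndarray
    end_coords: np.ndarray
    k_steer: float  # kcal/mol per unit s²
    rate: float  # s units per fs
    selected: np.ndarray | None = None  # center indices; None = all
    mode: str = "projection"

    def __post_init__(self):
        self.start_coords = np.asarray(self.start_coords, dtype=float)
        self.end_coords = np.asarray(self.end_coords, dtype=float)
        if self.start_coords.shape != self.end_coords.shape:
            raise UsageError("steering path endpoints must be congruent")
        if self.rate <= 0:
            raise UsageError("steering rate must be positive")
        if self.mode not in ("projection", "targeted"):
            raise UsageError(f"unknown steering mode {self.mode!r}")


class _Steerer:
    def __init__(self, spec: SteerSpec, n_centers: int):
        self.spec = spec
        sel = (
            np.arange(n_centers)
            if spec.selected is None
            else np.asarray(spec.selected, dtype=np.intp)
        )
        self.sel = sel
        self.A = spec.start_coords[sel].ravel()
        self.B = spec.end_coords[sel].ravel()
        d = self.B - self.A
        L2 = float(d @ d)
        if L2 < 1e-12:
            raise UsageError("steering path has zero length")
        self.L2 = L2
        self.u_over_L2 = d / L2

    def s_of(self, coords) -> float:
        return float((coords[self.sel].ravel() - self.A) @ self.u_over_L2)

    def apply(self, coords, F, t_fs) -> tuple[float, float, float]:
        """Add restraint force in place; return (s, s_target, restraint energy)."""
        s = self.s_of(coords)
        s_target = min(1.0, self.spec.rate * t_fs)
        k = self.spec.k_steer
        if self.spec.mode == "projection":
            e = 0.5 * k * (s - s_target) ** 2
            if k != 0.0:
                g = -k * (s - s_target)
                F[self.sel] += (g * self.u_over_L2).reshape(-1, 3)
        else:  # targeted
            path = (1.0 - s_target) * self.A + s_target * self.B
            dev = coords[self.sel].ravel() - path
            e = 0.5 * k * float(dev @ dev) / self.L2
            if k != 0.0:
                F[self.sel] += (-(k / self.L2) * dev).reshape(-1, 3)
        return s, s_target, e


def _dw_b_departure(ts: TermSet, coords: np.ndarray) -> float:
    """Max over double-well terms of u_B(x) above its own minimum (kcal/mol)."""
    worst = 0.0
    found = False
    for t in ts:
        if not hasattr(t, "parent_b"):
            continue
        found = True
        b = t.parent_b
        e = term_energy(b, coords)
        floor = -float(b.params["D"]) if b.kind in ("morse", "hbond-morse") else 0.0
        worst = max(worst, e - floor)
    return worst if found else np.inf


def run_md(
    state: SimulationState,
    ts: TermSet,
    n_steps: int,
    dt_fs: float = 1.0,
    T_target_K: float | None = None,
    tau_fs: float = 50.0,
    stride: int = 10,
    steer: SteerSpec | None = None,
    stop_on_arrival: bool = False,
    arrival_tol_kcal: float | None = None,
    check_every: int = 100,
) -> tuple[SimulationState, Trajectory, pd.DataFrame]:
    """Run NVE/NVT dynamics (optionally steered) and log energies.

    Returns (final state, trajectory sampled every ``stride`` steps
    including the initial frame, energy table).  With ``T_target_K``
    None the run is microcanonical.  ``stop_on_arrival`` ends a steered
    run once every double-well term sits in its B-parent well (within
    ``arrival_tol_kcal``, default max(ε-scale 0.5, k_B·T)).
    """
    if n_steps < 0:
        raise UsageError("n_steps must be non-negative")
    st = state.copy()
    masses = st.masses
    x = st.coords
    v = st.velocities

    steerer = _Steerer(steer, len(masses)) if steer is not None else None
    if arrival_tol_kcal is None:
        T_for_tol = T_target_K if T_target_K else 300.0
        arrival_tol_kcal = max(0.5, KB_KCAL_MOL_K * T_for_tol)

    def eval_forces(t_fs):
        e, F = energy_and_forces(ts, x)
        extra = {}
        if steerer is not None:
            s, s_t, e_r = steerer.apply(x, F, t_fs)
            e += e_r
            extra = {"s": s, "s_target": s_t, "restraint": e_r}
        return e, F, extra

    frames = [x.copy()]
    temps = [instantaneous_temperature(st)]
    rows = []
    e, F, extra = eval_forces(0.0)
    if not np.isfinite(F).all():
        raise IntegrationError("non-finite initial force")
    rows.append(
        {"step": 0, "time_fs": st.time_fs, "potential": e,
         "kinetic": st.kinetic_energy(), "temperature": temps[0], **extra}
    )
    conv = KCAL_MOL_TO_INTERNAL / masses[:, None]
    t_local = 0.0
    for step in range(1, n_steps + 1):
        v += (0.5 * dt_fs) * F * conv
        x += dt_fs * v
        t_local += dt_fs
        e, F, extra = eval_forces(t_local)
        v += (0.5 * dt_fs) * F * conv
        if not np.isfinite(x).all():
            raise IntegrationError(f"non-finite coordinates at step {step}")
        if T_target_K is not None:
            ke_int = 0.5 * np.sum(masses[:, None] * v * v)
            T_inst = 2.0 * ke_int * INTERNAL_TO_KCAL_MOL / (3 * len(masses) * KB_KCAL_MOL_K)
            if T_inst <= 0.0:
                if T_target_K > 0.0:
                    v[:] = maxwell_boltzmann_velocities(masses, T_target_K, st.rng)
            else:
                v *= np.sqrt(1.0 + (dt_fs / tau_fs) * (T_target_K / T_inst - 1.0))
        if step % stride == 0 or step == n_steps:
            st.velocities = v
            ke = st.kinetic_energy()
            T_now = instantaneous_temperature(st)
            frames.append(x.copy())
            temps.append(T_now)
            rows.append(
                {"step": step, "time_fs": st.time_fs + t_local, "potential": e,
                 "kinetic": ke, "temperature": T_now, **extra}
            )
            if (
                stop_on_arrival
                and steerer is not None
                and extra.get("s_target", 0.0) >= 1.0
                and step % check_every < stride
                and _dw_b_departure(ts, x) <= arrival_tol_kcal
            ):
                break
    st.coords = x
    st.velocities = v
    st.time_fs += t_local
    traj = Trajectory(
        frames=np.array(frames),
        dt_fs=dt_fs * stride,
        temperatures_K=np.array(temps),
    )
    return st, traj, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Annealing
# ---------------------------------------------------------------------------

def anneal(
    state: SimulationState,
    ts: TermSet,
    schedule: list[tuple[float, float]] | None = None,
    dt_fs: float = 1.0,
    tau_fs: float = 1.0,
    stride: int = 50,
    minimize_first: bool = True,
    force_tol: float = 1e-4,
) -> tuple[SimulationState, Trajectory, pd.DataFrame]:
    """Minimize, then heat in stages (default 10→300 K, 1 ps per leg).

    ``schedule`` is a list of (temperature K, duration fs) legs; the
    default mirrors the staged-heating protocol at desk-scale leg
    lengths.
    """
    if schedule is None:
        schedule = [(T, 1000.0) for T in DEFAULT_ANNEAL_TEMPS]
    if not schedule:
        raise UsageError("annealing schedule must be non-empty")
    st = state.copy()
    if minimize_first:
        st.coords = minimize(ts, st.coords, force_tol=force_tol)
        st.velocities[:] = 0.0
    all_frames = []
    all_temps = []
    tables = []
    for leg, (T, dur) in enumerate(schedule):
        n_steps = max(1, int(round(dur / dt_fs)))
        if T > 0 and st.temperature() <= 0:
            st.velocities = maxwell_boltzmann_velocities(st.masses, T, st.rng)
        st, traj, table = run_md(
            st, ts, n_steps=n_steps, dt_fs=dt_fs, T_target_K=T,
            tau_fs=tau_fs, stride=stride,
        )
        table["leg"] = leg
        table["T_leg"] = T
        tables.append(table)
        first = 1 if all_frames else 0
        all_frames.append(traj.frames[first:])
        all_temps.append(traj.temperatures_K[first:])
    traj = Trajectory(
        frames=np.concatenate(all_frames),
        dt_fs=dt_fs * stride,
        temperatures_K=np.concatenate(all_temps),
    )
    return st, traj, pd.concat(tables, ignore_index=True)


# ---------------------------------------------------------------------------
# Photocycle
# ---------------------------------------------------------------------------

@dataclass
class Segment:
    """One photocycle segment: a force field run for a number of steps.

    ``kind`` is "state" (single-state FF) or "transition" (bistable FF);
    a photo-triggered swap is simply a "state" segment whose FF is the
    product state's, started from the thermalized reactant.
    """

    ts: TermSet
    n_steps: int
    label: str = ""
    kind: str = "state"
    T_K: float = 300.0
    tau_fs: float = 50.0
    steer: SteerSpec | None = None


@dataclass
class PhotocycleResult:
    trajectory: Trajectory
    energies: pd.DataFrame  # per-log-point, with aligned potential energies
    segment_table: pd.DataFrame  # per-segment means and alignment offsets
    final_state: SimulationState


def run_photocycle(
    segments: list[Segment],
    initial_state: SimulationState,
    dt_fs: float = 1.0,
    stride: int = 10,
) -> PhotocycleResult:
    """Run an ordered list of state/transition segments.

    Consecutive segments share the splice frame; potential-energy traces
    are aligned pairwise by evaluating both force fields on that shared
    frame and offsetting the later segment so the aligned trace is
    continuous at every splice.
    """
    if not segments:
        raise UsageError("photocycle needs at least one segment")
    for seg in segments:
        if seg.n_steps <= 0:
            raise UsageError("segment durations must be positive")
    st = initial_state.copy()
    offset = 0.0
    prev_ts = None
    frames = []
    temps = []
    rows = []
    seg_rows = []
    for i, seg in enumerate(segments):
        if prev_ts is not None:
            from .forcefield import total_energy

            e_prev = total_energy(prev_ts, st.coords).total
            e_next = total_energy(seg.ts, st.coords).total
            offset = offset + e_prev - e_next
        st, traj, table = run_md(
            st,
            seg.ts,
            n_steps=seg.n_steps,
            dt_fs=dt_fs,
            T_target_K=seg.T_K,
            tau_fs=seg.tau_fs,
            stride=stride,
            steer=seg.steer,
            stop_on_arrival=seg.steer is not None,
        )
        table["segment"] = i
        table["label"] = seg.label or f"seg{i}"
        table["kind"] = seg.kind
        table["potential_aligned"] = table["potential"] + offset
        rows.append(table)
        seg_rows.append(
            {
                "segment": i,
                "label": seg.label or f"seg{i}",
                "kind": seg.kind,
                "offset": offset,
                "mean_potential_aligned": float(table["potential_aligned"].mean()),
                "mean_temperature": float(table["temperature"].mean()),
            }
        )
        first = 1 if frames else 0
        frames.append(traj.frames[first:])
        temps.append(traj.temperatures_K[first:])
        prev_ts = seg.ts
    traj = Trajectory(
        frames=np.concatenate(frames),
        dt_fs=dt_fs * stride,
        temperatures_K=np.concatenate(temps),
    )
    return PhotocycleResult(
        trajectory=traj,
        energies=pd.concat(rows, ignore_index=True),
        segment_table=pd.DataFrame(seg_rows),
        final_state=st,
    )


def steer_along_path(
    state: SimulationState,
    ts_bistable: TermSet,
    path: tuple[np.ndarray, np.ndarray],
    k_steer: float,
    rate: float,
    selected: np.ndarray | None = None,
    n_steps: int = 50000,
    dt_fs: float = 1.0,
    T_K: float = 300.0,
    tau_fs: float = 50.0,
    stride: int = 10,
    mode: str = "projection",
) -> tuple[SimulationState, Trajectory, pd.DataFrame]:
    """Steered run over a high barrier; see :class:`SteerSpec`.

    With ``k_steer = 0`` this reduces exactly to unrestrained dynamics.
    The energy table includes the reaction coordinate ``s`` and the
    restraint energy, i.e. the work profile of the pull.
    """
    start, end = path
    spec = SteerSpec(
        start_coords=start, end_coords=end, k_steer=k_steer, rate=rate,
        selected=selected, mode=mode,
    )
    return run_md(
        state,
        ts_bistable,
        n_steps=n_steps,
        dt_fs=dt_fs,
        T_target_K=T_K,
        tau_fs=tau_fs,
        stride=stride,
        steer=spec,
        stop_on_arrival=k_steer > 0,
    )
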