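"""Trajectory analysis: deviations, fluctuations, essential dynamics.

Standard observables of coarse-grained protein simulation:

* RMSD(t) = √(1/N Σᵢ |rᵢ(t) − rᵢ⁰|²), optionally after least-squares
  rigid-body superposition (Kabsch).
* RMSFᵢ = √(1/T Σₜ |rᵢ(t) − ⟨rᵢ⟩|²), related to the crystallographic
  temperature factor by Bᵢ = 8π²⟨Δrᵢ²⟩.
* Essential dynamics: eigen-decomposition of the 3N×3N positional
  covariance matrix σᵢⱼᵅᵝ = ⟨(rᵢᵅ−⟨rᵢᵅ⟩)(rⱼᵝ−⟨rⱼᵝ⟩)⟩; trajectories are
  projected onto the first ten eigenmodes by default.
* Free-energy landscapes by Boltzmann inversion of the 2-D histogram of
  the first two principal components, F = −k_B·T·ln(ρ/ρ_max), and
  metastable-minimum counting on the resulting grid with a
  ridge-persistence criterion.

Superposition before RMSF/PCA is optional (flag): for membrane-tethered
simulations the lab frame is physical and superposition off is also
meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EvaluationError, UsageError
from .forcefield import dihedral_angles
from .structure_io import Trajectory
from .units import KB_KCAL_MOL_K

__all__ = [
    "superpose",
    "rmsd",
    "rmsf",
    "bfactor_from_rmsf",
    "rmsf_from_bfactor",
    "dihedral",
    "pca",
    "EssentialDynamicsResult",
    "FreeEnergyLandscape",
    "free_energy_landscape",
    "count_minima",
]


# ---------------------------------------------------------------------------
# Superposition / RMSD / RMSF
# ---------------------------------------------------------------------------

def superpose(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Least-squares rigid superposition of ``mobile`` onto ``reference`` (Kabsch)."""
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    P = mobile - mc
    Q = reference - rc
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt
    return P @ R + rc


def rmsd(frame: np.ndarray, reference: np.ndarray, superpose_first: bool = False) -> float:
    """Root-mean-square deviation between two frames (Å)."""
    frame = np.asarray(frame, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if frame.shape != reference.shape:
        raise UsageError("frames must have identical shapes")
    if frame.shape[0] == 0:
        raise UsageError("cannot compute RMSD of zero centers")
    if superpose_first:
        frame = superpose(frame, reference)
    d = frame - reference
    return float(np.sqrt(np.mean(np.einsum("ij,ij->i", d, d))))


def _superposed_frames(frames: np.ndarray) -> np.ndarray:
    """Superpose all frames onto their mean (one fixed-point iteration)."""
    ref = frames.mean(axis=0)
    aligned = np.array([superpose(f, ref) for f in frames])
    ref = aligned.mean(axis=0)
    return np.array([superpose(f, ref) for f in frames])


def rmsf(traj: Trajectory, superpose: bool = True) -> np.ndarray:
    """Per-center root-mean-square fluctuation about the time-averaged position."""
    if traj.n_frames < 2:
        raise UsageError("RMSF needs at least two frames")
    frames = traj.frames
    if superpose:
        frames = _superposed_frames(frames)
    mean = frames.mean(axis=0)
    d = frames - mean
    return np.sqrt(np.mean(np.einsum("tij,tij->ti", d, d), axis=0))


def bfactor_from_rmsf(rmsf_profile: np.ndarray) -> np.ndarray:
    """Crystallographic B-factor, B = 8π²·⟨Δr²⟩ (Å²)."""
    rmsf_profile = np.asarray(rmsf_profile, dtype=float)
    if np.any(rmsf_profile < 0):
        raise UsageError("RMSF values must be non-negative")
    return 8.0 * np.pi**2 * rmsf_profile**2


def rmsf_from_bfactor(b: np.ndarray) -> np.ndarray:
    """Inverse of :func:`bfactor_from_rmsf`."""
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise UsageError("B-factors must be non-negative")
    return np.sqrt(b / (8.0 * np.pi**2))


def dihedral(frame: np.ndarray, i: int, j: int, k: int, l: int) -> float:
    """Signed dihedral in degrees, IUPAC convention (cis = 0°, trans = 180°).

    The return value lies in (−180, 180]."""
    if len({i, j, k, l}) != 4:
        raise UsageError("dihedral needs four distinct indices")
    phi = float(
        np.rad2deg(dihedral_angles(np.asarray(frame, float), np.array([[i, j, k, l]])))[0]
    )
    if phi <= -180.0:
        phi += 360.0
    return phi


# ---------------------------------------------------------------------------
# PCA / essential dynamics
# ---------------------------------------------------------------------------

@dataclass
class EssentialDynamicsResult:
    """Eigenmodes of the positional covariance and per-frame projections."""

    mean_coords: np.ndarray  # (N, 3)
    eigenvalues: np.ndarray  # (n_modes,), Å², descending
    eigenvectors: np.ndarray  # (3N, n_modes), orthonormal columns
    projections: np.ndarray  # (T, n_modes), Å
    n_modes_kept: int
    total_variance: float  # trace of the covariance (Å²)


def pca(traj: Trajectory, superpose: bool = True, n_modes: int = 10) -> EssentialDynamicsResult:
    """Essential dynamics of a trajectory.

    Covariance of the flattened coordinates about the mean, symmetric
    eigendecomposition, projections of the centered frames onto the
    leading ``n_modes`` eigenmodes (all modes if the system is smaller).
    """
    if traj.n_frames < 2:
        raise UsageError("PCA needs at least two frames")
    frames = traj.frames
    if superpose:
        frames = _superposed_frames(frames)
    T = frames.shape[0]
    X = frames.reshape(T, -1)
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = (Xc.T @ Xc) / T
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    keep = min(n_modes, X.shape[1])
    proj = Xc @ evecs[:, :keep]
    return EssentialDynamicsResult(
        mean_coords=mean.reshape(-1, 3),
        eigenvalues=evals[:keep],
        eigenvectors=evecs[:, :keep],
        projections=proj,
        n_modes_kept=keep,
        total_variance=float(np.trace(cov)),
    )


# ---------------------------------------------------------------------------
# Free-energy landscape
# ---------------------------------------------------------------------------

@dataclass
class FreeEnergyLandscape:
    """Boltzmann-inverted 2-D histogram over (PC1, PC2)."""

    edges_x: np.ndarray
    edges_y: np.ndarray
    F: np.ndarray  # kcal/mol, min-shifted to 0 over populated bins
    mask: np.ndarray  # True where the bin is empty (F undefined)
    temperature_K: float
    counts: np.ndarray | None = None  # raw histogram (incl. pseudocount)

    @property
    def centers_x(self) -> np.ndarray:
        return 0.5 * (self.edges_x[:-1] + self.edges_x[1:])

    @property
    def centers_y(self) -> np.ndarray:
        return 0.5 * (self.edges_y[:-1] + self.edges_y[1:])


def free_energy_landscape(
    projections: np.ndarray,
    T_K: float = 300.0,
    bins: int = 50,
    pseudocount: float = 0.0,
    pad_fraction: float = 0.05,
) -> FreeEnergyLandscape:
    """F(PC1, PC2) = −k_B·T·ln(ρ/ρ_max) from sampled projections.

    The grid spans the data range padded by ``pad_fraction`` on each
    side; empty bins are masked, populated bins are shifted so the
    global minimum is zero.
    """
    P = np.asarray(projections, dtype=float)
    if P.ndim != 2 or P.shape[1] < 2:
        raise UsageError("projections must be (frames, >=2 modes)")
    if P.shape[0] < 1:
        raise UsageError("no frames to histogram")
    x, y = P[:, 0], P[:, 1]

    def padded(lo, hi):
        span = hi - lo
        pad = pad_fraction * span if span > 0 else max(abs(hi), 1.0) * pad_fraction + 1e-9
        return lo - pad, hi + pad

    xr = padded(x.min(), x.max())
    yr = padded(y.min(), y.max())
    H, ex, ey = np.histogram2d(x, y, bins=bins, range=[xr, yr])
    H = H + pseudocount
    mask = H <= 0
    F = np.full_like(H, np.nan)
    with np.errstate(divide="ignore"):
        F[~mask] = -KB_KCAL_MOL_K * T_K * np.log(H[~mask] / H.max())
    return FreeEnergyLandscape(
        edges_x=ex, edges_y=ey, F=F, mask=mask, temperature_K=T_K, counts=H
    )


def count_minima(
    fel: FreeEnergyLandscape, min_depth_kcal: float = 0.5
) -> tuple[int, list[tuple[float, float]]]:
    """Count metastable minima on the landscape grid.

    Local minima (8-neighbour rule on populated bins) are retained only
    if separated from every *deeper* basin by a ridge of at least
    ``min_depth_kcal`` — a persistence criterion implemented by flooding
    bins in order of increasing F and merging shallow basins into the
    deeper basin they first touch.  Because F in a bin holding n samples
    carries a statistical error of about k_B·T/√n, each basin's required
    persistence is raised by that noise floor at its minimum bin, which
    suppresses spurious minima in the sparsely sampled fringe.
    """
    mask = fel.mask
    if mask.all():
        raise UsageError("landscape has no populated bins")
    # empty bins become passable high ground at the top of the landscape, so
    # fringe islands merge (and die) there instead of surviving in isolation
    F = fel.F.copy()
    top = float(np.nanmax(F[~mask]))
    F[mask] = top
    nx, ny = F.shape
    order = sorted(
        (F[i, j], int(mask[i, j]), i, j) for i in range(nx) for j in range(ny)
    )
    kT = KB_KCAL_MOL_K * fel.temperature_K
    if fel.counts is not None:
        noise = np.where(fel.counts > 0, kT / np.sqrt(np.clip(fel.counts, 1, None)), 0.0)
    else:
        noise = np.zeros_like(F)
    basin = -np.ones((nx, ny), dtype=int)
    basin_min: list[float] = []  # F at each basin's minimum
    basin_noise: list[float] = []  # statistical noise floor at that bin
    alive: list[bool] = []
    parent: list[int] = []

    def find(b):
        while parent[b] != b:
            parent[b] = parent[parent[b]]
            b = parent[b]
        return b

    minima_pos: list[tuple[int, int] | None] = []
    for f, is_masked, i, j in order:
        neigh = set()
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if di == dj == 0:
                    continue
                a, b = i + di, j + dj
                if 0 <= a < nx and 0 <= b < ny and basin[a, b] >= 0:
                    neigh.add(find(basin[a, b]))
        if not neigh:
            idx = len(basin_min)
            basin_min.append(f)
            basin_noise.append(float(noise[i, j]))
            alive.append(not is_masked)
            parent.append(idx)
            basin[i, j] = idx
            minima_pos.append(None if is_masked else (i, j))
            continue
        target = min(neigh, key=lambda b: basin_min[b])
        basin[i, j] = target
        for b in neigh - {target}:
            # basin b meets the deeper basin at level f: its persistence
            # is the ridge height above its own minimum, which must beat
            # the depth threshold plus the basin's own sampling noise
            if f - basin_min[b] < min_depth_kcal + basin_noise[b]:
                alive[b] = False
                minima_pos[b] = None  # merged away
            parent[b] = target

    kept = [
        (fel.centers_x[i], fel.centers_y[j])
        for b, pos in enumerate(minima_pos)
        if alive[b] and pos is not None
        for i, j in [pos]
    ]
    return len(kept), kept
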