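"""Structure and trajectory I/O.

Reference structures enter as fixed-column PDB text (``ATOM``/``HETATM``
records with ``HELIX``/``SHEET`` secondary-structure annotation and
optional ``MODEL`` blocks).  Trajectories are stored as multi-frame XYZ
text by default, with a multi-model PDB writer as an alternative.

The reader is deliberately strict and minimal: it implements exactly the
record subset the model builder consumes (coordinates from columns
31–54, first altloc wins, helix/sheet ranges), and reports parse errors
with the offending line number — behaviour the rest of the package's
contracts depend on.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ParseError, UsageError

__all__ = [
    "Atom",
    "Structure",
    "Trajectory",
    "read_pdb",
    "write_pdb",
    "write_trajectory",
    "read_trajectory",
]

_WATER_RESNAMES = {"HOH", "WAT", "H2O", "SOL", "W"}


@dataclass(frozen=True)
class Atom:
    """One ATOM/HETATM record (hydrogens are never modelled)."""

    name: str
    element: str
    residue_name: str
    residue_index: int  # 1-based, as in the source file
    chain_id: str
    xyz: tuple[float, float, float]
    hetero: bool = False

    @property
    def is_water(self) -> bool:
        return self.residue_name.upper() in _WATER_RESNAMES


@dataclass
class Structure:
    """An ordered list of atoms plus per-residue secondary structure.

    ``secondary_structure`` maps ``(chain_id, residue_index)`` to one of
    ``"H"`` (helix), ``"E"`` (strand) or ``"C"`` (coil, the default).
    """

    atoms: list[Atom]
    secondary_structure: dict[tuple[str, int], str] = field(default_factory=dict)
    source_id: str = ""

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise UsageError(
                f"coordinate array shape {coords.shape} does not match "
                f"{len(self.atoms)} atoms"
            )
        atoms = [replace(a, xyz=tuple(c)) for a, c in zip(self.atoms, coords)]
        return Structure(atoms, dict(self.secondary_structure), self.source_id)

    def residues(self) -> list[tuple[str, int, str]]:
        """Ordered unique (chain_id, residue_index, residue_name)."""
        seen: dict[tuple[str, int], str] = {}
        for a in self.atoms:
            seen.setdefault((a.chain_id, a.residue_index), a.residue_name)
        return [(c, r, n) for (c, r), n in seen.items()]

    def ss_label(self, chain_id: str, residue_index: int) -> str:
        return self.secondary_structure.get((chain_id, residue_index), "C")

    def validate(self) -> None:
        """Check the structural invariants; raise :class:`UsageError` if broken."""
        if not self.atoms:
            raise UsageError("structure has no atoms")
        if not np.isfinite(self.coords).all():
            raise UsageError("structure has non-finite coordinates")
        last: dict[str, int] = {}
        for a in self.atoms:
            prev = last.get(a.chain_id)
            if prev is not None and a.residue_index < prev:
                raise UsageError(
                    f"residue index decreases within chain {a.chain_id!r}: "
                    f"{prev} -> {a.residue_index}"
                )
            last[a.chain_id] = a.residue_index


@dataclass
class Trajectory:
    """Time-ordered coordinate frames for a fixed set of interaction centers."""

    frames: np.ndarray  # (n_frames, n_centers, 3), Å
    dt_fs: float  # femtoseconds between saved frames
    temperatures_K: np.ndarray | None = None  # optional per-frame instantaneous T
    model_ref: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[-1] != 3:
            raise UsageError(f"frames must have shape (T, N, 3), got {self.frames.shape}")
        if self.frames.shape[0] == 0:
            raise UsageError("trajectory must contain at least one frame")
        if not self.dt_fs > 0:
            raise UsageError("dt_fs must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_centers(self) -> int:
        return self.frames.shape[1]

    def times_fs(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt_fs


# ---------------------------------------------------------------------------
# PDB reading
# ---------------------------------------------------------------------------

def _parse_float(text: str, line_no: int, what: str) -> float:
    try:
        return float(text)
    except ValueError:
        raise ParseError(f"line {line_no}: unreadable {what} field {text.strip()!r}") from None


def _guess_element(atom_name: str, element_field: str) -> str:
    el = element_field.strip()
    if el:
        return el.capitalize()
    name = atom_name.strip()
    # PDB convention: element is the first letter for C/N/O/S/P-style names
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "X"


def read_pdb(text: str, model_index: int = 0, source_id: str = "") -> Structure:
    """Parse PDB text into a :class:`Structure`.

    Parameters
    ----------
    text:
        Full PDB file content.
    model_index:
        Which MODEL block to read (0-based).  Files without MODEL records
        are treated as a single model 0.

    Notes
    -----
    Coordinates come from fixed columns 31–54.  Only the first altloc of
    an atom is kept; hydrogens are dropped (the united-atom model has
    none).  HELIX/SHEET records populate the secondary-structure
    annotation (H/E); unannotated residues default to coil (C).
    """
    atoms: list[Atom] = []
    ss: dict[tuple[str, int], str] = {}
    seen_atom_keys: set[tuple[str, int, str]] = set()
    current_model = 0
    in_wanted_model = model_index == 0
    saw_any_model = False

    for line_no, raw in enumerate(text.splitlines(), start=1):
        rec = raw[:6].strip().upper()
        if rec == "MODEL":
            saw_any_model = True
            try:
                current_model = int(raw[6:].split()[0]) - 1
            except (ValueError, IndexError):
                current_model += 1
            in_wanted_model = current_model == model_index
            continue
        if rec == "ENDMDL":
            in_wanted_model = False
            continue
        if rec == "HELIX":
            chain = raw[19:20].strip() or raw[31:32].strip()
            start = int(raw[21:25])
            end = int(raw[33:37])
            for r in range(start, end + 1):
                ss[(chain, r)] = "H"
            continue
        if rec == "SHEET":
            chain = raw[21:22].strip()
            start = int(raw[22:26])
            end = int(raw[33:37])
            for r in range(start, end + 1):
                ss.setdefault((chain, r), "E")
            continue
        if rec not in ("ATOM", "HETATM"):
            continue
        if saw_any_model and not in_wanted_model:
            continue
        line = raw.ljust(80)
        name = line[12:16].strip()
        altloc = line[16]
        resname = line[17:20].strip()
        chain = line[21].strip()
        try:
            resindex = int(line[22:26])
        except ValueError:
            raise ParseError(
                f"line {line_no}: unreadable residue index {line[22:26].strip()!r}"
            ) from None
        x = _parse_float(line[30:38], line_no, "x coordinate")
        y = _parse_float(line[38:46], line_no, "y coordinate")
        z = _parse_float(line[46:54], line_no, "z coordinate")
        element = _guess_element(name, line[76:78])
        if element == "H":
            continue
        key = (chain, resindex, name)
        if altloc not in (" ", "A", "1", ""):  # first altloc wins
            continue
        if key in seen_atom_keys:
            continue
        seen_atom_keys.add(key)
        atoms.append(
            Atom(
                name=name,
                element=element,
                residue_name=resname,
                residue_index=resindex,
                chain_id=chain,
                xyz=(x, y, z),
                hetero=rec == "HETATM",
            )
        )

    if not atoms:
        raise ParseError(
            f"no ATOM/HETATM records found (model_index={model_index})"
        )
    s = Structure(atoms=atoms, secondary_structure=ss, source_id=source_id)
    s.validate()
    return s


# ---------------------------------------------------------------------------
# PDB writing
# ---------------------------------------------------------------------------

def _format_atom_line(serial: int, a: Atom) -> str:
    record = "HETATM" if a.hetero else "ATOM  "
    name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
    x, y, z = a.xyz
    return (
        f"{record}{serial:5d} {name:<4.4s} {a.residue_name:<3.3s} "
        f"{a.chain_id:1.1s}{a.residue_index:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
        f"{a.element:>2.2s}"
    )


def _helix_records(s: Structure) -> list[str]:
    # contiguous H runs per chain become HELIX records
    lines = []
    runs: list[tuple[str, int, int]] = []
    by_chain: dict[str, list[int]] = {}
    for (chain, resi), label in sorted(s.secondary_structure.items()):
        if label == "H":
            by_chain.setdefault(chain, []).append(resi)
    for chain, resis in by_chain.items():
        resis.sort()
        start = prev = resis[0]
        for r in resis[1:]:
            if r == prev + 1:
                prev = r
                continue
            runs.append((chain, start, prev))
            start = prev = r
        runs.append((chain, start, prev))
    for n, (chain, start, end) in enumerate(runs, start=1):
        lines.append(
            f"HELIX  {n:3d} {n:3d} ALA {chain:1.1s} {start:4d}  "
            f"ALA {chain:1.1s} {end:4d}  1{'':30s}{end - start + 1:5d}"
        )
    return lines


def write_pdb(s: Structure) -> str:
    """Render a :class:`Structure` as PDB text (helix annotation included)."""
    lines = _helix_records(s)
    for i, a in enumerate(s.atoms, start=1):
        lines.append(_format_atom_line(i, a))
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Trajectory I/O
# ---------------------------------------------------------------------------

def write_trajectory(traj: Trajectory, path, format: str = "xyz") -> None:
    """Write a trajectory to disk as multi-frame XYZ or multi-model PDB.

    XYZ frames carry the frame time in the comment line; coordinates are
    printed with 1e-3 Å precision (the round-trip tolerance).
    """
    if traj.n_frames == 0:
        raise UsageError("cannot write an empty trajectory")
    if format == "xyz":
        buf = io.StringIO()
        for t, frame in enumerate(traj.frames):
            buf.write(f"{traj.n_centers}\n")
            buf.write(f"frame {t} time_fs {t * traj.dt_fs:.3f} model {traj.model_ref}\n")
            for x, y, z in frame:
                buf.write(f"X {x:12.3f} {y:12.3f} {z:12.3f}\n")
        text = buf.getvalue()
    elif format == "pdb-multimodel":
        buf = io.StringIO()
        for t, frame in enumerate(traj.frames):
            buf.write(f"MODEL {t + 1:8d}\n")
            for i, (x, y, z) in enumerate(frame, start=1):
                buf.write(
                    f"ATOM  {i:5d}  CA  ALA A{min(i, 9999):4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
                )
            buf.write("ENDMDL\n")
        buf.write("END\n")
        text = buf.getvalue()
    else:
        raise UsageError(f"unknown trajectory format {format!r}")
    with open(path, "w") as fh:
        fh.write(text)


def read_trajectory(path, dt_fs: float = 1.0, format: str = "xyz") -> Trajectory:
    """Read a trajectory written by :func:`write_trajectory`."""
    with open(path) as fh:
        text = fh.read()
    if format == "xyz":
        lines = text.splitlines()
        frames = []
        dt = dt_fs
        i = 0
        prev_time = None
        while i < len(lines):
            if not lines[i].strip():
                i += 1
                continue
            try:
                n = int(lines[i].strip())
            except ValueError:
                raise ParseError(f"line {i + 1}: expected atom count") from None
            comment = lines[i + 1] if i + 1 < len(lines) else ""
            tok = comment.split()
            if "time_fs" in tok:
                t = float(tok[tok.index("time_fs") + 1])
                if prev_time is not None and t > prev_time:
                    dt = t - prev_time
                prev_time = t
            frame = []
            for j in range(n):
                parts = lines[i + 2 + j].split()
                frame.append([float(parts[1]), float(parts[2]), float(parts[3])])
            frames.append(frame)
            i += 2 + n
        if not frames:
            raise ParseError("no frames in XYZ file")
        return Trajectory(frames=np.array(frames), dt_fs=dt)
    if format == "pdb-multimodel":
        frames = []
        current: list[list[float]] = []
        for raw in text.splitlines():
            rec = raw[:6].strip().upper()
            if rec in ("ATOM", "HETATM"):
                current.append(
                    [float(raw[30:38]), float(raw[38:46]), float(raw[46:54])]
                )
            elif rec == "ENDMDL":
                frames.append(current)
                current = []
        if current:
            frames.append(current)
        if not frames:
            raise ParseError("no frames in multi-model PDB")
        return Trajectory(frames=np.array(frames), dt_fs=dt_fs)
    raise UsageError(f"unknown trajectory format {format!r}")
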