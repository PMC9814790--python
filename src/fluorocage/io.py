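"""Readers and writers for the formats the pipeline consumes.

Structures travel as fixed-width PDB, trajectories as a plain multi-frame
XYZ dialect whose comment line carries the frame time in ps, and per-atom
partial charges / Lennard-Jones parameters as TSV tables.

Internal indexing is 0-based everywhere; 1-based serials appear only at
the PDB boundary. Coordinates are Angstrom, charges elementary charge,
LJ epsilon kcal/mol.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity plus reference coordinates."""

    index: int
    name: str
    element: str
    residue_name: str
    residue_id: int
    coordinates: tuple[float, float, float]

    def __post_init__(self):
        if not all(np.isfinite(self.coordinates)):
            raise ValueError(f"atom {self.index}: non-finite coordinates")


@dataclass
class Structure:
    """An ordered collection of atoms with a title.

    Atom indices are contiguous from 0 and equal each atom's position in
    ``atoms``.
    """

    atoms: list[AtomRecord]
    title: str = ""

    def __post_init__(self):
        for i, a in enumerate(self.atoms):
            if a.index != i:
                raise ValueError(f"atom index {a.index} at position {i}: indices must be contiguous from 0")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coordinates(self) -> np.ndarray:
        """(n_atoms, 3) reference coordinates in Angstrom."""
        return np.array([a.coordinates for a in self.atoms], dtype=float)

    def select(self, *, residue_id: int | None = None, residue_name: str | None = None,
               element: str | None = None, names: Iterable[str] | None = None) -> np.ndarray:
        """Indices of atoms matching all given filters, in structure order."""
        names = set(names) if names is not None else None
        out = []
        for a in self.atoms:
            if residue_id is not None and a.residue_id != residue_id:
                continue
            if residue_name is not None and a.residue_name != residue_name:
                continue
            if element is not None and a.element != element:
                continue
            if names is not None and a.name not in names:
                continue
            out.append(a.index)
        return np.array(out, dtype=int)

    def residue_ids(self) -> list[int]:
        """Distinct residue ids in order of first appearance."""
        seen: dict[int, None] = {}
        for a in self.atoms:
            seen.setdefault(a.residue_id, None)
        return list(seen)


@dataclass
class Trajectory:
    """Per-frame coordinates for a fixed set of atoms.

    ``times_ps`` is strictly increasing; ``coordinates`` has shape
    (n_frames, n_atoms, 3).
    """

    times_ps: np.ndarray
    coordinates: np.ndarray

    def __post_init__(self):
        self.times_ps = np.asarray(self.times_ps, dtype=float)
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (n_frames, n_atoms, 3)")
        if len(self.times_ps) != len(self.coordinates):
            raise ValueError("times and coordinate frames disagree in length")
        if len(self.times_ps) == 0:
            raise ValueError("trajectory must contain at least one frame")
        if np.any(np.diff(self.times_ps) <= 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.times_ps)

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    @property
    def frame_spacing_ps(self) -> float:
        """Spacing between consecutive frames; requires a uniform grid."""
        if self.n_frames == 1:
            raise ValueError("frame spacing undefined for a single frame")
        dt = np.diff(self.times_ps)
        if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-9):
            raise ValueError("trajectory is not uniformly spaced in time")
        return float(dt[0])


@dataclass
class ChargeTable:
    """Per-atom partial charges and (optionally) Lennard-Jones parameters."""

    table: pd.DataFrame = field(repr=False)

    REQUIRED = ("atom_index", "atom_name", "residue", "charge_e")
    LJ_COLUMNS = ("lj_sigma_A", "lj_epsilon_kcal")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise FormatError(f"charge table missing required columns: {missing}")
        idx = self.table["atom_index"].to_numpy()
        if len(np.unique(idx)) != len(idx):
            dup = int(pd.Series(idx)[pd.Series(idx).duplicated()].iloc[0])
            raise FormatError(f"duplicate atom index {dup} in charge table")
        if not np.all(np.isfinite(self.table["charge_e"].to_numpy(dtype=float))):
            raise FormatError("non-finite charge in charge table")
        self.table = self.table.sort_values("atom_index").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def has_lj(self) -> bool:
        return all(c in self.table.columns for c in self.LJ_COLUMNS)

    def charges(self, indices: Sequence[int] | None = None) -> np.ndarray:
        """Charges (e) for the given atom indices (all atoms if None)."""
        q = self.table.set_index("atom_index")["charge_e"]
        if indices is None:
            return q.to_numpy(dtype=float)
        try:
            return q.loc[list(indices)].to_numpy(dtype=float)
        except KeyError as exc:
            raise KeyError(f"charge table has no entry for atom index {exc.args[0]}") from exc

    def lj_params(self, indices: Sequence[int] | None = None) -> tuple[np.ndarray, np.ndarray]:
        """(sigma_A, epsilon_kcal) arrays; fails loudly when LJ columns are absent."""
        if not self.has_lj:
            raise FormatError("charge table has no Lennard-Jones columns "
                              f"({', '.join(self.LJ_COLUMNS)}); LJ queries unavailable")
        t = self.table.set_index("atom_index")
        if indices is None:
            sub = t
        else:
            try:
                sub = t.loc[list(indices)]
            except KeyError as exc:
                raise KeyError(f"charge table has no entry for atom index {exc.args[0]}") from exc
        sig = sub["lj_sigma_A"].to_numpy(dtype=float)
        eps = sub["lj_epsilon_kcal"].to_numpy(dtype=float)
        if not (np.all(np.isfinite(sig)) and np.all(np.isfinite(eps))):
            raise FormatError("non-finite Lennard-Jones parameter requested")
        return sig, eps

    def net_charge(self, residue: str | None = None) -> float:
        t = self.table if residue is None else self.table[self.table["residue"] == residue]
        return float(t["charge_e"].sum())


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

_ELEMENT_FROM_NAME = re.compile(r"([A-Za-z])")


def _guess_element(name: str) -> str:
    """Element from an atom name: leading letter, honouring 2-letter F/Cl style
    names is unnecessary here (toy systems use C, N, O, H, F)."""
    m = _ELEMENT_FROM_NAME.search(name)
    if not m:
        raise FormatError(f"cannot infer element from atom name {name!r}")
    return m.group(1).upper()


def read_pdb(path: str | Path) -> Structure:
    """Parse ATOM/HETATM records from a fixed-width PDB file.

    Atom order is preserved; PDB 1-based serials are discarded in favour of
    0-based positional indices. Malformed records raise :class:`FormatError`
    naming the offending line number.
    """
    path = Path(path)
    atoms: list[AtomRecord] = []
    title = ""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "TITLE ":
                title = line[10:].strip()
            if rec not in ("ATOM  ", "HETATM"):
                continue
            if len(line.rstrip("\n")) < 54:
                raise FormatError(f"{path.name}:{lineno}: truncated {rec.strip()} record")
            try:
                name = line[12:16].strip()
                resname = line[17:20].strip()
                resid = int(line[22:26])
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except ValueError as exc:
                raise FormatError(f"{path.name}:{lineno}: malformed fixed-width field ({exc})") from exc
            elem = line[76:78].strip() if len(line) >= 78 else ""
            element = elem.capitalize().upper() if elem else _guess_element(name)
            atoms.append(AtomRecord(index=len(atoms), name=name, element=element,
                                    residue_name=resname, residue_id=resid,
                                    coordinates=(x, y, z)))
    if not atoms:
        raise FormatError(f"{path.name}: no ATOM/HETATM records found")
    return Structure(atoms=atoms, title=title)


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write a Structure as fixed-width PDB (coordinates to 3 decimals)."""
    path = Path(path)
    with open(path, "w") as fh:
        if structure.title:
            fh.write(f"TITLE     {structure.title}\n")
        for a in structure.atoms:
            x, y, z = a.coordinates
            name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
            fh.write(f"HETATM{a.index + 1:5d} {name:<4s} {a.residue_name:<3s} A"
                     f"{a.residue_id:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                     f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2s}\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Multi-frame XYZ
# ---------------------------------------------------------------------------

_TIME_RE = re.compile(r"t\s*=\s*([-+0-9.eE]+)\s*ps")


def read_xyz_trajectory(path: str | Path, structure: Structure,
                        default_spacing_ps: float = 20.0) -> Trajectory:
    """Read a multi-frame XYZ file against a known structure.

    Each frame: an atom-count line, a comment line (``t = <time> ps`` if
    present), then one ``element x y z`` line per atom. A frame whose atom
    count disagrees with ``structure`` raises :class:`FormatError` naming
    the frame. Missing times fall back to ``frame_index * default_spacing_ps``.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    times: list[float] = []
    frames: list[np.ndarray] = []
    pos = 0
    frame_no = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n = int(lines[pos].strip())
        except ValueError as exc:
            raise FormatError(f"{path.name}: frame {frame_no}: bad atom-count line {lines[pos]!r}") from exc
        if n != len(structure):
            raise FormatError(f"{path.name}: frame {frame_no} has {n} atoms, "
                              f"structure has {len(structure)}")
        comment = lines[pos + 1] if pos + 1 < len(lines) else ""
        m = _TIME_RE.search(comment)
        times.append(float(m.group(1)) if m else frame_no * default_spacing_ps)
        body = lines[pos + 2: pos + 2 + n]
        if len(body) < n:
            raise FormatError(f"{path.name}: frame {frame_no}: truncated coordinate block")
        coords = np.empty((n, 3))
        for i, ln in enumerate(body):
            parts = ln.split()
            if len(parts) < 4:
                raise FormatError(f"{path.name}: frame {frame_no}, atom {i}: malformed line {ln!r}")
            coords[i] = [float(v) for v in parts[1:4]]
        frames.append(coords)
        pos += 2 + n
        frame_no += 1
    if not frames:
        raise FormatError(f"{path.name}: empty trajectory file")
    return Trajectory(times_ps=np.array(times), coordinates=np.stack(frames))


def write_xyz_trajectory(structure: Structure, trajectory: Trajectory,
                         path: str | Path, precision: int = 6) -> None:
    """Write a trajectory as multi-frame XYZ; the comment line carries the
    frame time in ps."""
    if trajectory.n_atoms != len(structure):
        raise ValueError("trajectory atom count does not match structure")
    path = Path(path)
    fmt = f"{{:s}} {{:.{precision}f}} {{:.{precision}f}} {{:.{precision}f}}\n"
    with open(path, "w") as fh:
        for t, frame in zip(trajectory.times_ps, trajectory.coordinates):
            fh.write(f"{len(structure)}\n")
            fh.write(f"t = {t:.4f} ps\n")
            for a, (x, y, z) in zip(structure.atoms, frame):
                fh.write(fmt.format(a.element, x, y, z))


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def read_charge_table(path: str | Path) -> ChargeTable:
    """Read a TSV charge/LJ table (columns: atom_index, atom_name, residue,
    charge_e[, lj_sigma_A, lj_epsilon_kcal])."""
    df = pd.read_csv(path, sep="\t")
    return ChargeTable(table=df)


def write_charge_table(table: ChargeTable, path: str | Path) -> None:
    table.table.to_csv(path, sep="\t", index=False, float_format="%.6f")
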