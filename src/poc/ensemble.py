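"""Conformational-ensemble exchange as multi-model PDB.

An ensemble is an ordered list of frames sharing one topology (the
(residue number, residue name, atom name) sequence).  Multi-model PDB is the
single interchange format: each MODEL/ENDMDL block is one frame; a file with
no MODEL records is a 1-frame ensemble.  Reading is strict — alternate
locations and insertion codes are rejected, and any frame whose atom set
deviates from the first model's raises a topology error naming the offending
model — because every downstream statistic assumes a fixed atom order.

Atom-name dialects: both O2' and O2* are accepted on read and normalized to
the PDB-v3 primed form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "Atom",
    "Frame",
    "Ensemble",
    "EnsembleParseError",
    "TopologyError",
    "EnsembleFormatError",
    "read_ensemble",
    "write_ensemble",
    "select_atoms",
]


class EnsembleParseError(ValueError):
    """Unparseable or disallowed PDB content."""


class TopologyError(ValueError):
    """Atom sets differ between models of one file."""


class EnsembleFormatError(ValueError):
    """Ensemble cannot be serialized (e.g. coordinate field overflow)."""


@dataclass(frozen=True)
class Atom:
    residue_number: int
    residue_name: str
    atom_name: str
    element: str
    xyz: tuple[float, float, float]

    def __post_init__(self):
        if not self.atom_name:
            raise ValueError("atom_name must be non-empty")
        if not all(np.isfinite(self.xyz)):
            raise ValueError("coordinates must be finite")

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.residue_number, self.residue_name, self.atom_name)


@dataclass(frozen=True)
class Frame:
    atoms: tuple[Atom, ...]
    frame_index: int = 0

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float)


@dataclass
class Ensemble:
    frames: list[Frame]
    provenance: str = ""
    _coords: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if not self.frames:
            raise ValueError("ensemble must contain at least one frame")
        topo = self.frames[0]
        for i, f in enumerate(self.frames[1:], start=2):
            if len(f.atoms) != len(topo.atoms) or any(
                a.key != b.key for a, b in zip(f.atoms, topo.atoms)
            ):
                raise TopologyError(f"frame {i} does not match the shared topology")

    @property
    def topology(self) -> tuple[tuple[int, str, str], ...]:
        """Shared (residue_number, residue_name, atom_name) sequence."""
        return tuple(a.key for a in self.frames[0].atoms)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return len(self.frames[0].atoms)

    @property
    def elements(self) -> tuple[str, ...]:
        return tuple(a.element for a in self.frames[0].atoms)

    @property
    def coords(self) -> np.ndarray:
        """Coordinates, shape (n_frames, n_atoms, 3), Å."""
        if self._coords is None:
            self._coords = np.stack([f.coords for f in self.frames])
        return self._coords


def _normalize_atom_name(name: str) -> str:
    # PDB-v2 dialect uses * where v3 uses ' (e.g. O2* for the 2'-oxygen)
    return name.strip().replace("*", "'")


def _infer_element(atom_name: str) -> str:
    for ch in atom_name:
        if ch.isalpha():
            return ch.upper()
    return ""


def select_atoms(
    ensemble: Ensemble,
    residue_numbers: set[int] | None = None,
    atom_names: set[str] | None = None,
) -> list[int]:
    """Topology indices of atoms matching the residue/atom-name filters.

    ``None`` means no constraint; an empty result is valid (downstream
    operations decide whether that is an error).
    """
    names = {_normalize_atom_name(n) for n in atom_names} if atom_names is not None else None
    out = []
    for i, (resnum, _resname, aname) in enumerate(ensemble.topology):
        if residue_numbers is not None and resnum not in residue_numbers:
            continue
        if names is not None and aname not in names:
            continue
        out.append(i)
    return out


def _prescan(path: Path) -> None:
    """Cheap line-level scan so malformed fixed-width records fail with a
    line number before the structure parser sees them."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                try:
                    float(line[30:38])
                    float(line[38:46])
                    float(line[46:54])
                    int(line[22:26])
                except (ValueError, IndexError) as exc:
                    raise EnsembleParseError(
                        f"{path}: unparseable coordinate record at line {lineno}"
                    ) from exc


def read_ensemble(path: str | Path) -> Ensemble:
    """Read a multi-model (or single-model) PDB file as an ensemble."""
    from Bio.PDB import PDBParser

    path = Path(path)
    _prescan(path)
    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure("ensemble", str(path))
    except Exception as exc:
        raise EnsembleParseError(f"{path}: {exc}") from exc

    frames: list[Frame] = []
    for model in structure:
        atoms: list[Atom] = []
        for chain in model:
            for residue in chain:
                _, resnum, icode = residue.id
                if icode.strip():
                    raise EnsembleParseError(
                        f"{path}: insertion code {icode!r} at residue {resnum} not supported"
                    )
                for atom in residue:
                    if atom.is_disordered() or atom.get_altloc().strip():
                        raise EnsembleParseError(
                            f"{path}: alternate location for atom {atom.get_name()} "
                            f"in residue {resnum} not supported"
                        )
                    name = _normalize_atom_name(atom.get_name())
                    element = (atom.element or "").strip() or _infer_element(name)
                    atoms.append(
                        Atom(
                            residue_number=resnum,
                            residue_name=residue.get_resname().strip(),
                            atom_name=name,
                            element=element,
                            xyz=tuple(float(x) for x in atom.coord),
                        )
                    )
        frames.append(Frame(atoms=tuple(atoms), frame_index=len(frames)))

    if not frames:
        raise EnsembleParseError(f"{path}: no models found")
    ref = frames[0]
    for i, f in enumerate(frames[1:], start=2):
        if len(f.atoms) != len(ref.atoms) or any(
            a.key != b.key for a, b in zip(f.atoms, ref.atoms)
        ):
            raise TopologyError(f"{path}: model {i} does not match model 1's atom set")
    return Ensemble(frames=frames, provenance=str(path))


def _format_atom_line(serial: int, atom: Atom) -> str:
    name = atom.atom_name
    # PDB convention: names of <4 chars with 1-char elements start in col 14
    field_name = name.ljust(4) if len(name) >= 4 or len(atom.element) == 2 else f" {name:<3s}"
    x, y, z = atom.xyz
    for v in (x, y, z):
        if not (-999.999 <= v <= 9999.999):
            raise EnsembleFormatError(f"coordinate {v} overflows fixed-width PDB field")
    resname = atom.residue_name[:4]
    return (
        f"ATOM  {serial:>5d} {field_name}"
        f"{resname:>4s} A{atom.residue_number:>4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
        f"          {atom.element:>2s}\n"
    )


def write_ensemble(ensemble: Ensemble, path: str | Path, single_model: bool = False) -> None:
    """Write a standard multi-model PDB (coordinates to 3 decimals).

    With ``single_model`` set, a 1-frame ensemble is written without
    MODEL/ENDMDL records.
    """
    if single_model and ensemble.n_frames != 1:
        raise EnsembleFormatError("single_model writing requires exactly one frame")
    with open(path, "w") as fh:
        if ensemble.provenance:
            fh.write(f"REMARK   6 {ensemble.provenance[:68]}\n")
        for m, frame in enumerate(ensemble.frames, start=1):
            if not single_model:
                fh.write(f"MODEL     {m:>4d}\n")
            for serial, atom in enumerate(frame.atoms, start=1):
                fh.write(_format_atom_line(serial, atom))
            if not single_model:
                fh.write("ENDMDL\n")
        fh.write("END\n")
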