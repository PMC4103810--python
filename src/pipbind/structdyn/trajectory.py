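"""Trajectory container and multi-model PDB I/O.

A trajectory is an ordered stack of coordinate frames over a fixed atom
list.  Multi-model PDB files (MODEL/ENDMDL records) are the on-disk
format; atom identity and order must be identical across models, which is
validated on read.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from ..errors import ParseError, SelectionError, SeriesValidationError

__all__ = [
    "AtomRecord",
    "Trajectory",
    "parse_selection",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
]


@dataclass(frozen=True)
class AtomRecord:
    """Identity of one atom: residue index (author numbering), residue
    name, atom name, chain id, element symbol."""

    residue_index: int
    residue_name: str
    atom_name: str
    chain: str
    element: str = ""

    def key(self):
        return (self.chain, self.residue_index, self.atom_name)


class Trajectory:
    """Frames of labeled 3-D coordinates (Å).

    Parameters
    ----------
    frames : (n_frames, n_atoms, 3) array
        Coordinates in Å; must be finite.
    atoms : sequence of AtomRecord
        Per-atom metadata, one entry per atom column.
    frame_times : optional sequence of float
        Times in ps.
    """

    def __init__(self, frames, atoms: Sequence[AtomRecord], frame_times=None):
        frames = np.asarray(frames, dtype=float)
        if frames.ndim != 3 or frames.shape[2] != 3:
            raise SeriesValidationError(
                f"frames must have shape (n_frames, n_atoms, 3), got {frames.shape}"
            )
        if not np.all(np.isfinite(frames)):
            raise SeriesValidationError("coordinates must be finite")
        if frames.shape[1] != len(atoms):
            raise SeriesValidationError(
                f"{frames.shape[1]} coordinate columns vs {len(atoms)} atom records"
            )
        self.frames = frames
        self.atoms = tuple(atoms)
        self.frame_times = None if frame_times is None else np.asarray(frame_times, float)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def atom_mask(self, selection: Optional[str] = None, atom_name: Optional[str] = None) -> np.ndarray:
        """Boolean mask from a 'CHAIN:START-END' selection and/or atom name."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if selection is not None:
            chain, lo, hi = parse_selection(selection)
            mask &= np.array([
                (chain is None or a.chain == chain)
                and (lo is None or lo <= a.residue_index <= hi)
                for a in self.atoms
            ])
        if atom_name is not None:
            mask &= np.array([a.atom_name == atom_name for a in self.atoms])
        if not mask.any():
            raise SelectionError(
                f"selection {selection!r}/{atom_name!r} matched no atoms"
            )
        return mask

    def subset(self, mask) -> "Trajectory":
        mask = np.asarray(mask, dtype=bool)
        return Trajectory(
            self.frames[:, mask, :],
            [a for a, m in zip(self.atoms, mask) if m],
            self.frame_times,
        )

    def frame(self, i: int) -> np.ndarray:
        return self.frames[i]


_SEL_RE = re.compile(r"^(?:(?P<chain>[A-Za-z0-9])?:)?(?P<lo>-?\d+)?(?:-(?P<hi>-?\d+))?$")


def parse_selection(selection: str):
    """Parse 'A:1-257', 'A:', ':5-10' or '1-257' into (chain, lo, hi)."""
    m = _SEL_RE.match(selection.strip())
    if m is None or (m.group("chain") is None and m.group("lo") is None and ":" not in selection):
        raise SelectionError(f"cannot parse selection {selection!r}")
    chain = m.group("chain")
    lo = m.group("lo")
    hi = m.group("hi")
    if lo is None and hi is None:
        return chain, None, None
    lo = int(lo)
    hi = int(hi) if hi is not None else lo
    if hi < lo:
        raise SelectionError(f"empty residue range in {selection!r}")
    return chain, lo, hi


_ELEMENT_FROM_NAME = re.compile(r"([A-Z])")


def _guess_element(atom_name: str) -> str:
    name = atom_name.strip()
    if name[:2].upper() in ("CL", "BR", "NA", "MG", "ZN", "FE", "SE"):
        return name[:2].capitalize()
    m = _ELEMENT_FROM_NAME.search(name.upper())
    return m.group(1) if m else ""


def read_multimodel_pdb(path) -> Trajectory:
    """Read a (multi-)model PDB file into a Trajectory.

    MODEL/ENDMDL records delimit frames; a file without MODEL records is a
    single-frame trajectory.  Atom count and identity must match across
    models."""
    path = Path(path)
    frames: list[list[tuple[float, float, float]]] = []
    atom_lists: list[list[AtomRecord]] = []
    current_coords: list = []
    current_atoms: list = []
    in_model = False
    saw_model_record = False

    def flush(lineno):
        nonlocal current_coords, current_atoms
        if current_atoms:
            frames.append(current_coords)
            atom_lists.append(current_atoms)
        current_coords, current_atoms = [], []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                saw_model_record = True
                in_model = True
            elif rec == "ENDMDL":
                flush(lineno)
                in_model = False
            elif rec in ("ATOM  ", "HETATM"):
                try:
                    atom_name = line[12:16].strip()
                    res_name = line[17:20].strip()
                    chain = line[21].strip() or "A"
                    res_idx = int(line[22:26])
                    x = float(line[30:38])
                    y = float(line[38:46])
                    z = float(line[46:54])
                except (ValueError, IndexError) as exc:
                    raise ParseError(f"{path}: line {lineno}: bad ATOM record") from exc
                element = line[76:78].strip() if len(line) >= 78 else ""
                if not element:
                    element = _guess_element(atom_name)
                current_coords.append((x, y, z))
                current_atoms.append(
                    AtomRecord(res_idx, res_name, atom_name, chain, element)
                )
    flush(None)
    if not frames:
        raise ParseError(f"{path}: no ATOM/HETATM records found")
    if saw_model_record and in_model:
        raise ParseError(f"{path}: unterminated MODEL block")
    ref = atom_lists[0]
    for i, atoms in enumerate(atom_lists[1:], start=2):
        if len(atoms) != len(ref) or any(
            a.key() != b.key() for a, b in zip(atoms, ref)
        ):
            raise ParseError(
                f"{path}: model {i} atom list differs from model 1 "
                "(multi-model PDB requires identical atom order)"
            )
    return Trajectory(np.array(frames, dtype=float), ref)


def write_multimodel_pdb(traj: Trajectory, path) -> None:
    """Write a Trajectory as a multi-model PDB file."""
    path = Path(path)
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"MODEL     {f + 1:4d}\n")
            for i, (atom, xyz) in enumerate(zip(traj.atoms, traj.frames[f]), start=1):
                fh.write(
                    "ATOM  {serial:5d} {name:^4s} {res:3s} {chain:1s}{resid:4d}    "
                    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {el:>2s}\n".format(
                        serial=i % 100000,
                        name=atom.atom_name[:4],
                        res=atom.residue_name[:3],
                        chain=(atom.chain or "A")[:1],
                        resid=atom.residue_index,
                        x=xyz[0], y=xyz[1], z=xyz[2],
                        occ=1.0, b=0.0,
                        el=atom.element[:2],
                    )
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")
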