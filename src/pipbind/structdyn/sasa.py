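"""Solvent-accessible surface area, anchor/tether classification and
hydrogen-bond presence.

SASA is computed with the Shrake–Rupley rolling-probe algorithm: each atom
is dressed with a sphere of radius (vdW + probe) sampled at a fixed,
deterministic point set; points not occluded by any neighbor contribute
their share of the sphere area.  Van der Waals radii follow the Bondi
compilation.

Anchor residues of a bound peptide are those burying more than a threshold
of accessible surface on binding (ΔSASA > 70 Å² by default); residues with
small burial but polar contacts (hydrogen bonds / salt bridges) are
classified as tethering residues.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ..errors import SelectionError, SeriesValidationError
from .trajectory import Trajectory

__all__ = [
    "BONDI_RADII",
    "sphere_points",
    "SasaProfile",
    "sasa",
    "delta_sasa",
    "AnchorTable",
    "classify_anchor",
    "hbond_presence",
]

#: Bondi-type van der Waals radii (Å) by element symbol
BONDI_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "Cl": 1.75,
    "Br": 1.85,
    "I": 1.98,
    "Se": 1.90,
    "B": 1.92,
    "Na": 2.27,
    "Mg": 1.73,
    "K": 2.75,
    "Ca": 2.31,
    "Zn": 1.39,
    "Fe": 2.00,
}


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (golden-section
    spiral), the classic Shrake–Rupley sampling lattice."""
    i = np.arange(n, dtype=float)
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * np.pi * i / phi
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


@dataclass(frozen=True)
class SasaProfile:
    """Per-residue solvent-accessible surface area (Å²)."""

    residue_index: np.ndarray
    residue_name: tuple[str, ...]
    area: np.ndarray
    probe_radius: float
    radii_set: str = "bondi"

    def as_series(self) -> pd.Series:
        return pd.Series(self.area, index=self.residue_index, name="sasa")


def _atom_radii(atoms) -> np.ndarray:
    radii = np.empty(len(atoms))
    unknown = []
    for i, a in enumerate(atoms):
        el = a.element.capitalize() if a.element else ""
        if el not in BONDI_RADII:
            unknown.append(f"{a.chain}:{a.residue_index}:{a.atom_name} ({el or '?'})")
            radii[i] = np.nan
        else:
            radii[i] = BONDI_RADII[el]
    if unknown:
        raise SeriesValidationError(
            "no van der Waals radius for atoms: " + ", ".join(unknown[:10])
        )
    return radii


def atom_sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Per-atom Shrake–Rupley SASA (Å²) for one coordinate set."""
    coords = np.asarray(coords, float)
    radii = np.asarray(radii, float)
    n = coords.shape[0]
    pts = sphere_points(n_points)
    ext = radii + probe_radius
    out = np.empty(n)
    # neighbor cutoff: spheres can only intersect within r_i + r_j
    max_ext = ext.max()
    for i in range(n):
        d = np.linalg.norm(coords - coords[i], axis=1)
        neigh = (d < ext[i] + max_ext) & (np.arange(n) != i)
        neigh_idx = np.flatnonzero(neigh & (d < ext[i] + ext))
        surface = coords[i] + ext[i] * pts
        if neigh_idx.size:
            diff = surface[:, None, :] - coords[neigh_idx][None, :, :]
            d2 = np.einsum("ijk,ijk->ij", diff, diff)
            buried = (d2 < (ext[neigh_idx] ** 2)[None, :]).any(axis=1)
            n_exposed = int((~buried).sum())
        else:
            n_exposed = n_points
        out[i] = 4.0 * np.pi * ext[i] ** 2 * n_exposed / n_points
    return out


def sasa(
    structure: Trajectory,
    frame: int = 0,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> SasaProfile:
    """Per-residue SASA of one frame of a structure/trajectory."""
    atoms = structure.atoms
    coords = structure.frame(frame)
    per_atom = atom_sasa(coords, _atom_radii(atoms), probe_radius, n_points)
    keys = [(a.chain, a.residue_index) for a in atoms]
    order: list = []
    agg: dict = {}
    names: dict = {}
    for k, a, area in zip(keys, atoms, per_atom):
        if k not in agg:
            agg[k] = 0.0
            names[k] = a.residue_name
            order.append(k)
        agg[k] += area
    return SasaProfile(
        residue_index=np.array([k[1] for k in order]),
        residue_name=tuple(names[k] for k in order),
        area=np.array([agg[k] for k in order]),
        probe_radius=probe_radius,
    )


def delta_sasa(
    complex_structure: Trajectory,
    ligand_mask,
    frame: int = 0,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> pd.DataFrame:
    """Per-ligand-residue surface burial on binding.

    ΔSASA_i = SASA_i(ligand alone) - SASA_i(ligand in complex), computed
    from the same coordinates, so it is non-negative up to point-sampling
    noise.  Returns a frame indexed by ligand residue number with columns
    ``residue_name``, ``sasa_free``, ``sasa_bound``, ``delta_sasa``.
    """
    ligand_mask = np.asarray(ligand_mask, dtype=bool)
    if not ligand_mask.any():
        raise SelectionError("ligand selection is empty")
    atoms = complex_structure.atoms
    coords = complex_structure.frame(frame)
    radii = _atom_radii(atoms)
    per_atom_complex = atom_sasa(coords, radii, probe_radius, n_points)
    lig_coords = coords[ligand_mask]
    lig_radii = radii[ligand_mask]
    per_atom_free = atom_sasa(lig_coords, lig_radii, probe_radius, n_points)

    lig_atoms = [a for a, m in zip(atoms, ligand_mask) if m]
    bound = per_atom_complex[ligand_mask]
    rows: dict = {}
    order = []
    for a, fa, ba in zip(lig_atoms, per_atom_free, bound):
        k = (a.chain, a.residue_index)
        if k not in rows:
            rows[k] = {"residue_name": a.residue_name, "sasa_free": 0.0, "sasa_bound": 0.0}
            order.append(k)
        rows[k]["sasa_free"] += fa
        rows[k]["sasa_bound"] += ba
    df = pd.DataFrame([rows[k] for k in order], index=[k[1] for k in order])
    df.index.name = "residue"
    df["delta_sasa"] = df["sasa_free"] - df["sasa_bound"]
    return df


@dataclass(frozen=True)
class AnchorTable:
    """Anchor/tether classification of ligand residues."""

    table: pd.DataFrame  # columns: residue_name, delta_sasa, class, evidence
    threshold: float

    def anchors(self) -> list[int]:
        return list(self.table.index[self.table["class"] == "anchor"])

    def tethers(self) -> list[int]:
        return list(self.table.index[self.table["class"] == "tether"])


def classify_anchor(
    delta: pd.DataFrame | Mapping[int, float],
    polar_evidence: Optional[Mapping[int, Sequence[str]]] = None,
    threshold: float = 70.0,
) -> AnchorTable:
    """Classify ligand residues as anchor / tether / other.

    anchor:  ΔSASA strictly greater than ``threshold`` (70 Å² default);
    tether:  not an anchor but with at least one polar-contact evidence
             entry (hydrogen bond or salt bridge partner);
    other:   neither.
    """
    polar_evidence = polar_evidence or {}
    if isinstance(delta, pd.DataFrame):
        dvals = delta["delta_sasa"]
        names = delta.get("residue_name", pd.Series("", index=delta.index))
    else:
        dvals = pd.Series(dict(delta))
        names = pd.Series("", index=dvals.index)
    rows = []
    for res, dv in dvals.items():
        ev = list(polar_evidence.get(res, []))
        if dv > threshold:
            cls = "anchor"
        elif ev:
            cls = "tether"
        else:
            cls = "other"
        rows.append({"residue_name": names.loc[res], "delta_sasa": float(dv),
                     "class": cls, "evidence": ev})
    table = pd.DataFrame(rows, index=dvals.index)
    table.index.name = "residue"
    return AnchorTable(table=table, threshold=threshold)


def _resolve_atom(traj: Trajectory, spec) -> int:
    """Resolve an atom spec (index, or (chain, residue_index, atom_name))."""
    if isinstance(spec, (int, np.integer)):
        if not 0 <= spec < traj.n_atoms:
            raise SelectionError(f"atom index {spec} out of range")
        return int(spec)
    chain, resid, name = spec
    for i, a in enumerate(traj.atoms):
        if a.chain == chain and a.residue_index == resid and a.atom_name == name:
            return i
    raise SelectionError(f"no atom matching {spec!r}")


def hbond_presence(
    traj: Trajectory,
    pairs: Sequence[tuple],
    distance_cutoff: float = 3.5,
    angle_cutoff: float = 120.0,
) -> pd.DataFrame:
    """Frame-by-frame hydrogen-bond presence table.

    ``pairs`` is a sequence of (donor, acceptor) or (donor, hydrogen,
    acceptor) atom specs — raw indices or (chain, residue, atom_name)
    triples.  A bond is present when the donor–acceptor heavy-atom
    distance is <= ``distance_cutoff`` (Å, inclusive) and, when a hydrogen
    is given, the D–H–A angle is >= ``angle_cutoff`` (degrees, inclusive).
    """
    resolved = []
    labels = []
    for pair in pairs:
        if len(pair) == 2:
            d, a = pair
            h = None
        elif len(pair) == 3:
            d, h, a = pair
        else:
            raise SeriesValidationError("each pair must be (donor, acceptor[, hydrogen])")
        di = _resolve_atom(traj, d)
        ai = _resolve_atom(traj, a)
        hi = None if h is None else _resolve_atom(traj, h)
        resolved.append((di, hi, ai))
        da, aa = traj.atoms[di], traj.atoms[ai]
        labels.append(
            f"{da.chain}:{da.residue_index}:{da.atom_name}"
            f"->{aa.chain}:{aa.residue_index}:{aa.atom_name}"
        )
    out = np.zeros((traj.n_frames, len(resolved)), dtype=bool)
    for f in range(traj.n_frames):
        xyz = traj.frames[f]
        for j, (di, hi, ai) in enumerate(resolved):
            dist = np.linalg.norm(xyz[di] - xyz[ai])
            ok = dist <= distance_cutoff
            if ok and hi is not None:
                v1 = xyz[di] - xyz[hi]
                v2 = xyz[ai] - xyz[hi]
                denom = np.linalg.norm(v1) * np.linalg.norm(v2)
                cosang = np.clip(v1 @ v2 / denom, -1.0, 1.0) if denom > 0 else 1.0
                ok = np.degrees(np.arccos(cosang)) >= angle_cutoff
            out[f, j] = ok
    return pd.DataFrame(out, columns=labels)
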