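"""Rigid-body superposition, RMSD/RMSF and snapshot PCA.

All operations work on Cα (or any masked) coordinates.  Superposition is
the Kabsch least-squares algorithm; PCA is an eigendecomposition of the
3N x 3N Cartesian covariance of frames aligned to the first frame, the
conventional way of summarizing conformational spread of an MD ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from ..errors import SeriesValidationError
from .trajectory import Trajectory

__all__ = ["superpose", "align_frames", "rmsd_series", "rmsf", "pca_snapshots", "PcaResult"]


def superpose(reference: np.ndarray, mobile: np.ndarray, mask=None):
    """Optimal rigid superposition of ``mobile`` onto ``reference`` (Kabsch).

    Parameters
    ----------
    reference, mobile : (n_atoms, 3) arrays
    mask : optional boolean array
        Atoms used to compute the transform (all atoms by default).

    Returns
    -------
    rotation : (3, 3) ndarray
        Proper rotation matrix (det = +1).
    translation : (3,) ndarray
        Such that ``mobile @ rotation.T + translation`` superposes onto
        ``reference``.
    rmsd : float
        RMSD (Å) over the masked atoms after superposition.
    """
    ref = np.asarray(reference, float)
    mob = np.asarray(mobile, float)
    if mask is None:
        mask = np.ones(ref.shape[0], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    A = ref[mask]
    B = mob[mask]
    if A.shape != B.shape:
        raise SeriesValidationError("masked atom counts differ")
    n = A.shape[0]
    if n < 3:
        raise SeriesValidationError(f"superposition needs >= 3 atoms, got {n}")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - ca, B - cb
    # geometry must span a plane for the rotation to be determined
    if np.linalg.matrix_rank(A0, tol=1e-8 * max(1.0, np.abs(A0).max())) < 2:
        raise SeriesValidationError("degenerate (collinear) reference geometry")
    H = B0.T @ A0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ca - cb @ R.T
    diff = B0 @ R.T - A0
    rmsd = float(np.sqrt((diff ** 2).sum() / n))
    return R, t, rmsd


def align_frames(traj: Trajectory, mask=None, ref_frame: int = 0) -> Trajectory:
    """Return a copy with every frame superposed onto ``ref_frame`` using
    the masked atoms to define the transform (applied to all atoms)."""
    if not 0 <= ref_frame < traj.n_frames:
        raise SeriesValidationError(f"ref_frame {ref_frame} out of range")
    ref = traj.frames[ref_frame]
    out = np.empty_like(traj.frames)
    for i in range(traj.n_frames):
        R, t, _ = superpose(ref, traj.frames[i], mask)
        out[i] = traj.frames[i] @ R.T + t
    return Trajectory(out, traj.atoms, traj.frame_times)


def rmsd_series(traj: Trajectory, mask=None, ref_frame: int = 0) -> np.ndarray:
    """Per-frame RMSD (Å) to ``ref_frame`` after optimal superposition of
    each frame; element ``ref_frame`` is exactly zero."""
    if not 0 <= ref_frame < traj.n_frames:
        raise SeriesValidationError(f"ref_frame {ref_frame} out of range")
    ref = traj.frames[ref_frame]
    out = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        if i == ref_frame:
            out[i] = 0.0
        else:
            out[i] = superpose(ref, traj.frames[i], mask)[2]
    return out


def rmsf(traj: Trajectory, mask=None, align: bool = True) -> np.ndarray:
    """Per-atom root-mean-square fluctuation (Å) about the time-average
    position, over the masked atoms.

    RMSF_i = sqrt(mean_t |x_i(t) - <x_i>|^2).  Frames are aligned to frame
    0 on the masked atoms first unless ``align=False`` (pre-aligned input).
    """
    if traj.n_frames < 2:
        raise SeriesValidationError("RMSF needs >= 2 frames")
    work = align_frames(traj, mask) if align else traj
    coords = work.frames if mask is None else work.frames[:, np.asarray(mask, bool), :]
    mean = coords.mean(axis=0)
    return np.sqrt(((coords - mean) ** 2).sum(axis=2).mean(axis=0))


@dataclass(frozen=True)
class PcaResult:
    """Eigenvalues (Å², non-increasing), orthonormal components (rows,
    length 3N) and per-frame projections of the snapshot covariance."""

    eigenvalues: np.ndarray
    components: np.ndarray
    projections: np.ndarray

    def explained_variance_ratio(self) -> np.ndarray:
        return self.eigenvalues / self.eigenvalues.sum()


def pca_snapshots(
    traj: Trajectory,
    mask=None,
    drop_residues: Optional[tuple[int, int]] = None,
    align: bool = True,
    n_components: Optional[int] = None,
) -> PcaResult:
    """PCA on Cartesian snapshot coordinates.

    ``drop_residues=(lo, hi)`` removes an author-numbered residue range
    before analysis — used to exclude mobile termini whose extreme motions
    would dominate the leading components.  The covariance is over frames
    of the flattened (3N,) coordinate vectors after alignment to frame 0.
    """
    if traj.n_frames < 3:
        raise SeriesValidationError("PCA needs >= 3 frames")
    work = traj if mask is None else traj.subset(mask)
    if drop_residues is not None:
        lo, hi = drop_residues
        keep = np.array([not (lo <= a.residue_index <= hi) for a in work.atoms])
        work = work.subset(keep)
    if align:
        work = align_frames(work)
    X = work.frames.reshape(work.n_frames, -1)
    Xc = X - X.mean(axis=0)
    if Xc.shape[1] <= Xc.shape[0]:
        cov = Xc.T @ Xc / work.n_frames
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals = np.clip(evals[order], 0.0, None)
        comps = evecs[:, order].T  # rows are components
    else:
        # more coordinates than frames: eigendecompose the frame-space
        # Gram matrix, which shares the nonzero spectrum
        gram = Xc @ Xc.T / work.n_frames
        evals, evecs = np.linalg.eigh(gram)
        order = np.argsort(evals)[::-1]
        evals = np.clip(evals[order], 0.0, None)
        evecs = evecs[:, order]
        nonzero = evals > max(evals[0], 1e-300) * 1e-12
        comps = (Xc.T @ evecs[:, nonzero]) / np.sqrt(evals[nonzero] * work.n_frames)
        comps = comps.T
        evals = evals[nonzero]
    if n_components is not None:
        comps = comps[:n_components]
        evals = evals[:n_components]
    projections = Xc @ comps.T
    return PcaResult(eigenvalues=evals, components=comps, projections=projections)
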