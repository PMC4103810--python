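"""Synthetic-data generators with known ground truth.

The assay generators emulate the working conditions of the PCNA
fluorescence-polarization competition assay: 50 nM FITC-labeled probe,
1 µM protein monomer, probe K_d = 760 nM, anisotropy window
0.0470–0.1587, quantum-yield ratio Q = 0.70, Gaussian anisotropy noise on
N = 4 replicates with occasional gross outliers.  The structural
generators build Cα-only toy ensembles with imposed per-residue
fluctuation profiles and peptide-in-groove complexes with designed buried
residues, so every downstream statistic has an exact expected value.

All generators are pure functions of (truth, seed): a single
``numpy.random.default_rng`` stream is derived from the explicit seed, and
no global random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .assay import (
    AnisotropyCalibration,
    CompetitionSeries,
    TitrationSeries,
    fraction_bound_to_anisotropy,
)
from .equilibria import (
    EquilibriumSystem,
    hill_fraction_bound,
    solve_competition_complete,
    solve_competition_incomplete,
)
from .errors import SeriesValidationError
from .structdyn.trajectory import AtomRecord, Trajectory

__all__ = [
    "AssayGroundTruth",
    "DEFAULT_TRUTH",
    "simulate_titration",
    "simulate_competition",
    "make_toy_trajectory",
    "make_toy_complex",
]


@dataclass(frozen=True)
class AssayGroundTruth:
    """Ground-truth constants for simulated assay data.

    ``K_d3 = None`` selects the complete-displacement model for
    competition data; a finite value selects the four-state model."""

    K_d1: float = 760e-9
    K_d2: Optional[float] = None
    K_d3: Optional[float] = None
    hill_n: float = 1.0
    calibration: AnisotropyCalibration = AnisotropyCalibration(0.0470, 0.1587, 0.70)
    noise_sd: float = 0.003
    n_replicates: int = 4
    outlier_rate: float = 0.0
    outlier_magnitude: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise SeriesValidationError("noise_sd must be >= 0")
        if not 0 <= self.outlier_rate < 0.5:
            raise SeriesValidationError("outlier_rate must be in [0, 0.5)")
        if self.n_replicates < 1:
            raise SeriesValidationError("n_replicates must be >= 1")

    def with_seed(self, seed: int) -> "AssayGroundTruth":
        return replace(self, seed=seed)


DEFAULT_TRUTH = AssayGroundTruth()


def _noisy_replicates(rng, r_clean: np.ndarray, truth: AssayGroundTruth) -> np.ndarray:
    n_pts = r_clean.size
    reps = r_clean[:, None] + rng.normal(0.0, truth.noise_sd, (n_pts, truth.n_replicates))
    if truth.outlier_rate > 0:
        hit = rng.random((n_pts, truth.n_replicates)) < truth.outlier_rate
        sign = rng.choice([-1.0, 1.0], size=(n_pts, truth.n_replicates))
        reps = reps + hit * sign * truth.outlier_magnitude
    return reps


def simulate_titration(
    truth: AssayGroundTruth,
    concentrations: Sequence[float],
    probe_total: float = 50e-9,
) -> TitrationSeries:
    """Simulate a direct titration (anisotropy vs protein monomer).

    The clean curve is the Hill isotherm at (K_d1, hill_n) mapped through
    the inverse anisotropy conversion; Gaussian noise of sd ``noise_sd``
    (plus seeded outliers) is added per replicate.  The concentration grid
    should span at least two decades around K_d1.
    """
    conc = np.asarray(sorted(concentrations), dtype=float)
    pos = conc[conc > 0]
    if pos.size and pos.max() / pos.min() < 100:
        raise SeriesValidationError("titration grid should span >= 2 decades")
    rng = np.random.default_rng(truth.seed)
    fb = hill_fraction_bound(conc, truth.K_d1, truth.hill_n)
    r_clean = fraction_bound_to_anisotropy(fb, truth.calibration)
    reps = _noisy_replicates(rng, np.atleast_1d(r_clean), truth)
    points = tuple((c, tuple(row)) for c, row in zip(conc, reps))
    return TitrationSeries(probe_total=probe_total, points=points)


def simulate_competition(
    truth: AssayGroundTruth,
    competitor_concentrations: Sequence[float],
    protein_total: float = 1e-6,
    probe_total: float = 50e-9,
) -> CompetitionSeries:
    """Simulate a competition series at fixed probe/protein.

    The clean fraction bound comes from the exact equilibrium solver
    (complete model when ``K_d3`` is absent, four-state otherwise), is
    converted to anisotropy through the calibration, and replicate noise
    and outliers are added as in :func:`simulate_titration`.
    """
    if truth.K_d2 is None:
        raise SeriesValidationError("competition simulation needs K_d2")
    conc = np.asarray(sorted(competitor_concentrations), dtype=float)
    rng = np.random.default_rng(truth.seed)
    fbs = []
    for c in conc:
        if truth.K_d3 is None:
            st = solve_competition_complete(
                EquilibriumSystem(R_T=protein_total, L_ST=probe_total,
                                  K_d1=truth.K_d1, L_T=float(c), K_d2=truth.K_d2)
            )
        else:
            st = solve_competition_incomplete(
                EquilibriumSystem(R_T=protein_total, L_ST=probe_total,
                                  K_d1=truth.K_d1, L_T=float(c),
                                  K_d2=truth.K_d2, K_d3=truth.K_d3)
            )
        fbs.append(st.probe_fraction_bound)
    r_clean = fraction_bound_to_anisotropy(np.array(fbs), truth.calibration)
    reps = _noisy_replicates(rng, np.atleast_1d(r_clean), truth)
    points = tuple((c, tuple(row)) for c, row in zip(conc, reps))
    return CompetitionSeries(
        probe_total=probe_total, protein_total=protein_total,
        points=points, calibration=truth.calibration,
    )


def make_toy_trajectory(
    n_frames: int,
    fluctuation_profile: Sequence[float],
    seed: int = 0,
    spacing: float = 3.8,
    rigid_motion: bool = True,
) -> Trajectory:
    """Cα-only toy ensemble with an imposed per-residue RMSF profile.

    Residue *i* sits at (i * spacing, 0, 0) plus an isotropic Gaussian
    displacement with per-axis sd = profile_i / sqrt(3), making the
    ground-truth 3-D RMSF exactly ``profile_i``.  Each frame additionally
    receives a random global rotation and translation (removed again by
    alignment) unless ``rigid_motion=False``.
    """
    profile = np.asarray(fluctuation_profile, dtype=float)
    if profile.ndim != 1 or profile.size < 3:
        raise SeriesValidationError("profile needs >= 3 residues")
    if np.any(profile < 0):
        raise SeriesValidationError("fluctuations must be >= 0")
    rng = np.random.default_rng(seed)
    n_res = profile.size
    backbone = np.zeros((n_res, 3))
    backbone[:, 0] = np.arange(n_res) * spacing
    # slight zig-zag so the reference geometry is never collinear
    backbone[:, 1] = 0.5 * (np.arange(n_res) % 2)
    frames = np.empty((n_frames, n_res, 3))
    per_axis = profile / np.sqrt(3.0)
    for f in range(n_frames):
        coords = backbone + rng.normal(0.0, 1.0, (n_res, 3)) * per_axis[:, None]
        if rigid_motion:
            q = rng.normal(size=4)
            q /= np.linalg.norm(q)
            w, x, y, z = q
            R = np.array([
                [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
                [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
                [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
            ])
            coords = coords @ R.T + rng.normal(0.0, 10.0, 3)
        frames[f] = coords
    atoms = [AtomRecord(i + 1, "GLY", "CA", "A", "C") for i in range(n_res)]
    return Trajectory(frames, atoms)


def make_toy_complex(
    n_peptide: int = 6,
    buried: Sequence[int] = (2, 4),
    spacing: float = 16.0,
    cage_radius: float = 4.5,
    cage_points: int = 80,
    seed: int = 0,
) -> tuple[Trajectory, np.ndarray]:
    """Peptide-in-groove complex with designed buried residues.

    The 'peptide' is a row of single-atom residues (chain A); each residue
    listed in ``buried`` is enclosed by a tight spherical cage of receptor
    atoms (chain B) that fully occludes it from solvent, so its ΔSASA on
    binding equals its isolated SASA; the remaining residues are far from
    any receptor atom and have ΔSASA ~ 0.

    Returns the single-frame complex trajectory and the boolean ligand
    (chain A) mask.  Raises when cage atoms sterically overlap a peptide
    atom (cage radius too small).
    """
    buried = sorted(set(int(b) for b in buried))
    if any(b < 0 or b >= n_peptide for b in buried):
        raise SeriesValidationError("buried indices out of peptide range")
    if cage_radius < 3.4:  # 2 * carbon vdW: cage would clash with the residue
        raise SeriesValidationError(
            f"cage_radius {cage_radius} Å sterically overlaps the enclosed atom"
        )
    coords = []
    atoms = []
    for i in range(n_peptide):
        coords.append((i * spacing, 0.0, 0.0))
        atoms.append(AtomRecord(i + 1, "GLY", "CA", "A", "C"))
    rng = np.random.default_rng(seed)
    from .structdyn.sasa import sphere_points

    shell = sphere_points(cage_points)
    res_b = 1
    for b in buried:
        center = np.array([b * spacing, 0.0, 0.0])
        # two interleaved shells close the gaps between cage spheres
        for scale, pts in ((1.0, shell), (1.25, sphere_points(cage_points) @ _rot(rng))):
            for p in pts:
                coords.append(tuple(center + cage_radius * scale * p))
                atoms.append(AtomRecord(res_b, "CAG", "C", "B", "C"))
            res_b += 1
    traj = Trajectory(np.array(coords)[None, :, :], atoms)
    ligand_mask = np.array([a.chain == "A" for a in atoms])
    return traj, ligand_mask


def _rot(rng) -> np.ndarray:
    """Random rotation matrix (for de-phasing interleaved cage shells)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])
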