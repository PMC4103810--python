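"""Fluorescence-polarization assay data model and quality control.

Anisotropy is the primary observable of an FP binding assay: a small
fluorescent peptide tumbles quickly (low anisotropy ``r_free``) and slows
down when bound to a large protein (high anisotropy ``r_bound``).  Because
binding may also quench the fluorophore, converting an observed anisotropy
into a fraction of probe bound requires the bound/free quantum-yield ratio
``Q``:

    f_b = (r - r_f) / [(r - r_f) + Q * (r_b - r)]

This module provides the conversion (and its exact inverse, used by the
simulators), the Z' assay-quality statistic, replicate-level outlier
screening with Grubbs' test, and the container types for titration and
competition series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import (
    DegenerateCalibrationError,
    InsufficientReplicatesError,
    SeriesValidationError,
    UndefinedSeparationError,
)

__all__ = [
    "AnisotropyCalibration",
    "TitrationSeries",
    "CompetitionSeries",
    "ControlPanel",
    "anisotropy_to_fraction_bound",
    "fraction_bound_to_anisotropy",
    "z_prime",
    "grubbs_critical_value",
    "grubbs_filter",
]


@dataclass(frozen=True)
class AnisotropyCalibration:
    """Endpoint anisotropies and quantum-yield ratio of an FP probe.

    Parameters
    ----------
    r_free : float
        Anisotropy of the unbound probe.
    r_bound : float
        Anisotropy of the fully bound probe; must exceed ``r_free``.
    q_ratio : float
        Quantum-yield ratio Q = q_bound / q_free (> 0).  Q < 1 means the
        probe is quenched on binding.
    """

    r_free: float
    r_bound: float
    q_ratio: float = 1.0

    def __post_init__(self) -> None:
        if not self.r_bound > self.r_free:
            raise DegenerateCalibrationError(
                f"r_bound ({self.r_bound}) must exceed r_free ({self.r_free})"
            )
        if not self.q_ratio > 0:
            raise SeriesValidationError(f"q_ratio must be > 0, got {self.q_ratio}")


def anisotropy_to_fraction_bound(r, cal: AnisotropyCalibration):
    """Convert observed anisotropy to fraction of probe bound.

    Accepts scalars or arrays.  Values are *not* clamped to [0, 1]: noisy
    anisotropies slightly outside the calibration window map to values
    slightly outside the unit interval, which keeps least-squares residuals
    unbiased.  Clamp only for display.
    """
    r = np.asarray(r, dtype=float)
    num = r - cal.r_free
    den = num + cal.q_ratio * (cal.r_bound - r)
    fb = num / den
    return float(fb) if fb.ndim == 0 else fb


def fraction_bound_to_anisotropy(f_b, cal: AnisotropyCalibration):
    """Exact inverse of :func:`anisotropy_to_fraction_bound`.

    Solving the conversion for r gives a ratio of affine functions of f_b:

        r = [r_f (1 - f) + Q r_b f] / [(1 - f) + Q f]
    """
    f = np.asarray(f_b, dtype=float)
    r = (cal.r_free * (1.0 - f) + cal.q_ratio * cal.r_bound * f) / (
        (1.0 - f) + cal.q_ratio * f
    )
    return float(r) if r.ndim == 0 else r


@dataclass(frozen=True)
class ControlPanel:
    """Replicate anisotropies of positive (probe+protein) and negative
    (probe only) control wells used for assay-quality assessment."""

    positive_values: tuple[float, ...]
    negative_values: tuple[float, ...]

    def __post_init__(self) -> None:
        for name, arm in (
            ("positive", self.positive_values),
            ("negative", self.negative_values),
        ):
            if len(arm) < 2:
                raise InsufficientReplicatesError(
                    f"{name} control arm needs N >= 2, got {len(arm)}"
                )
        object.__setattr__(self, "positive_values", tuple(float(v) for v in self.positive_values))
        object.__setattr__(self, "negative_values", tuple(float(v) for v in self.negative_values))


def z_prime(panel: ControlPanel) -> float:
    """Z' separation statistic, Z' = 1 - 3(s+ + s-)/|m+ - m-|.

    Uses sample standard deviations (ddof=1).  Z' close to 1 indicates a
    wide, well-separated assay window; values above ~0.5 are conventionally
    considered excellent for screening.
    """
    pos = np.asarray(panel.positive_values)
    neg = np.asarray(panel.negative_values)
    sep = abs(pos.mean() - neg.mean())
    if sep == 0:
        raise UndefinedSeparationError("control means coincide; Z' undefined")
    return 1.0 - 3.0 * (pos.std(ddof=1) + neg.std(ddof=1)) / sep


def grubbs_critical_value(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value G_crit(n, alpha).

    Derived from the Student-t quantile at alpha/(2n) on n-2 degrees of
    freedom; e.g. G_crit(4, 0.05) = 1.481.
    """
    if n < 3:
        raise InsufficientReplicatesError(f"Grubbs' test needs N >= 3, got {n}")
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t))


def grubbs_filter(
    values: Sequence[float], alpha: float = 0.05, max_passes: int = 1
) -> tuple[np.ndarray, list[int]]:
    """Screen replicate measurements for outliers with Grubbs' test.

    Two-sided test: the most extreme value (largest |x - mean|/s) is flagged
    when its G statistic exceeds the critical value.  At most one value is
    removed per pass; the default is a single pass, which with small N (the
    assay uses N = 4) avoids the instability of iterative deletion.

    Returns
    -------
    kept : ndarray
        Values surviving the screen, in original order.
    flagged : list of int
        Indices (into the input) of removed values.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size < 3:
        raise InsufficientReplicatesError(
            f"Grubbs' test needs N >= 3 replicates, got {vals.size}"
        )
    keep = np.ones(vals.size, dtype=bool)
    flagged: list[int] = []
    for _ in range(max_passes):
        cur = vals[keep]
        if cur.size < 3:
            break
        s = cur.std(ddof=1)
        if s == 0:
            break
        dev = np.abs(cur - cur.mean())
        g = dev.max() / s
        if g > grubbs_critical_value(cur.size, alpha):
            idx_in_cur = int(np.argmax(dev))
            orig_idx = int(np.flatnonzero(keep)[idx_in_cur])
            keep[orig_idx] = False
            flagged.append(orig_idx)
        else:
            break
    return vals[keep], flagged


def _validate_points(points, what: str) -> tuple[tuple[float, tuple[float, ...]], ...]:
    out = []
    prev = -np.inf
    for conc, reps in points:
        conc = float(conc)
        reps = tuple(float(x) for x in np.atleast_1d(reps))
        if conc < 0:
            raise SeriesValidationError(f"negative {what} concentration {conc}")
        if conc <= prev:
            raise SeriesValidationError(
                f"{what} concentrations must be strictly increasing "
                f"({conc} after {prev})"
            )
        if len(reps) < 1:
            raise SeriesValidationError("each point needs >= 1 replicate")
        prev = conc
        out.append((conc, reps))
    return tuple(out)


@dataclass(frozen=True)
class TitrationSeries:
    """Direct-binding titration: replicate anisotropies vs protein (monomer)
    concentration at fixed labeled-probe concentration.  Molar units."""

    probe_total: float
    points: tuple[tuple[float, tuple[float, ...]], ...]

    def __post_init__(self) -> None:
        if self.probe_total < 0:
            raise SeriesValidationError("probe_total must be >= 0")
        object.__setattr__(self, "points", _validate_points(self.points, "protein"))

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([c for c, _ in self.points])

    def qc(self, alpha: float = 0.05) -> "TitrationSeries":
        """Return a copy with per-point Grubbs-screened replicates."""
        new_points = []
        for conc, reps in self.points:
            if len(reps) >= 3:
                kept, _ = grubbs_filter(reps, alpha)
                reps = tuple(kept)
            new_points.append((conc, reps))
        return TitrationSeries(self.probe_total, tuple(new_points))


@dataclass(frozen=True)
class CompetitionSeries:
    """Competition series: replicate anisotropies vs competitor concentration
    at fixed probe and protein concentrations.  Molar units."""

    probe_total: float
    protein_total: float
    points: tuple[tuple[float, tuple[float, ...]], ...]
    calibration: AnisotropyCalibration = field(
        default_factory=lambda: AnisotropyCalibration(0.0470, 0.1587, 0.70)
    )

    def __post_init__(self) -> None:
        if not self.protein_total > 0:
            raise SeriesValidationError("protein_total must be > 0")
        if self.probe_total < 0:
            raise SeriesValidationError("probe_total must be >= 0")
        object.__setattr__(self, "points", _validate_points(self.points, "competitor"))

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([c for c, _ in self.points])

    def qc(self, alpha: float = 0.05) -> "CompetitionSeries":
        new_points = []
        for conc, reps in self.points:
            if len(reps) >= 3:
                kept, _ = grubbs_filter(reps, alpha)
                reps = tuple(kept)
            new_points.append((conc, reps))
        return CompetitionSeries(
            self.probe_total, self.protein_total, tuple(new_points), self.calibration
        )

    def fraction_bound_points(self):
        """Replicate anisotropies converted to fraction bound, per point."""
        return tuple(
            (conc, tuple(anisotropy_to_fraction_bound(np.array(reps), self.calibration)))
            for conc, reps in self.points
        )
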