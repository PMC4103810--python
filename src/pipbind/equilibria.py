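"""Exact solvers for direct and competitive binding equilibria.

Three models are covered, all in terms of total concentrations (molar) and
dissociation constants:

* direct binding  R + L* <-> RL*  (K_d1) — quadratic mass balance;
* complete competition  R + L* <-> RL* (K_d1),  R + I <-> RI (K_d2) — the
  free-protein concentration is the physical root of a cubic (the exact
  analytical solution of the three-species mass-balance system);
* incomplete competition — the four-state model adding RI + L* <-> RIL*
  (K_d3), in which the probe can still bind competitor-occupied protein, so
  displacement plateaus above zero.

A brute-force bisection oracle (:func:`oracle_solve`) solves the same mass
balances independently of the closed forms; it exists for cross-checking in
tests and should not be used inside fitting loops.

Concentrations below 1 fM are treated as zero.  All tolerances are relative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize

from .errors import NumericalFailureError, SeriesValidationError

__all__ = [
    "EquilibriumSystem",
    "SpeciesState",
    "hill_fraction_bound",
    "solve_direct",
    "solve_competition_complete",
    "solve_competition_incomplete",
    "oracle_solve",
]

#: concentrations below this (molar) are treated as zero
CONC_FLOOR = 1e-15


@dataclass(frozen=True)
class EquilibriumSystem:
    """Total concentrations and dissociation constants of a binding system.

    Attributes
    ----------
    R_T : float
        Total protein monomer (M).
    L_ST : float
        Total labeled probe (M).
    L_T : float
        Total competitor (M).
    K_d1 : float
        Probe dissociation constant (M).
    K_d2 : float, optional
        Competitor dissociation constant (M).
    K_d3 : float, optional
        Probe dissociation constant against competitor-bound protein (M);
        presence selects the four-state (incomplete-displacement) model.
    """

    R_T: float
    L_ST: float
    K_d1: float
    L_T: float = 0.0
    K_d2: Optional[float] = None
    K_d3: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("R_T", "L_ST", "L_T"):
            if getattr(self, name) < 0:
                raise SeriesValidationError(f"{name} must be >= 0")
        for name in ("K_d1", "K_d2", "K_d3"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise SeriesValidationError(f"{name} must be > 0, got {v}")
        if self.K_d3 is not None and self.K_d2 is None:
            raise SeriesValidationError("K_d3 requires K_d2")


@dataclass(frozen=True)
class SpeciesState:
    """Equilibrium concentrations (M) of all species of the four-state model.

    For the simpler models the absent species are zero."""

    free_protein: float
    free_probe: float
    free_competitor: float
    binary_probe_complex: float
    binary_competitor_complex: float
    ternary_complex: float

    @property
    def probe_fraction_bound(self) -> float:
        """Observed probe occupancy ([RL*] + [RIL*]) / L_ST; the ternary
        complex is assumed spectroscopically identical to the binary one."""
        total = self.free_probe + self.binary_probe_complex + self.ternary_complex
        if total == 0:
            return 0.0
        return (self.binary_probe_complex + self.ternary_complex) / total


def hill_fraction_bound(P, K_d: float, n: float = 1.0):
    """Hill isotherm f_b = P^n / (K_d^n + P^n).

    The phenomenological model used to fit direct titrations of anisotropy
    against monomeric protein concentration; ``n`` is the Hill slope.
    Accepts scalar or array P.
    """
    if K_d <= 0:
        raise SeriesValidationError("K_d must be > 0")
    P = np.asarray(P, dtype=float)
    if np.any(P < 0):
        raise SeriesValidationError("P must be >= 0")
    if n < 0 and np.any(P == 0):
        raise SeriesValidationError("P = 0 with negative Hill slope is undefined")
    with np.errstate(over="ignore"):
        ratio = (P / K_d) ** n
        fb = ratio / (1.0 + ratio)
    fb = np.where(np.isinf(ratio), 1.0, fb)
    return float(fb) if fb.ndim == 0 else fb


def _clean(x: float) -> float:
    # clamp negative round-off; genuine sub-floor species are kept so mass
    # balances close exactly
    return 0.0 if x < 0.0 else float(x)


def solve_direct(R_T: float, L_ST: float, K_d1: float) -> SpeciesState:
    """Exact ligand-depletion solution of R + L* <-> RL*.

    [RL*] is the smaller root of x^2 - (R_T + L_ST + K_d1) x + R_T L_ST = 0,
    computed in the numerically stable form that avoids cancellation.
    """
    sys = EquilibriumSystem(R_T=R_T, L_ST=L_ST, K_d1=K_d1)
    b = sys.R_T + sys.L_ST + sys.K_d1
    c = sys.R_T * sys.L_ST
    disc = b * b - 4.0 * c
    # disc >= 0 always holds here (K_d1 > 0)
    bound = 2.0 * c / (b + math.sqrt(disc))
    bound = min(bound, sys.R_T, sys.L_ST)
    return SpeciesState(
        free_protein=_clean(sys.R_T - bound),
        free_probe=_clean(sys.L_ST - bound),
        free_competitor=0.0,
        binary_probe_complex=_clean(bound),
        binary_competitor_complex=0.0,
        ternary_complex=0.0,
    )


def _cubic_free_protein(R_T, L_ST, L_T, K_d1, K_d2) -> float:
    """Physical root (in (0, R_T]) of the competitive-binding cubic in the
    free-protein concentration, via the trigonometric solution."""
    d = K_d1 + K_d2 + L_ST + L_T - R_T
    e = K_d1 * K_d2 + K_d2 * (L_ST - R_T) + K_d1 * (L_T - R_T)
    f = -K_d1 * K_d2 * R_T
    # depressed cubic t^3 + p t + q with R = t - d/3
    p = e - d * d / 3.0
    q = 2.0 * d ** 3 / 27.0 - d * e / 3.0 + f
    m2 = -p / 3.0
    if m2 <= 0:
        return float("nan")
    m = 2.0 * math.sqrt(m2)
    arg = 3.0 * q / (p * m)
    if abs(arg) > 1.0:
        if abs(arg) - 1.0 > 1e-9:
            return float("nan")
        arg = math.copysign(1.0, arg)
    theta = math.acos(arg) / 3.0
    # the largest of the three real roots is the physical one
    R = m * math.cos(theta) - d / 3.0
    return R


def _balance_residual(R, R_T, L_ST, L_T, K_d1, K_d2):
    L = L_ST / (1.0 + R / K_d1)
    I = L_T / (1.0 + R / K_d2)
    return R * (1.0 + L / K_d1 + I / K_d2) - R_T


def _newton_polish(R, R_T, L_ST, L_T, K_d1, K_d2, n_iter=4):
    """Refine the free-protein root; the balance is smooth and monotone so
    a few Newton steps reach machine precision from the closed form."""
    for _ in range(n_iter):
        g = _balance_residual(R, R_T, L_ST, L_T, K_d1, K_d2)
        dg = (
            1.0
            + L_ST * K_d1 / (K_d1 + R) ** 2
            + L_T * K_d2 / (K_d2 + R) ** 2
        )
        step = g / dg
        R_new = R - step
        if not 0.0 < R_new <= R_T:
            break
        if R_new == R:
            R = R_new
            break
        R = R_new
    return R


def solve_competition_complete(sys: EquilibriumSystem) -> SpeciesState:
    """Exact solution of the complete-displacement competition model.

    Requires ``K_d2`` set and ``K_d3`` unset.  The free protein [R] is the
    physical cubic root; probe fraction bound equals [R]/([R] + K_d1).
    Falls back to bounded bisection when the closed form is numerically
    marginal.
    """
    if sys.K_d2 is None or sys.K_d3 is not None:
        raise SeriesValidationError("complete model needs K_d2 and no K_d3")
    R_T, L_ST, L_T, K_d1, K_d2 = sys.R_T, sys.L_ST, sys.L_T, sys.K_d1, sys.K_d2
    if R_T < CONC_FLOOR:
        return SpeciesState(0.0, _clean(L_ST), _clean(L_T), 0.0, 0.0, 0.0)
    R = _cubic_free_protein(R_T, L_ST, L_T, K_d1, K_d2)
    if math.isfinite(R) and 0.0 < R <= R_T * (1.0 + 1e-9):
        R = _newton_polish(min(R, R_T), R_T, L_ST, L_T, K_d1, K_d2)
    ok = (
        math.isfinite(R)
        and 0.0 < R <= R_T * (1.0 + 1e-12)
        and abs(_balance_residual(R, R_T, L_ST, L_T, K_d1, K_d2)) <= 1e-9 * R_T
    )
    if not ok:
        # bisect in log space so tiny free-protein roots keep relative accuracy
        try:
            u = optimize.brentq(
                lambda u_: _balance_residual(math.exp(u_), R_T, L_ST, L_T, K_d1, K_d2),
                math.log(R_T) - 80.0,
                math.log(R_T),
                xtol=1e-14,
                rtol=1e-15,
            )
            R = _newton_polish(math.exp(u), R_T, L_ST, L_T, K_d1, K_d2)
        except ValueError as exc:  # pragma: no cover - guarded by physics
            raise NumericalFailureError(
                f"no physical root in [0, R_T] for {sys}"
            ) from exc
    R = min(R, R_T)
    L = L_ST / (1.0 + R / K_d1)
    I = L_T / (1.0 + R / K_d2)
    return SpeciesState(
        free_protein=_clean(R),
        free_probe=_clean(L),
        free_competitor=_clean(I),
        binary_probe_complex=_clean(R * L / K_d1),
        binary_competitor_complex=_clean(R * I / K_d2),
        ternary_complex=0.0,
    )


def _inner_free_ligands(R, R_T, L_ST, L_T, K_d1, K_d2, K_d3):
    """Given free protein R, solve the (L, I) sub-system exactly.

    The two ligand balances L (1 + a + b I) = L_ST and I (1 + c + b L) = L_T
    with a = R/K_d1, b = R/(K_d2 K_d3), c = R/K_d2 reduce to a quadratic in
    the free competitor I, taken in its cancellation-free form."""
    a = R / K_d1
    b = R / (K_d2 * K_d3)
    c = R / K_d2
    A = b * (1.0 + c)
    B = (1.0 + a) * (1.0 + c) + b * (L_ST - L_T)
    C = -L_T * (1.0 + a)
    if A == 0.0:
        I = -C / B
    else:
        disc = math.sqrt(B * B - 4.0 * A * C)
        if B >= 0.0:
            I = 2.0 * (-C) / (B + disc)
        else:
            I = (-B + disc) / (2.0 * A)
    L = L_ST / (1.0 + a + b * I)
    return L, I


def solve_competition_incomplete(sys: EquilibriumSystem) -> SpeciesState:
    """Solve the four-state incomplete-displacement model.

    States: R + L* <-> RL* (K_d1), R + I <-> RI (K_d2), RI + L* <-> RIL*
    (K_d3).  The protein mass balance is monotone in the free protein
    concentration, so the outer problem is a bracketed 1-D root solve with
    an inner fixed-point solve for the free probe/competitor.
    Converges to relative 1e-9 or raises :class:`NumericalFailureError`.
    """
    if sys.K_d2 is None or sys.K_d3 is None:
        raise SeriesValidationError("incomplete model needs K_d2 and K_d3")
    R_T, L_ST, L_T = sys.R_T, sys.L_ST, sys.L_T
    K_d1, K_d2, K_d3 = sys.K_d1, sys.K_d2, sys.K_d3
    if R_T < CONC_FLOOR:
        return SpeciesState(0.0, _clean(L_ST), _clean(L_T), 0.0, 0.0, 0.0)

    def residual(R):
        if R <= 0:
            return -R_T
        L, I = _inner_free_ligands(R, R_T, L_ST, L_T, K_d1, K_d2, K_d3)
        RI = R * I / K_d2
        return R + R * L / K_d1 + RI + RI * L / K_d3 - R_T

    # root-find in log space: the free protein can be many orders of
    # magnitude below R_T under a tight-binding competitor, and the balance
    # needs relative (not absolute) resolution there
    try:
        u = optimize.brentq(
            lambda u_: residual(math.exp(u_)),
            math.log(R_T) - 80.0,
            math.log(R_T),
            xtol=1e-14,
            rtol=1e-15,
        )
        R = math.exp(u)
    except ValueError as exc:
        raise NumericalFailureError(
            f"four-state solver failed to bracket free protein for {sys}"
        ) from exc
    L, I = _inner_free_ligands(R, R_T, L_ST, L_T, K_d1, K_d2, K_d3)
    RI = R * I / K_d2
    state = SpeciesState(
        free_protein=_clean(R),
        free_probe=_clean(L),
        free_competitor=_clean(I),
        binary_probe_complex=_clean(R * L / K_d1),
        binary_competitor_complex=_clean(RI),
        ternary_complex=_clean(RI * L / K_d3),
    )
    _check_mass_balance(sys, state, rtol=1e-9)
    return state


def _check_mass_balance(sys: EquilibriumSystem, st: SpeciesState, rtol: float) -> None:
    scale = max(sys.R_T, sys.L_ST, sys.L_T, CONC_FLOOR)
    errs = (
        abs(st.free_protein + st.binary_probe_complex + st.binary_competitor_complex + st.ternary_complex - sys.R_T),
        abs(st.free_probe + st.binary_probe_complex + st.ternary_complex - sys.L_ST),
        abs(st.free_competitor + st.binary_competitor_complex + st.ternary_complex - sys.L_T),
    )
    if max(errs) > rtol * scale:
        raise NumericalFailureError(
            f"mass balance violated (max err {max(errs):.3e}, scale {scale:.3e})"
        )


def solve(sys: EquilibriumSystem) -> SpeciesState:
    """Dispatch to the appropriate exact solver for the system topology."""
    if sys.K_d3 is not None:
        return solve_competition_incomplete(sys)
    if sys.K_d2 is not None:
        return solve_competition_complete(sys)
    return solve_direct(sys.R_T, sys.L_ST, sys.K_d1)


def oracle_solve(sys: EquilibriumSystem) -> SpeciesState:
    """Brute-force verifier: plain bisection on the free-protein balance.

    Independent of the closed forms above (no cubic, no brentq); intended
    for cross-checks in tests.  Relative tolerance 1e-12.
    """
    R_T, L_ST, L_T = sys.R_T, sys.L_ST, sys.L_T
    K_d1 = sys.K_d1
    K_d2 = sys.K_d2 if sys.K_d2 is not None else 1.0
    L_T_eff = L_T if sys.K_d2 is not None else 0.0
    K_d3 = sys.K_d3

    if R_T < CONC_FLOOR:
        return SpeciesState(0.0, _clean(L_ST), _clean(L_T), 0.0, 0.0, 0.0)

    def species_at(R):
        if K_d3 is None:
            L = L_ST / (1.0 + R / K_d1)
            I = L_T_eff / (1.0 + R / K_d2)
            return L, I, R * L / K_d1, R * I / K_d2, 0.0
        L, I = _inner_free_ligands(R, R_T, L_ST, L_T_eff, K_d1, K_d2, K_d3)
        RI = R * I / K_d2
        return L, I, R * L / K_d1, RI, RI * L / K_d3

    lo, hi = 0.0, R_T
    # bisect down to ulp resolution (~60 iterations)
    for _ in range(120):
        mid = 0.5 * (lo + hi)
        if mid == lo or mid == hi:
            break
        L, I, RL, RI, RIL = species_at(mid)
        if mid + RL + RI + RIL > R_T:
            hi = mid
        else:
            lo = mid
    R = 0.5 * (lo + hi)
    L, I, RL, RI, RIL = species_at(R)
    return SpeciesState(
        free_protein=_clean(R),
        free_probe=_clean(L),
        free_competitor=_clean(I if sys.K_d2 is not None else L_T),
        binary_probe_complex=_clean(RL),
        binary_competitor_complex=_clean(RI),
        ternary_complex=_clean(RIL),
    )
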