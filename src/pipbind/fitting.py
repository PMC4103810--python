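"""Nonlinear least-squares estimation for FP binding and competition data.

Four estimators are provided, mirroring the standard analysis chain of a
fluorescence-polarization competition assay:

1. :func:`fit_direct` — Hill binding isotherm on a direct titration
   (anisotropy vs protein), yielding the probe dissociation constant K_d.
2. :func:`fit_ic50` — four-parameter logistic on the converted fraction
   bound vs competitor, yielding IC50 and the Hill slope (negative for
   displacement curves).
3. :func:`fit_competition_complete` / :func:`fit_competition_incomplete` —
   mechanistic fits through the exact equilibrium solvers, yielding the
   competitor constant K_d2 (and K_d3 for incomplete displacement).
4. :func:`ki_classic` / :func:`ki_modified` — Cheng–Prusoff conversion of
   an IC50 into an inhibition constant; the modified form corrects for the
   free probe and free protein concentrations of an FP assay.

All fits operate on replicate-level residuals (every surviving replicate is
a residual, unweighted) after Grubbs outlier screening.  Mechanistic-model
parameters are optimized in log10 space so positivity is structural.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import lmfit
import numpy as np

from .assay import CompetitionSeries, TitrationSeries, anisotropy_to_fraction_bound
from .equilibria import (
    EquilibriumSystem,
    hill_fraction_bound,
    solve_competition_complete,
    solve_competition_incomplete,
)
from .errors import SeriesValidationError

__all__ = [
    "BindingFit",
    "Ic50Fit",
    "CompetitionFit",
    "KiResult",
    "fit_direct",
    "fit_ic50",
    "ki_classic",
    "ki_modified",
    "fit_competition_complete",
    "fit_competition_incomplete",
    "select_competition_model",
]


@dataclass(frozen=True)
class BindingFit:
    """Result of a direct-titration Hill fit."""

    K_d: float
    hill_n: float
    r_free: float
    r_bound: float
    K_d_stderr: Optional[float]
    hill_n_stderr: Optional[float]
    r_free_stderr: Optional[float]
    r_bound_stderr: Optional[float]
    converged: bool
    message: str = ""


@dataclass(frozen=True)
class Ic50Fit:
    """Result of a four-parameter logistic fit to a displacement curve.

    ``hill_n`` is signed: displacement data give negative slopes.
    ``fb_at_max`` is the mean *observed* fraction bound at the highest
    tested competitor concentration (after QC), the quantity used for
    complete/incomplete model selection."""

    IC50: float
    hill_n: float
    top: float
    bottom: float
    fb_at_max: float
    IC50_stderr: Optional[float]
    hill_n_stderr: Optional[float]
    top_stderr: Optional[float]
    bottom_stderr: Optional[float]
    converged: bool
    message: str = ""


@dataclass(frozen=True)
class CompetitionFit:
    """Result of a mechanistic competition fit (K_d1 held fixed)."""

    model: str  # "complete" | "incomplete"
    K_d2: float
    K_d3: Optional[float]
    K_d1: float
    K_d2_stderr: Optional[float]
    K_d3_stderr: Optional[float]
    residual_norm: float
    converged: bool
    message: str = ""


@dataclass(frozen=True)
class KiResult:
    """Inhibition constant derived from an IC50."""

    K_i: float
    method: str  # "classic" | "modified"
    inputs: dict = field(default_factory=dict)


def _flatten(points):
    xs, ys = [], []
    for conc, reps in points:
        for r in reps:
            xs.append(conc)
            ys.append(r)
    return np.asarray(xs), np.asarray(ys)


def fit_direct(
    series: TitrationSeries, alpha: float = 0.05, cal_hints=None, q_ratio=None
) -> BindingFit:
    """Fit the Hill isotherm to a direct titration of anisotropy vs protein.

    The occupancy model is f_b = P^n / (K_d^n + P^n); the predicted
    anisotropy carries the quantum-yield correction,

        r = [r_f (1 - f_b) + Q r_b f_b] / [(1 - f_b) + Q f_b],

    which for Q = 1 reduces to the familiar r = r_f + (r_b - r_f) f_b.
    Fitting without the correction when the probe is quenched (Q < 1)
    returns the apparent constant K_d / Q rather than K_d, so Q is taken
    from ``cal_hints`` (an :class:`AnisotropyCalibration`, which also seeds
    r_free/r_bound) or ``q_ratio``, defaulting to 1.

    Replicates are Grubbs-screened per concentration before fitting; r_f,
    r_b remain free parameters.  A fit is flagged unconverged when the
    optimizer fails, the window collapses, or K_d leaves the tested
    concentration range.
    """
    if len(series.points) < 5:
        raise SeriesValidationError("direct fit needs >= 5 concentration points")
    series = series.qc(alpha)
    x, y = _flatten(series.points)
    pos = x[x > 0]
    if np.ptp(y) == 0 or pos.size == 0:
        return BindingFit(np.nan, np.nan, np.nan, np.nan, None, None, None, None,
                          False, "degenerate data: flat anisotropy response")

    rf0 = cal_hints.r_free if cal_hints is not None else float(y.min())
    rb0 = cal_hints.r_bound if cal_hints is not None else float(y.max())
    if q_ratio is None:
        q_ratio = cal_hints.q_ratio if cal_hints is not None else 1.0
    params = lmfit.Parameters()
    params.add("log10_Kd", value=float(np.log10(np.median(pos))), min=np.log10(pos.min()) - 3,
               max=np.log10(pos.max()) + 3)
    params.add("hill_n", value=1.0, min=0.05, max=10.0)
    params.add("r_free", value=rf0)
    params.add("r_bound", value=rb0)

    def resid(p):
        fb = hill_fraction_bound(x, 10.0 ** p["log10_Kd"].value, p["hill_n"].value)
        rf, rb = p["r_free"].value, p["r_bound"].value
        model = (rf * (1.0 - fb) + q_ratio * rb * fb) / ((1.0 - fb) + q_ratio * fb)
        return model - y

    out = lmfit.minimize(resid, params, method="leastsq")
    kd = 10.0 ** out.params["log10_Kd"].value
    lse = out.params["log10_Kd"].stderr
    kd_se = kd * np.log(10.0) * lse if lse is not None else None
    rf = out.params["r_free"].value
    rb = out.params["r_bound"].value
    ok = bool(out.success) and rb > rf and pos.min() / 10 <= kd <= pos.max() * 10
    msg = "" if ok else "fit flagged: " + (
        out.message if not out.success else "K_d outside tested range or inverted window"
    )
    return BindingFit(
        K_d=kd, hill_n=out.params["hill_n"].value, r_free=rf, r_bound=rb,
        K_d_stderr=kd_se, hill_n_stderr=out.params["hill_n"].stderr,
        r_free_stderr=out.params["r_free"].stderr,
        r_bound_stderr=out.params["r_bound"].stderr,
        converged=ok, message=msg,
    )


def _logistic_fb(conc, ic50, n, top, bottom):
    """Four-parameter logistic in log-concentration; signed Hill slope.

    f(I) = bottom + (top - bottom) / (1 + (I/IC50)^(-n)); the I = 0 limit
    is ``top`` for n < 0 and ``bottom`` for n > 0."""
    conc = np.asarray(conc, dtype=float)
    with np.errstate(divide="ignore", over="ignore"):
        z = -n * (np.log(conc) - np.log(ic50))
        frac = np.where(np.isposinf(z), 0.0, 1.0 / (1.0 + np.exp(np.minimum(z, 700))))
    return bottom + (top - bottom) * frac


def fit_ic50(series: CompetitionSeries, alpha: float = 0.05) -> Ic50Fit:
    """Fit the four-parameter logistic to converted fraction-bound data."""
    if len(series.points) < 6:
        raise SeriesValidationError("IC50 fit needs >= 6 competitor concentrations")
    series = series.qc(alpha)
    fb_points = series.fraction_bound_points()
    x, y = _flatten(fb_points)
    fb_at_max = float(np.mean(fb_points[-1][1]))

    pos = x[x > 0]
    if pos.size < 3 or np.ptp(y) == 0:
        return Ic50Fit(np.nan, np.nan, np.nan, np.nan, fb_at_max,
                       None, None, None, None, False, "degenerate data")

    params = lmfit.Parameters()
    params.add("log10_ic50", value=float(np.log10(np.median(pos))),
               min=np.log10(pos.min()) - 3, max=np.log10(pos.max()) + 3)
    params.add("hill_n", value=-1.0, min=-10.0, max=10.0)
    params.add("top", value=float(y.max()))
    params.add("bottom", value=float(max(y.min(), 0.0)))

    def resid(p):
        return _logistic_fb(x, 10.0 ** p["log10_ic50"].value, p["hill_n"].value,
                            p["top"].value, p["bottom"].value) - y

    out = lmfit.minimize(resid, params, method="leastsq")
    ic50 = 10.0 ** out.params["log10_ic50"].value
    lse = out.params["log10_ic50"].stderr
    n_fit = out.params["hill_n"].value
    top, bottom = out.params["top"].value, out.params["bottom"].value
    ok = bool(out.success) and top > bottom and n_fit < 0
    msg = ""
    if not ok:
        msg = ("fit flagged: wrong-direction response (Hill slope >= 0)"
               if n_fit >= 0 or top <= bottom else f"fit flagged: {out.message}")
    return Ic50Fit(
        IC50=ic50, hill_n=n_fit, top=top, bottom=bottom, fb_at_max=fb_at_max,
        IC50_stderr=ic50 * np.log(10.0) * lse if lse is not None else None,
        hill_n_stderr=out.params["hill_n"].stderr,
        top_stderr=out.params["top"].stderr,
        bottom_stderr=out.params["bottom"].stderr,
        converged=ok, message=msg,
    )


def ki_classic(I50: float, L_probe_total: float, K_d: float) -> KiResult:
    """Classic Cheng–Prusoff conversion K_i = IC50 / (1 + L/K_d)."""
    if I50 <= 0 or L_probe_total < 0 or K_d <= 0:
        raise SeriesValidationError("I50, K_d must be > 0 and L >= 0")
    ki = I50 / (1.0 + L_probe_total / K_d)
    return KiResult(K_i=ki, method="classic",
                    inputs={"I50": I50, "L": L_probe_total, "K_d": K_d})


def ki_modified(I50: float, fb0: float, L_ST: float, R_T: float, K_d: float) -> KiResult:
    """FP-corrected Cheng–Prusoff conversion.

    K_i = IC50 / ([L]50/K_d + [P]0/K_d + 1), with the free-species terms
    derived from the zero-competitor occupancy fb0:

        [L]50 = L_ST (1 - fb0/2)   (free probe at 50% inhibition)
        [P]0  = R_T - fb0 L_ST     (free protein at 0% inhibition)
    """
    if not 0.0 < fb0 < 1.0:
        raise SeriesValidationError("fb0 must lie in (0, 1)")
    if I50 <= 0 or L_ST < 0 or R_T < 0 or K_d <= 0:
        raise SeriesValidationError("concentrations must be physical")
    L50 = L_ST * (1.0 - fb0 / 2.0)
    P0 = R_T - fb0 * L_ST
    ki = I50 / (L50 / K_d + P0 / K_d + 1.0)
    return KiResult(K_i=ki, method="modified",
                    inputs={"I50": I50, "fb0": fb0, "L50_free": L50,
                            "P0_free": P0, "L_ST": L_ST, "R_T": R_T, "K_d": K_d})


def _model_fb_complete(concs, K_d1, K_d2, R_T, L_ST):
    return np.array([
        solve_competition_complete(
            EquilibriumSystem(R_T=R_T, L_ST=L_ST, K_d1=K_d1, L_T=c, K_d2=K_d2)
        ).probe_fraction_bound
        for c in concs
    ])


def _model_fb_incomplete(concs, K_d1, K_d2, K_d3, R_T, L_ST):
    return np.array([
        solve_competition_incomplete(
            EquilibriumSystem(R_T=R_T, L_ST=L_ST, K_d1=K_d1, L_T=c,
                              K_d2=K_d2, K_d3=K_d3)
        ).probe_fraction_bound
        for c in concs
    ])


def fit_competition_complete(
    series: CompetitionSeries, K_d1: float, alpha: float = 0.05
) -> CompetitionFit:
    """Least-squares estimate of K_d2 under the complete-displacement model.

    K_d1 (the probe constant, from a prior direct fit) is held fixed; the
    single free parameter is optimized in log10 space with the exact cubic
    solver evaluating the model."""
    series = series.qc(alpha)
    x, y = _flatten(series.fraction_bound_points())
    pos = series.concentrations[series.concentrations > 0]
    params = lmfit.Parameters()
    guess = float(np.median(pos)) if pos.size else K_d1
    params.add("log10_Kd2", value=np.log10(guess), min=-15, max=0)

    def resid(p):
        return _model_fb_complete(x, K_d1, 10.0 ** p["log10_Kd2"].value,
                                  series.protein_total, series.probe_total) - y

    out = lmfit.minimize(resid, params, method="leastsq")
    kd2 = 10.0 ** out.params["log10_Kd2"].value
    lse = out.params["log10_Kd2"].stderr
    return CompetitionFit(
        model="complete", K_d2=kd2, K_d3=None, K_d1=K_d1,
        K_d2_stderr=kd2 * np.log(10.0) * lse if lse is not None else None,
        K_d3_stderr=None,
        residual_norm=float(np.linalg.norm(out.residual)),
        converged=bool(out.success),
        message="" if out.success else str(out.message),
    )


def fit_competition_incomplete(
    series: CompetitionSeries,
    K_d1: float,
    alpha: float = 0.05,
    n_starts: int = 3,
    seed: int = 0,
) -> CompetitionFit:
    """Joint least-squares estimate of (K_d2, K_d3) under the four-state model.

    Multi-start (default 3 starts with seeded log-space jitter) guards
    against the shallow valley that couples K_d2 and K_d3 when the
    displacement plateau is barely sampled; in that situation (observed
    plateau < 0.02) an identifiability warning is emitted and K_d3 is
    effectively bounded only from below."""
    series = series.qc(alpha)
    fb_points = series.fraction_bound_points()
    x, y = _flatten(fb_points)
    plateau = float(np.mean(fb_points[-1][1]))
    if plateau < 0.02:
        warnings.warn(
            "displacement plateau unsampled (fb at max competitor ~ 0); "
            "K_d3 is unbounded above and only a lower bound is identifiable",
            stacklevel=2,
        )
    pos = series.concentrations[series.concentrations > 0]
    guess2 = float(np.median(pos)) if pos.size else K_d1
    rng = np.random.default_rng(seed)

    def resid(p):
        return _model_fb_incomplete(
            x, K_d1, 10.0 ** p["log10_Kd2"].value, 10.0 ** p["log10_Kd3"].value,
            series.protein_total, series.probe_total) - y

    best = None
    for i in range(n_starts):
        params = lmfit.Parameters()
        j2 = 0.0 if i == 0 else rng.normal(0, 0.7)
        j3 = 0.0 if i == 0 else rng.normal(0, 0.7)
        params.add("log10_Kd2", value=np.log10(guess2) + j2, min=-15, max=0)
        params.add("log10_Kd3", value=np.log10(max(K_d1 * 10, 1e-9)) + j3,
                   min=-15, max=2)
        out = lmfit.minimize(resid, params, method="leastsq")
        cost = float(np.sum(out.residual ** 2))
        if best is None or cost < best[0]:
            best = (cost, out)
    out = best[1]
    kd2 = 10.0 ** out.params["log10_Kd2"].value
    kd3 = 10.0 ** out.params["log10_Kd3"].value
    se2 = out.params["log10_Kd2"].stderr
    se3 = out.params["log10_Kd3"].stderr
    return CompetitionFit(
        model="incomplete", K_d2=kd2, K_d3=kd3, K_d1=K_d1,
        K_d2_stderr=kd2 * np.log(10.0) * se2 if se2 is not None else None,
        K_d3_stderr=kd3 * np.log(10.0) * se3 if se3 is not None else None,
        residual_norm=float(np.linalg.norm(out.residual)),
        converged=bool(out.success),
        message="" if out.success else str(out.message),
    )


def select_competition_model(fit: Ic50Fit, threshold: float = 0.05) -> str:
    """Choose the displacement model from the residual probe occupancy.

    ``incomplete`` iff the observed fraction bound at the highest tested
    competitor concentration exceeds ``threshold`` (strict inequality);
    ``complete`` otherwise."""
    if not fit.converged:
        raise SeriesValidationError("model selection requires a converged IC50 fit")
    return "incomplete" if fit.fb_at_max > threshold else "complete"
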