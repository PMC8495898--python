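"""Stage 2: the second thermokinetic plot and enthalpy–entropy decorrelation.

The (slope, intercept) pairs of the first plots are strongly correlated
estimates of ΔacidH° and Δ(ΔS°).  Plotting the *negated* first-plot
intercepts against the first-plot slopes decorrelates them:

    y = −intercept₁ = (ΔacidH° − ΔacidH°_ref^avg)·x − Δ(ΔS°)/R,
    x = slope₁ = 1/(R·T_eff)

so a straight-line fit across collision energies gives

    slope₂     = ΔacidH° − ΔacidH°_ref^avg     (kJ/mol)
    intercept₂ = −Δ(ΔS°)/R                     (dimensionless)

Both coordinates carry uncertainty inherited from the first-stage
covariances, so the line is fitted by an effective-variance
(York-type) errors-in-both-variables regression that also honours the
per-point slope–intercept covariance.  With all uncertainties zero the
estimator reduces exactly to ordinary least squares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import (
    R_J,
    ConvergenceError,
    EKMResult,
    IdentifiabilityError,
    LadderSummary,
    T_STD,
    ga_from_enthalpy_entropy,
)
from .kinetics import FirstPlotFit, _line_fit

__all__ = [
    "SecondPlotPoint",
    "SecondPlotFit",
    "build_second_plot",
    "fit_second_plot",
    "derive_thermochemistry",
]


@dataclass(frozen=True)
class SecondPlotPoint:
    """One collision energy's contribution to the second plot.

    ``x`` is the first-plot slope 1/(R·T_eff) (mol/kJ); ``y`` the negated
    first-plot intercept.  ``xy_cov`` is the covariance between them —
    the sign flip of y negates the first-stage slope–intercept covariance.
    """

    x: float
    y: float
    x_unc: float = 0.0
    y_unc: float = 0.0
    xy_cov: float = 0.0
    e_cm: float = math.nan

    def __post_init__(self) -> None:
        if self.x_unc < 0 or self.y_unc < 0:
            raise ValueError("uncertainties must be non-negative")


@dataclass(frozen=True)
class SecondPlotFit:
    """Errors-in-variables line fit of the second thermokinetic plot."""

    slope: float  # ΔacidH° − ΔacidH°_ref^avg, kJ/mol
    intercept: float  # −Δ(ΔS°)/R, dimensionless
    slope_unc: float
    intercept_unc: float
    cov: np.ndarray  # 2×2 covariance of (slope, intercept)
    n_points: int = 0
    n_iter: int = 0


def build_second_plot(fits: Sequence[FirstPlotFit]) -> list[SecondPlotPoint]:
    """Turn retained first-plot fits into second-plot points.

    Fits flagged for a non-positive slope are dropped.  Raises
    :class:`IdentifiabilityError` when fewer than 3 fits remain or when all
    effective temperatures coincide (the x spread vanishes and ΔH cannot be
    separated from Δ(ΔS°)).
    """
    good = [f for f in fits if f.ok]
    if len(good) < 3:
        raise IdentifiabilityError(
            f"second plot needs at least 3 retained first-plot fits, got {len(good)}"
        )
    x = np.array([f.slope for f in good])
    if np.ptp(x) < 1e-12:
        raise IdentifiabilityError(
            "all effective temperatures are equal: the second plot has no "
            "abscissa spread, so enthalpy and entropy are not separately "
            "identifiable (vary the collision energy)"
        )
    return [
        SecondPlotPoint(
            x=f.slope,
            y=-f.intercept,
            x_unc=math.sqrt(max(f.cov[0, 0], 0.0)),
            y_unc=math.sqrt(max(f.cov[1, 1], 0.0)),
            xy_cov=-f.cov[0, 1],
            e_cm=f.e_cm,
        )
        for f in good
    ]


def _effective_variance(
    b: float, sx2: np.ndarray, sy2: np.ndarray, sxy: np.ndarray
) -> np.ndarray:
    """Variance of the residual y − a − b·x for correlated (x, y) errors."""
    return sy2 + b * b * sx2 - 2.0 * b * sxy


def _profile_chi2(
    b: float, x: np.ndarray, y: np.ndarray, sx2: np.ndarray, sy2: np.ndarray, sxy: np.ndarray
) -> float:
    """Effective-variance chi-square with the intercept profiled out."""
    denom = _effective_variance(b, sx2, sy2, sxy)
    if np.any(denom <= 0):
        return math.inf
    W = 1.0 / denom
    a = float(np.sum(W * (y - b * x)) / np.sum(W))
    return float(np.sum(W * (y - a - b * x) ** 2))


def fit_second_plot(
    points: Sequence[SecondPlotPoint],
    rel_tol: float = 1e-12,
    max_iter: int = 100,
) -> SecondPlotFit:
    """Effective-variance (York-type) straight-line fit with x and y errors.

    The slope is iterated from the OLS solution; each pass re-weights the
    points by the inverse effective variance σ_y² + b²σ_x² − 2bσ_xy and
    stops when successive slope estimates agree to ``rel_tol`` relative.
    Parameter uncertainties come from the converged weight matrix (York's
    adjusted-abscissa expressions).  With every uncertainty zero the OLS
    closed form is returned directly.
    """
    if len(points) < 3:
        raise IdentifiabilityError(
            f"second-plot fit needs at least 3 points, got {len(points)}"
        )
    x = np.array([p.x for p in points])
    y = np.array([p.y for p in points])
    sx2 = np.array([p.x_unc**2 for p in points])
    sy2 = np.array([p.y_unc**2 for p in points])
    sxy = np.array([p.xy_cov for p in points])
    if np.ptp(x) < 1e-12:
        raise IdentifiabilityError("no x spread in second plot")

    b, a, cov = _line_fit(x, y, None)
    if not (np.any(sx2 > 0) or np.any(sy2 > 0)):
        return SecondPlotFit(
            slope=b,
            intercept=a,
            slope_unc=math.sqrt(max(cov[0, 0], 0.0)),
            intercept_unc=math.sqrt(max(cov[1, 1], 0.0)),
            cov=cov,
            n_points=len(points),
            n_iter=0,
        )

    def york_step(bk: float) -> float:
        denom = _effective_variance(bk, sx2, sy2, sxy)
        if np.any(denom <= 0):
            raise ValueError(
                "non-positive effective variance: per-point uncertainties are "
                "inconsistent (|correlation| >= 1?)"
            )
        W = 1.0 / denom
        xbar = float(np.sum(W * x) / np.sum(W))
        ybar = float(np.sum(W * y) / np.sum(W))
        U = x - xbar
        V = y - ybar
        # York's expansion coefficients; sxy carries the correlation term.
        beta = W * (U * sy2 + bk * V * sx2 - (bk * U + V) * sxy)
        return float(np.sum(W * beta * V) / np.sum(W * beta * U))

    db = math.inf
    b_prev = b
    converged = False
    for it in range(1, max_iter + 1):
        b_new = york_step(b)
        db = abs(b_new - b)
        b_prev, b = b, b_new
        # drive the slope to the floating-point fixed point; cheap and keeps
        # the estimate frame-invariant to well below the stated tolerance
        if db <= 1e-15 * abs(b):
            converged = True
            break
    if not converged and db <= rel_tol * abs(b):
        converged = True
    if not converged:
        # strong per-point correlations can make the fixed-point map
        # oscillate around the chi-square minimum; the stationarity residual
        # g(b) = york_step(b) − b then changes sign between the two cycle
        # iterates, so solve it by bracketed root-finding instead
        from scipy.optimize import brentq

        lo, hi = sorted((b_prev, b))
        try:
            if lo < hi and (york_step(lo) - lo) * (york_step(hi) - hi) < 0:
                b = float(
                    brentq(lambda v: york_step(v) - v, lo, hi, xtol=1e-15, rtol=8.9e-16)
                )
                it = max_iter
                converged = True
        except ValueError:
            pass
    if not converged:
        raise ConvergenceError(
            f"York iteration did not converge in {max_iter} iterations "
            f"(last relative slope change {db / abs(b):.2e})",
            last_iterate=(b, None),
        )

    denom = _effective_variance(b, sx2, sy2, sxy)
    W = 1.0 / denom
    xbar = float(np.sum(W * x) / np.sum(W))
    ybar = float(np.sum(W * y) / np.sum(W))
    a = ybar - b * xbar
    U = x - xbar
    V = y - ybar
    beta = W * (U * sy2 + b * V * sx2 - (b * U + V) * sxy)
    x_adj = xbar + beta
    xbar_adj = float(np.sum(W * x_adj) / np.sum(W))
    u = x_adj - xbar_adj
    var_b = 1.0 / float(np.sum(W * u**2))
    var_a = 1.0 / float(np.sum(W)) + xbar_adj**2 * var_b
    cov_ab = -xbar_adj * var_b
    cov = np.array([[var_b, cov_ab], [cov_ab, var_a]])
    return SecondPlotFit(
        slope=b,
        intercept=a,
        slope_unc=math.sqrt(var_b),
        intercept_unc=math.sqrt(var_a),
        cov=cov,
        n_points=len(points),
        n_iter=it,
    )


def derive_thermochemistry(
    fit: SecondPlotFit,
    ladder: LadderSummary,
    T: float = T_STD,
    site_label: str = "",
) -> EKMResult:
    """Back-substitute the ladder averages to obtain ΔacidH°, ΔacidS°, GA.

    ΔacidH° = slope₂ + ΔacidH°_ref^avg;  Δ(ΔS°) = −R·intercept₂;
    ΔacidS° = Δ(ΔS°) + ΔacidS°_ref^avg;  GA = ΔH − T·ΔS at ``T``.

    Uncertainties are first-order propagated from the second-plot
    covariance with the ladder-average uncertainties added in quadrature.
    The GA variance keeps the slope–intercept covariance term: the fitted
    enthalpy and entropy are strongly anti-correlated and dropping it would
    overstate the GA uncertainty — handling that correlation is the point
    of the decorrelated formulation.
    """
    dH = fit.slope + ladder.dH_avg
    ddS = -R_J * fit.intercept
    dS = ddS + ladder.dS_avg
    ga = ga_from_enthalpy_entropy(dH, dS, T)

    var_dH = fit.cov[0, 0] + ladder.dH_avg_unc**2
    var_dS = R_J**2 * fit.cov[1, 1] + ladder.dS_avg_unc**2
    # ga = slope + dH_avg + (T*R/1000)*intercept - T*dS_avg/1000
    k = T * R_J / 1000.0
    var_ga_fit = fit.cov[0, 0] + k**2 * fit.cov[1, 1] + 2.0 * k * fit.cov[0, 1]
    var_ga = max(var_ga_fit, 0.0) + ladder.dH_avg_unc**2 + (T / 1000.0) ** 2 * ladder.dS_avg_unc**2
    return EKMResult(
        dH=dH,
        dH_unc=math.sqrt(max(var_dH, 0.0)),
        dS=dS,
        dS_unc=math.sqrt(max(var_dS, 0.0)),
        ga=ga,
        ga_unc=math.sqrt(var_ga),
        ddS=ddS,
        site_label=site_label,
        temperature=T,
    )
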