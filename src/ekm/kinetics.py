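"""Stage 1: ln-ratio computation and the first thermokinetic plots.

At each collision energy the log branching ratio ln([A⁻]/[A_ref(i)⁻]) is
regressed on the centered reference deprotonation enthalpy
x_i = ΔacidH°_ref(i) − ΔacidH°_ref^avg.  The line has

    slope      = 1/(R·T_eff)
    intercept  = −[(ΔacidH° − ΔacidH°_ref^avg)/(R·T_eff) − Δ(ΔS°)/R]

so each collision energy yields one "effective temperature" T_eff and one
(slope, intercept) pair that feeds the second-stage regression.  T_eff is a
purely phenomenological regression parameter characterizing the excitation
of the dissociating heterodimers; empirically it rises roughly linearly
with the center-of-mass collision energy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np

from .core import R_KJ, IdentifiabilityError, ReferenceAcid, SchemaError, ladder_summary

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .io import CIDDataset

__all__ = [
    "FirstPlotPoint",
    "FirstPlotFit",
    "TeffCorrelation",
    "center_of_mass_energy",
    "ln_abundance_ratio",
    "build_first_plot_points",
    "fit_first_plot",
    "effective_temperature",
    "fit_teff_vs_ecm",
    "ECM_GROUP_TOL",
]

#: Measurements whose e_cm differ by less than this (eV) are one energy group.
ECM_GROUP_TOL = 1e-6


def center_of_mass_energy(e_lab: float, m_gas: float, dimer_mass: float) -> float:
    """Convert lab-frame ion kinetic energy to the center-of-mass frame.

    E_CM = E_lab · m/(M + m) for collision-gas mass m and heterodimer ion
    mass M (both in Da); always strictly less than E_lab.
    """
    if e_lab <= 0:
        raise ValueError(f"e_lab must be positive, got {e_lab}")
    if m_gas <= 0 or dimer_mass <= 0:
        raise ValueError("masses must be positive")
    return e_lab * m_gas / (dimer_mass + m_gas)


def ln_abundance_ratio(i_analyte: float, i_reference: float) -> float:
    """ln of the fragment branching ratio [A⁻]/[A_ref(i)⁻].

    Under the kinetic-method assumptions this equals ln(k/k_i), the log
    ratio of the two dissociation rate constants.
    """
    if i_analyte <= 0 or i_reference <= 0:
        raise ValueError(
            f"intensities must be positive, got ({i_analyte}, {i_reference})"
        )
    return math.log(i_analyte / i_reference)


@dataclass(frozen=True)
class FirstPlotPoint:
    """One (reference acid, collision energy) point of a first plot.

    ``x`` is the centered reference enthalpy (kJ/mol), ``y`` the replicate
    mean ln branching ratio, ``y_unc`` the standard error of that mean
    (0 for a single replicate).
    """

    x: float
    y: float
    y_unc: float = 0.0
    reference: str = ""

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError("point coordinates must be finite")
        if self.y_unc < 0:
            raise ValueError("y_unc must be non-negative")


@dataclass(frozen=True)
class FirstPlotFit:
    """Per-collision-energy regression of the first thermokinetic plot.

    ``slope`` is 1/(R·T_eff) in mol/kJ, ``cov`` the 2×2 covariance of
    (slope, intercept).  ``t_eff`` is NaN when the fitted slope is not
    positive; such fits are flagged (``ok`` False) and excluded from the
    second stage rather than aborting the pipeline.
    """

    e_cm: float
    slope: float
    intercept: float
    cov: np.ndarray
    t_eff: float
    n_points: int

    @property
    def ok(self) -> bool:
        return self.slope > 0


@dataclass(frozen=True)
class TeffCorrelation:
    """Linear trend of effective temperature with collision energy."""

    a0: float  # K
    a1: float  # K/eV
    r2: float


def build_first_plot_points(
    dataset: "CIDDataset",
    refs: Sequence[ReferenceAcid],
    e_cm_group: float,
    tol: float = ECM_GROUP_TOL,
) -> list[FirstPlotPoint]:
    """Collapse one energy group of a dataset into first-plot points.

    Replicates are averaged on the ln-ratio scale (the scale on which the
    model is linear); ``y_unc`` is the standard error over replicates.
    ``x`` values are centered on the ladder's mean deprotonation enthalpy.
    """
    ladder = ladder_summary(list(refs))
    by_name = {r.name: r for r in refs}

    groups: dict[str, list[float]] = {}
    for m in dataset.measurements:
        if m.e_cm is None or abs(m.e_cm - e_cm_group) > tol:
            continue
        groups.setdefault(m.reference, []).append(
            ln_abundance_ratio(m.i_analyte, m.i_reference)
        )
    if not groups:
        raise ValueError(f"no measurements at e_cm = {e_cm_group} eV")
    missing = sorted(set(groups) - set(by_name))
    if missing:
        raise SchemaError(f"references not in ladder: {', '.join(missing)}")
    if len(groups) < 2:
        raise IdentifiabilityError(
            f"energy group {e_cm_group} eV has fewer than 2 distinct references"
        )

    points = []
    for name in sorted(groups):
        ratios = np.asarray(groups[name])
        y = float(ratios.mean())
        y_unc = (
            float(ratios.std(ddof=1) / math.sqrt(ratios.size))
            if ratios.size > 1
            else 0.0
        )
        points.append(
            FirstPlotPoint(
                x=by_name[name].dH - ladder.dH_avg,
                y=y,
                y_unc=y_unc,
                reference=name,
            )
        )
    return points


def _line_fit(
    x: np.ndarray, y: np.ndarray, w: np.ndarray | None
) -> tuple[float, float, np.ndarray]:
    """Straight-line fit y = b·x + a returning (b, a, cov(b, a)).

    With weights w = 1/σ² the covariance is (XᵀWX)⁻¹ (σ treated as known);
    unweighted, it is the residual-based OLS covariance s²(XᵀX)⁻¹ with
    s² = RSS/(n−2), which vanishes for an exact fit.
    """
    X = np.column_stack([x, np.ones_like(x)])
    if w is not None:
        XtW = X.T * w
        cov = np.linalg.inv(XtW @ X)
        beta = cov @ (XtW @ y)
    else:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        dof = len(x) - 2
        s2 = float(resid @ resid) / dof if dof > 0 else 0.0
        cov = s2 * np.linalg.inv(X.T @ X)
    return float(beta[0]), float(beta[1]), cov


def fit_first_plot(points: Sequence[FirstPlotPoint], e_cm: float) -> FirstPlotFit:
    """Fit one first thermokinetic plot.

    Weighted least squares with weights 1/y_unc² when every point carries a
    positive uncertainty; ordinary least squares otherwise.  A negative
    fitted slope (unphysical T_eff) is not an error here: the fit is
    returned with ``t_eff = NaN`` and ``ok = False``.
    """
    if len(points) < 3:
        raise IdentifiabilityError(
            f"first plot needs at least 3 points, got {len(points)}"
        )
    x = np.array([p.x for p in points])
    y = np.array([p.y for p in points])
    if np.ptp(x) < 1e-12:
        raise IdentifiabilityError("all reference enthalpies identical: rank-deficient")
    y_unc = np.array([p.y_unc for p in points])
    w = 1.0 / y_unc**2 if np.all(y_unc > 0) else None
    slope, intercept, cov = _line_fit(x, y, w)
    t_eff = effective_temperature(slope) if slope > 0 else math.nan
    return FirstPlotFit(
        e_cm=e_cm,
        slope=slope,
        intercept=intercept,
        cov=cov,
        t_eff=t_eff,
        n_points=len(points),
    )


def effective_temperature(slope: float) -> float:
    """T_eff = 1/(R·slope) for a first-plot slope in mol/kJ."""
    if slope <= 0:
        raise ValueError(f"first-plot slope must be positive, got {slope}")
    return 1.0 / (R_KJ * slope)


def fit_teff_vs_ecm(fits: Sequence[FirstPlotFit]) -> TeffCorrelation:
    """OLS trend T_eff = a0 + a1·E_CM across retained (positive-slope) fits.

    r² is 1 − RSS/TSS; for data fitted exactly (including constant T_eff,
    where the fitted slope is 0) it is reported as 1.
    """
    good = [f for f in fits if f.ok]
    e = np.array([f.e_cm for f in good])
    t = np.array([f.t_eff for f in good])
    if len(np.unique(np.round(e / ECM_GROUP_TOL))) < 3:
        raise IdentifiabilityError(
            "T_eff-E_CM correlation needs at least 3 distinct collision energies"
        )
    a1, a0, _ = _line_fit(e, t, None)
    resid = t - (a0 + a1 * e)
    tss = float(np.sum((t - t.mean()) ** 2))
    rss = float(resid @ resid)
    r2 = 1.0 if tss == 0 and rss < 1e-18 else (1.0 - rss / tss if tss > 0 else 0.0)
    return TeffCorrelation(a0=a0, a1=a1, r2=r2)
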