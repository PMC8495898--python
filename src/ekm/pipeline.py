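"""End-to-end composition of the two regression stages."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from .core import EKMResult, ReferenceAcid, T_STD, ladder_summary
from .decorrelation import (
    SecondPlotFit,
    SecondPlotPoint,
    build_second_plot,
    derive_thermochemistry,
    fit_second_plot,
)
from .io import CIDDataset
from .kinetics import (
    FirstPlotFit,
    FirstPlotPoint,
    TeffCorrelation,
    build_first_plot_points,
    fit_first_plot,
    fit_teff_vs_ecm,
)

__all__ = ["PipelineResult", "analyze_dataset"]

log = logging.getLogger("ekm")


@dataclass
class PipelineResult:
    """Everything the two-stage analysis produces, including diagnostics."""

    result: EKMResult
    first_points: dict[float, list[FirstPlotPoint]]
    first_fits: list[FirstPlotFit]
    second_points: list[SecondPlotPoint]
    second_fit: SecondPlotFit
    teff_correlation: TeffCorrelation | None
    warnings: list[str] = field(default_factory=list)


def analyze_dataset(
    dataset: CIDDataset,
    refs: Sequence[ReferenceAcid],
    T: float = T_STD,
    site_label: str | None = None,
) -> PipelineResult:
    """Run stages 1–2 on a dataset and derive the analyte thermochemistry.

    Per collision energy, the first thermokinetic plot is built and fitted;
    fits with a non-positive slope (negative effective temperature) are
    excluded from stage 2 with a logged warning.  The retained
    (slope, intercept) pairs form the second plot, fitted with errors in
    both variables, and the ladder averages are back-substituted.
    """
    warnings: list[str] = []
    ladder = ladder_summary(list(refs))

    first_points: dict[float, list[FirstPlotPoint]] = {}
    fits: list[FirstPlotFit] = []
    for e_cm in dataset.e_cm_groups:
        points = build_first_plot_points(dataset, refs, e_cm)
        fit = fit_first_plot(points, e_cm)
        first_points[e_cm] = points
        fits.append(fit)
        if not fit.ok:
            msg = (
                f"first plot at E_CM = {e_cm:g} eV has non-positive slope "
                f"({fit.slope:.4g} mol/kJ); excluded from stage 2"
            )
            warnings.append(msg)
            log.warning(msg)

    teff_corr: TeffCorrelation | None
    try:
        teff_corr = fit_teff_vs_ecm(fits)
    except Exception as exc:  # diagnostic only; never fatal
        teff_corr = None
        warnings.append(f"T_eff-E_CM correlation unavailable: {exc}")

    points2 = build_second_plot(fits)
    fit2 = fit_second_plot(points2)
    label = dataset.site_label if site_label is None else site_label
    result = derive_thermochemistry(fit2, ladder, T=T, site_label=label)
    return PipelineResult(
        result=result,
        first_points=first_points,
        first_fits=fits,
        second_points=points2,
        second_fit=fit2,
        teff_correlation=teff_corr,
        warnings=warnings,
    )
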