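"""Figure generation for the thermokinetic plots (headless-safe)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .pipeline import PipelineResult

__all__ = ["save_figures"]


def save_figures(pr: PipelineResult, outdir: str | Path, stem: str = "ekm") -> list[Path]:
    """Write first-plot, second-plot, and T_eff–E_CM figures as PNG."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    fig, ax = plt.subplots(figsize=(5, 4))
    for fit in pr.first_fits:
        pts = pr.first_points[fit.e_cm]
        x = np.array([p.x for p in pts])
        y = np.array([p.y for p in pts])
        yerr = np.array([p.y_unc for p in pts])
        label = f"{fit.e_cm:g} eV"
        ax.errorbar(x, y, yerr=yerr, fmt="o", ms=4, capsize=2, label=label)
        xs = np.linspace(x.min(), x.max(), 2)
        ax.plot(xs, fit.slope * xs + fit.intercept, lw=0.8, color="gray")
    ax.set_xlabel(r"$\Delta_{acid}H^\circ_{ref(i)} - \Delta_{acid}H^{avg}_{ref}$ (kJ/mol)")
    ax.set_ylabel(r"ln([A$^-$]/[A$_{ref}^-$])")
    ax.legend(fontsize=7, title="$E_{CM}$")
    fig.tight_layout()
    p = outdir / f"{stem}_first_plots.png"
    fig.savefig(p, dpi=150)
    plt.close(fig)
    written.append(p)

    fig, ax = plt.subplots(figsize=(5, 4))
    x = np.array([pt.x for pt in pr.second_points])
    y = np.array([pt.y for pt in pr.second_points])
    ax.errorbar(
        x,
        y,
        xerr=[pt.x_unc for pt in pr.second_points],
        yerr=[pt.y_unc for pt in pr.second_points],
        fmt="o",
        ms=4,
        capsize=2,
    )
    xs = np.linspace(x.min(), x.max(), 2)
    f2 = pr.second_fit
    ax.plot(xs, f2.slope * xs + f2.intercept, color="C1")
    ax.set_xlabel(r"$1/(R\,T_{eff})$ (mol/kJ)")
    ax.set_ylabel("negated first-plot intercept")
    fig.tight_layout()
    p = outdir / f"{stem}_second_plot.png"
    fig.savefig(p, dpi=150)
    plt.close(fig)
    written.append(p)

    if pr.teff_correlation is not None:
        fig, ax = plt.subplots(figsize=(5, 4))
        e = np.array([f.e_cm for f in pr.first_fits if f.ok])
        t = np.array([f.t_eff for f in pr.first_fits if f.ok])
        ax.plot(e, t, "o")
        c = pr.teff_correlation
        xs = np.linspace(e.min(), e.max(), 2)
        ax.plot(xs, c.a0 + c.a1 * xs, color="C1", label=f"$r^2$ = {c.r2:.4f}")
        ax.set_xlabel(r"$E_{CM}$ (eV)")
        ax.set_ylabel(r"$T_{eff}$ (K)")
        ax.legend()
        fig.tight_layout()
        p = outdir / f"{stem}_teff_vs_ecm.png"
        fig.savefig(p, dpi=150)
        plt.close(fig)
        written.append(p)
    return written
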