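"""Shared fixtures and independent regression oracles."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from ekm import ReferenceAcid, SyntheticConfig, simulate_dataset


@pytest.fixture
def high_ladder():
    from ekm import default_high_ga_ladder

    return default_high_ga_ladder()


@pytest.fixture
def zero_noise_config():
    return dataclasses.replace(SyntheticConfig(), noise_sd=0.0)


@pytest.fixture
def zero_noise_dataset(zero_noise_config):
    return simulate_dataset(zero_noise_config)


def write_ladder_csv(refs, path):
    lines = ["name,dH_kJmol,dH_unc_kJmol,dS_JmolK,dS_unc_JmolK,GA_kJmol"]
    for r in refs:
        ga = "" if r.ga is None else repr(r.ga)
        lines.append(
            f"{r.name},{r.dH!r},{r.dH_unc!r},{r.dS!r},{r.dS_unc!r},{ga}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def random_zero_noise_config(rng: np.random.Generator) -> SyntheticConfig:
    """An admissible zero-noise design with a shared-entropy ladder.

    Ladders honour the method's similar-reference-entropy assumption; the
    design always has ≥ 3 rungs (one first-plot fit needs ≥ 3 points),
    ≥ 3 energies, and a non-constant effective temperature.
    """
    n_refs = int(rng.integers(3, 7))
    center = rng.uniform(1340.0, 1430.0)
    span = rng.uniform(10.0, 40.0)
    dH = center + np.linspace(-span / 2, span / 2, n_refs)
    dH += rng.uniform(-span / (4 * n_refs), span / (4 * n_refs), size=n_refs)
    dS_ref = rng.uniform(80.0, 110.0)
    refs = tuple(
        ReferenceAcid(f"ref{i}", float(h), float(dS_ref)) for i, h in enumerate(dH)
    )
    n_e = int(rng.integers(3, 9))
    e_grid = tuple(np.linspace(rng.uniform(0.5, 1.0), rng.uniform(2.5, 4.5), n_e))
    return SyntheticConfig(
        dH_true=float(center + rng.uniform(-15, 15)),
        dS_true=float(rng.uniform(80.0, 130.0)),
        refs=refs,
        e_cm_grid=e_grid,
        teff_t0=float(rng.uniform(350.0, 700.0)),
        teff_t1=float(rng.uniform(50.0, 250.0)),
        noise_sd=0.0,
        n_replicates=int(rng.integers(1, 3)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def ols_oracle(x, y, w=None):
    """Closed-form (weighted) normal-equations line fit: returns (slope, intercept)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    w = np.ones_like(x) if w is None else np.asarray(w, float)
    sw, swx, swy = w.sum(), (w * x).sum(), (w * y).sum()
    swxx, swxy = (w * x * x).sum(), (w * x * y).sum()
    delta = sw * swxx - swx**2
    slope = (sw * swxy - swx * swy) / delta
    intercept = (swxx * swy - swx * swxy) / delta
    return slope, intercept


def york_chi2_oracle(x, y, sx, sy, sxy, b_window=5.0):
    """Brute-force effective-variance chi-square minimizer.

    Profiles the intercept out analytically and minimizes over the slope
    with a bounded scalar search — an independent route to the same
    objective the iterative fit solves.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    sx2, sy2 = np.asarray(sx, float) ** 2, np.asarray(sy, float) ** 2
    sxy = np.asarray(sxy, float)

    def chi2(b):
        w = 1.0 / (sy2 + b * b * sx2 - 2.0 * b * sxy)
        a = np.sum(w * (y - b * x)) / np.sum(w)
        return float(np.sum(w * (y - a - b * x) ** 2))

    b0, _ = ols_oracle(x, y)
    res = minimize_scalar(
        chi2,
        bounds=(b0 - b_window, b0 + b_window),
        method="bounded",
        options={"xatol": 1e-13},
    )
    b = float(res.x)
    w = 1.0 / (sy2 + b * b * sx2 - 2.0 * b * sxy)
    a = float(np.sum(w * (y - b * x)) / np.sum(w))
    return b, a
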