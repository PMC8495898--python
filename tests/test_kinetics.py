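"""Energy conversion, ln-ratios, and the first thermokinetic plots."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ekm import (
    FirstPlotPoint,
    IdentifiabilityError,
    R_KJ,
    ReferenceAcid,
    SyntheticConfig,
    build_first_plot_points,
    center_of_mass_energy,
    effective_temperature,
    fit_first_plot,
    fit_teff_vs_ecm,
    ln_abundance_ratio,
    simulate_dataset,
)

from conftest import ols_oracle

pos = st.floats(min_value=1e-3, max_value=1e6, allow_nan=False)


class TestCenterOfMassEnergy:
    def test_equal_masses_halve_the_energy(self):
        assert center_of_mass_energy(2.0, 100.0, 100.0) == pytest.approx(1.0)

    def test_argon_on_heterodimer(self):
        # hand evaluation: 10.0 * 39.948 / (282.6 + 39.948)
        assert center_of_mass_energy(10.0, 39.948, 282.6) == pytest.approx(
            1.2385, abs=1e-4
        )

    def test_massless_target_limit(self):
        assert center_of_mass_energy(10.0, 1e-12, 282.6) == pytest.approx(0.0, abs=1e-12)

    @given(e=pos, m=pos, M=pos)
    @settings(max_examples=100, deadline=None)
    def test_always_below_lab_energy(self, e, m, M):
        assert center_of_mass_energy(e, m, M) < e

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            center_of_mass_energy(-1.0, 39.948, 282.6)
        with pytest.raises(ValueError):
            center_of_mass_energy(1.0, 0.0, 282.6)


class TestLnAbundanceRatio:
    def test_equal_channels(self):
        assert ln_abundance_ratio(1000.0, 1000.0) == 0.0

    def test_e_fold(self):
        assert ln_abundance_ratio(2718.28, 1000.0) == pytest.approx(1.0, abs=1e-4)

    @given(a=pos, b=pos)
    @settings(max_examples=100, deadline=None)
    def test_antisymmetric(self, a, b):
        assert ln_abundance_ratio(a, b) == pytest.approx(
            -ln_abundance_ratio(b, a), abs=1e-12
        )

    def test_rejects_nonpositive_intensity(self):
        with pytest.raises(ValueError):
            ln_abundance_ratio(0.0, 10.0)


class TestBuildFirstPlotPoints:
    def test_one_point_per_reference_with_replicate_scatter(self, high_ladder):
        cfg = SyntheticConfig(seed=7)
        ds = simulate_dataset(cfg)
        e0 = ds.e_cm_groups[0]
        pts = build_first_plot_points(ds, high_ladder, e0)
        assert len(pts) == 4
        assert all(p.y_unc > 0 for p in pts)  # 2 replicates each

    def test_centering_yields_zero_x_at_ladder_mean(self):
        refs = [ReferenceAcid("a", 1330.0, 95.0), ReferenceAcid("b", 1340.0, 95.0),
                ReferenceAcid("c", 1335.0, 95.0)]
        cfg = SyntheticConfig(
            dH_true=1335.0, dS_true=95.0, refs=tuple(refs), noise_sd=0.0
        )
        ds = simulate_dataset(cfg)
        pts = build_first_plot_points(ds, refs, ds.e_cm_groups[0])
        x_by_name = {p.reference: p.x for p in pts}
        assert x_by_name["c"] == pytest.approx(0.0, abs=1e-12)

    def test_zero_noise_points_are_collinear(self, zero_noise_config, zero_noise_dataset):
        refs = list(zero_noise_config.refs)
        pts = build_first_plot_points(
            zero_noise_dataset, refs, zero_noise_dataset.e_cm_groups[3]
        )
        x = np.array([p.x for p in pts])
        y = np.array([p.y for p in pts])
        slope, intercept = ols_oracle(x, y)
        rss = float(np.sum((y - slope * x - intercept) ** 2))
        assert rss < 1e-18


class TestFitFirstPlot:
    def test_exact_line_recovers_slope_intercept_and_teff(self):
        pts = [FirstPlotPoint(x, 0.403 * x + 0.7) for x in (-10.0, -2.0, 5.0, 11.0)]
        fit = fit_first_plot(pts, e_cm=1.0)
        assert fit.slope == pytest.approx(0.403, abs=1e-12)
        assert fit.intercept == pytest.approx(0.7, abs=1e-12)
        assert fit.t_eff == pytest.approx(1.0 / (0.0083145 * 0.403), rel=1e-12)
        assert fit.t_eff == pytest.approx(298.4, abs=0.1)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = int(rng.integers(3, 9))
            x = rng.uniform(-20, 20, n)
            x[1] = x[0] + 5.0  # guarantee spread
            y = rng.normal(size=n)
            fit = fit_first_plot(
                [FirstPlotPoint(float(a), float(b)) for a, b in zip(x, y)], 1.0
            )
            b_or, a_or = ols_oracle(x, y)
            assert fit.slope == pytest.approx(b_or, abs=1e-10)
            assert fit.intercept == pytest.approx(a_or, abs=1e-10)

    def test_weighted_fit_matches_weighted_oracle(self):
        rng = np.random.default_rng(13)
        x = rng.uniform(-15, 15, 6)
        y = 0.2 * x + rng.normal(size=6)
        u = rng.uniform(0.05, 0.5, 6)
        pts = [FirstPlotPoint(float(a), float(b), float(s)) for a, b, s in zip(x, y, u)]
        fit = fit_first_plot(pts, 1.0)
        b_or, a_or = ols_oracle(x, y, w=1.0 / u**2)
        assert fit.slope == pytest.approx(b_or, abs=1e-10)
        assert fit.intercept == pytest.approx(a_or, abs=1e-10)

    @given(c=st.floats(min_value=-50, max_value=50, allow_nan=False))
    @settings(max_examples=50, deadline=None)
    def test_translation_shifts_intercept_only(self, c):
        rng = np.random.default_rng(3)
        x = rng.uniform(-10, 10, 5)
        y = 0.15 * x + rng.normal(size=5)
        f0 = fit_first_plot([FirstPlotPoint(float(a), float(b)) for a, b in zip(x, y)], 1.0)
        f1 = fit_first_plot(
            [FirstPlotPoint(float(a + c), float(b)) for a, b in zip(x, y)], 1.0
        )
        assert f1.slope == pytest.approx(f0.slope, abs=1e-9)
        assert f1.intercept == pytest.approx(f0.intercept - f0.slope * c, abs=1e-8)

    def test_two_points_underdetermined(self):
        with pytest.raises(IdentifiabilityError):
            fit_first_plot([FirstPlotPoint(0.0, 0.0), FirstPlotPoint(1.0, 1.0)], 1.0)

    def test_identical_x_rank_deficient(self):
        pts = [FirstPlotPoint(2.0, float(v)) for v in (0.0, 1.0, 2.0)]
        with pytest.raises(IdentifiabilityError):
            fit_first_plot(pts, 1.0)

    def test_negative_slope_flagged_not_fatal(self):
        pts = [FirstPlotPoint(x, -0.1 * x) for x in (-10.0, 0.0, 10.0)]
        fit = fit_first_plot(pts, 1.0)
        assert not fit.ok
        assert math.isnan(fit.t_eff)


class TestEffectiveTemperature:
    def test_inverse_identity(self):
        assert effective_temperature(1.0 / (R_KJ * 500.0)) == pytest.approx(500.0)

    def test_rejects_nonpositive_slope(self):
        with pytest.raises(ValueError):
            effective_temperature(-0.1)
        with pytest.raises(ValueError):
            effective_temperature(0.0)


class TestTeffVsEcm:
    def _fits(self, e, t):
        out = []
        for ei, ti in zip(e, t):
            slope = 1.0 / (R_KJ * ti)
            out.append(
                fit_first_plot(
                    [FirstPlotPoint(x, slope * x) for x in (-10.0, 0.0, 10.0)], ei
                )
            )
        return out

    def test_exact_linear_trend_r2_one(self):
        e = [1.0, 2.0, 3.0, 4.0]
        t = [600.0 + 150.0 * x for x in e]
        corr = fit_teff_vs_ecm(self._fits(e, t))
        assert corr.a0 == pytest.approx(600.0, rel=1e-9)
        assert corr.a1 == pytest.approx(150.0, rel=1e-9)
        assert corr.r2 == pytest.approx(1.0, abs=1e-12)

    def test_constant_teff_zero_slope(self):
        corr = fit_teff_vs_ecm(self._fits([1.0, 2.0, 3.0], [800.0, 800.0, 800.0]))
        assert corr.a1 == pytest.approx(0.0, abs=1e-9)

    def test_synthetic_trend_recovered_at_zero_noise(self, zero_noise_config):
        from ekm import analyze_dataset, simulate_dataset

        pr = analyze_dataset(
            simulate_dataset(zero_noise_config), list(zero_noise_config.refs)
        )
        corr = pr.teff_correlation
        assert corr.a0 == pytest.approx(zero_noise_config.teff_t0, rel=1e-6)
        assert corr.a1 == pytest.approx(zero_noise_config.teff_t1, rel=1e-6)

    def test_needs_three_distinct_energies(self):
        with pytest.raises(IdentifiabilityError):
            fit_teff_vs_ecm(self._fits([1.0, 2.0], [650.0, 800.0]))
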