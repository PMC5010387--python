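"""Dimerization isotherm evaluation, fitting and thermodynamics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lipodimer.density import ConversionConstants
from lipodimer.fdimer import FdimerPoint
from lipodimer.isotherm import (
    IsothermRegressor,
    delta_delta_g,
    fit_isotherm,
    free_energy,
    isotherm_fdimer,
    thermo_summary,
)


class TestIsothermEvaluation:
    def test_half_saturation_identity(self):
        """At chi* K = 1 the dimer fraction is exactly (1+4-sqrt(9))/4."""
        assert isotherm_fdimer(1e-6, 1e6) == pytest.approx(0.5, abs=1e-12)

    def test_biological_lower_bound_density(self):
        """chi* = 2e-7 with K = 2.1e8 puts 90% of subunits in dimers."""
        f = isotherm_fdimer(2e-7, 2.1e8)
        assert f == pytest.approx(0.897, abs=5e-4)
        assert round(100 * f) == 90

    def test_limits(self):
        assert isotherm_fdimer(0.0, 1e6) == 0.0
        assert isotherm_fdimer(0.0, 1e6, y0=0.07) == pytest.approx(0.07)
        assert isotherm_fdimer(1e3, 1e6) == pytest.approx(1.0, abs=1e-4)
        assert isotherm_fdimer(1e3, 1e6) < 1.0

    @given(chi=st.floats(1e-12, 1e-3), k=st.floats(1e2, 1e10),
           y0=st.floats(0.0, 0.5))
    @settings(max_examples=80, derandomize=True)
    def test_baseline_affine_identity(self, chi, k, y0):
        assert isotherm_fdimer(chi, k, y0) == pytest.approx(
            y0 + (1 - y0) * isotherm_fdimer(chi, k), rel=1e-12
        )

    @given(chi=st.floats(1e-12, 1e-3), k=st.floats(1e2, 1e10))
    @settings(max_examples=80, derandomize=True)
    def test_mass_conservation(self, chi, k):
        """Splitting chi* into monomer and dimer pools by F reconstructs
        the equilibrium constant (and total mass) exactly."""
        f = isotherm_fdimer(chi, k)
        chi_m = (1 - f) * chi
        chi_d = f * chi / 2.0
        assert chi_m + 2 * chi_d == pytest.approx(chi, rel=1e-12)
        assert chi_d / chi_m**2 == pytest.approx(k, rel=1e-6)

    def test_monotone_in_chi_and_k(self):
        grid = np.logspace(-10, -4, 30)
        f = isotherm_fdimer(grid, 3.7e6)
        assert np.all(np.diff(f) > 0)
        assert isotherm_fdimer(1e-7, 1e7) > isotherm_fdimer(1e-7, 1e6)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            isotherm_fdimer(1e-6, 0.0)
        with pytest.raises(ValueError):
            isotherm_fdimer(1e-6, 1e6, y0=1.0)


class TestFreeEnergy:
    def test_printed_single_tryptophan_value(self):
        assert free_energy(3.7e6) == pytest.approx(-8.956, abs=1e-3)
        assert round(free_energy(3.7e6), 1) == -9.0

    def test_printed_double_tryptophan_value(self):
        assert free_energy(2.1e5) == pytest.approx(-7.257, abs=1e-3)
        assert round(free_energy(2.1e5), 1) == -7.3

    def test_standard_state(self):
        assert free_energy(1.0) == 0.0

    def test_difference_consistency(self):
        k1, k2, t = 3.7e6, 2.1e5, 298.0
        direct = free_energy(k1) - free_energy(k2)
        assert direct == pytest.approx(
            -1.9872036 * t * math.log(k1 / k2) / 1000.0, rel=1e-12
        )

    def test_nonpositive_k_rejected(self):
        with pytest.raises(ValueError):
            free_energy(0.0)


class TestDeltaDeltaG:
    def test_printed_differences(self):
        assert delta_delta_g(-9.0, -11.4) == pytest.approx(2.4)
        assert delta_delta_g(-7.3, -11.4) == pytest.approx(4.1)

    def test_antisymmetric_and_zero(self):
        assert delta_delta_g(-9.0, -7.3) == -delta_delta_g(-7.3, -9.0)
        assert delta_delta_g(-9.0, -9.0) == 0.0


class TestThermoSummary:
    def test_printed_double_tryptophan_row(self):
        s = thermo_summary(2.1e5)
        assert s.k_rho == pytest.approx(6.3e4)
        assert round(s.eq_box) == 251

    def test_printed_single_tryptophan_dissociation(self):
        s = thermo_summary(3.7e6)
        assert s.kd_chi == pytest.approx(2.70e-7, abs=5e-9)

    def test_unit_case(self):
        s = thermo_summary(1.0, ConversionConstants(sa_lipid=0.6))
        assert s.k_rho == pytest.approx(0.3)
        assert s.eq_box == pytest.approx(math.sqrt(0.3))

    def test_reciprocal_invariants(self):
        s = thermo_summary(5.5e6)
        assert s.kd_chi * s.k_chi == pytest.approx(1.0, rel=1e-12)
        assert s.kd_rho * s.k_rho == pytest.approx(1.0, rel=1e-12)
        assert s.eq_box**2 == pytest.approx(s.k_rho, rel=1e-12)


def noise_free_points(k, y0, n=10):
    chi = np.logspace(-9, -5, n)
    f = isotherm_fdimer(chi, k, y0)
    return [FdimerPoint(chi_star=c, f_dimer=v, r2_min=1e-4, weight=1e4)
            for c, v in zip(chi, f)]


class TestFitIsotherm:
    def test_noise_free_self_consistency(self):
        fit = fit_isotherm(noise_free_points(3.7e6, 0.07))
        assert fit.k_chi_star == pytest.approx(3.7e6, rel=1e-3)
        assert fit.y0 == pytest.approx(0.07, abs=1e-4)
        assert fit.ci95_k[0] <= fit.k_chi_star <= fit.ci95_k[1]
        assert fit.converged

    def test_fixed_baseline(self):
        fit = fit_isotherm(noise_free_points(2.1e8, 0.07), fix_y0=0.07)
        assert fit.fixed_y0
        assert fit.y0 == 0.07
        assert fit.k_chi_star == pytest.approx(2.1e8, rel=1e-3)

    def test_array_interface(self):
        chi = np.logspace(-8, -5, 8)
        f = isotherm_fdimer(chi, 1e6, 0.0)
        fit = fit_isotherm((chi, f))
        assert fit.k_chi_star == pytest.approx(1e6, rel=1e-3)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_isotherm(noise_free_points(3.7e6, 0.0, n=2))

    def test_narrow_span_rejected(self):
        chi = np.array([1e-7, 1.5e-7, 2e-7])
        with pytest.raises(ValueError, match="decade"):
            fit_isotherm((chi, isotherm_fdimer(chi, 3.7e6)))

    def test_all_monomer_data_rejected(self):
        chi = np.logspace(-10, -8, 6)
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_isotherm((chi, np.full(6, 0.001)))

    def test_weight_floor_insensitivity(self, radius_dist, yields):
        """Flooring R² before inversion moves the fitted K by less than
        one standard error on a synthetic reference set."""
        from lipodimer.fdimer import titration_fdimer
        from lipodimer.synthetic import generate_titration

        ds = generate_titration(
            3.7e6, y0=0.07, chi_list=np.logspace(-9, -5, 8), n_spots=300,
            mode="mixture", seed=5, n_replicates=3, yields=yields,
            radius_dist=radius_dist,
        )
        pts = titration_fdimer(ds.chi_star, ds.counts, yields=yields,
                               radius_dist=radius_dist)
        floored = fit_isotherm(pts)
        raw_weights = np.array([1.0 / max(p.r2_min, 1e-300) for p in pts])
        unfloored = fit_isotherm(pts, weights=raw_weights)
        assert abs(unfloored.log10_k - floored.log10_k) < floored.se_log10_k


class TestIsothermRegressor:
    def test_fit_predict_round_trip(self):
        chi = np.logspace(-9, -5, 12)
        f = isotherm_fdimer(chi, 3.7e6, 0.05)
        reg = IsothermRegressor().fit(chi.reshape(-1, 1), f)
        assert reg.k_chi_ == pytest.approx(3.7e6, rel=1e-3)
        np.testing.assert_allclose(
            reg.predict(chi.reshape(-1, 1)), f, atol=1e-6
        )

    def test_sklearn_plumbing(self):
        from sklearn.base import clone

        reg = IsothermRegressor(fix_y0=0.07)
        assert clone(reg).get_params()["fix_y0"] == 0.07
        with pytest.raises(AttributeError):
            IsothermRegressor().predict([[1e-7]])

    def test_thermo_summary_from_fit(self):
        chi = np.logspace(-8, -4, 10)
        reg = IsothermRegressor().fit(chi, isotherm_fdimer(chi, 2.1e5))
        s = reg.thermo_summary()
        assert s.k_rho == pytest.approx(6.3e4, rel=1e-2)
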