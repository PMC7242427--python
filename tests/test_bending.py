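import numpy as np
import pytest

from memswell.bending import (
    BendingParams,
    ObservedBending,
    bending_from_stretching,
    el_residual,
    fit_bending_constants,
    helfrich_energy,
    solve_inverse_bending,
)
from memswell.geometry import EllipsoidShape, curvature_field, ellipsoid_volume

KC = 1.38e-5  # erg, the preset bending modulus of the 0 mM shape
KD = 0.71e-5


@pytest.fixture(scope="module")
def oblate_field():
    return curvature_field(EllipsoidShape(8.0, 2.0), 200)


@pytest.fixture(scope="module")
def sphere_field():
    return curvature_field(EllipsoidShape(2.0, 2.0), 64)


class TestEnergy:
    def test_sphere_scale_invariant_closed_form(self):
        # 8 pi k_c + 4 pi k_d for any radius (Gauss-Bonnet)
        params = BendingParams(KC, KD)
        expected = 8 * np.pi * KC + 4 * np.pi * KD
        for R in (0.5, 2.0, 10.0):
            f = curvature_field(EllipsoidShape(R, R), 64)
            assert helfrich_energy(f, params) == pytest.approx(expected, rel=1e-12)

    def test_pure_pressure_term(self, oblate_field):
        # with vanishing moduli and tension only the p V term remains
        params = BendingParams(k_c=0.0, k_d=0.0)
        V = ellipsoid_volume(oblate_field.shape)
        p = 7.5  # Pa
        assert helfrich_energy(oblate_field, params, lam=0.0, dp=p) == pytest.approx(
            p * 1e-11 * V, rel=1e-12
        )

    def test_linearity_in_moduli(self, oblate_field):
        e1 = helfrich_energy(oblate_field, BendingParams(KC, 0.0))
        e2 = helfrich_energy(oblate_field, BendingParams(2 * KC, 0.0))
        assert e2 == pytest.approx(2 * e1, rel=1e-12)

    def test_first_variation_sign_matches_residual(self):
        # sphere, lam = 0, dp > 0: residual = dp > 0 and enlarging the
        # sphere raises F through the pressure term (bending part is
        # scale-invariant), so the signs agree
        params = BendingParams(KC, KD)
        dp = 5.0
        R, eps = 2.0, 1e-4
        f0 = curvature_field(EllipsoidShape(R, R), 64)
        res = el_residual(f0, params, lam=0.0, dp=dp)
        Fm = helfrich_energy(curvature_field(EllipsoidShape(R - eps, R - eps), 64),
                             params, 0.0, dp)
        Fp = helfrich_energy(curvature_field(EllipsoidShape(R + eps, R + eps), 64),
                             params, 0.0, dp)
        assert np.all(res > 0) and Fp - Fm > 0


class TestResidual:
    def test_sphere_laplace_law_exact(self, sphere_field):
        # dp = 2 lam / R solves the shape equation identically on a
        # sphere: 2H^2 - 2K = 0 and lap H = 0
        lam = 1e-4  # N/m
        R_m = 2.0 * 1e-6
        res = el_residual(sphere_field, BendingParams(KC, KD), lam, 2 * lam / R_m)
        assert np.abs(res).max() < 1e-8 * (2 * lam / R_m)

    def test_sphere_constant_offset(self, sphere_field):
        lam, R_m = 1e-4, 2.0e-6
        res = el_residual(sphere_field, BendingParams(KC, KD), lam, 2 * lam / R_m + 3.0)
        assert res == pytest.approx(3.0, rel=1e-9)

    def test_zero_modulus_reduction(self, oblate_field):
        lam, dp = 2e-4, 11.0
        res = el_residual(oblate_field, BendingParams(0.0, 0.0), lam, dp)
        expected = dp - 2 * lam * oblate_field.H * 1e6
        assert np.allclose(res, expected, rtol=1e-12)


class TestInverseSolve:
    def test_sphere_constrained_recovers_laplace_pressure(self, sphere_field):
        lam = 1e-4
        sol = solve_inverse_bending(sphere_field, BendingParams(KC, KD), lam_fixed=lam)
        assert sol.dp == pytest.approx(2 * lam / 2.0e-6, rel=1e-8)

    def test_sphere_free_solve_flagged_degenerate(self, sphere_field):
        sol = solve_inverse_bending(sphere_field, BendingParams(KC, KD))
        assert sol.degenerate
        assert sol.condition_number > 1e8

    def test_oblate_solve_reports_condition_number(self, oblate_field):
        sol = solve_inverse_bending(oblate_field, BendingParams(KC, KD))
        assert np.isfinite(sol.condition_number) and sol.condition_number > 1
        assert not sol.degenerate
        assert sol.residual_rms >= 0

    def test_homogeneous_linearity_in_moduli(self, oblate_field):
        s = 3.0
        sol1 = solve_inverse_bending(oblate_field, BendingParams(KC, KD))
        sol2 = solve_inverse_bending(oblate_field, BendingParams(s * KC, s * KD))
        assert sol2.dp == pytest.approx(s * sol1.dp, rel=1e-10)
        assert sol2.lam == pytest.approx(s * sol1.lam, rel=1e-10)

    def test_grid_refinement_stability(self):
        shape = EllipsoidShape(8.0, 2.0)
        params = BendingParams(KC, KD)
        dp_n = solve_inverse_bending(curvature_field(shape, 200), params).dp
        dp_2n = solve_inverse_bending(curvature_field(shape, 400), params).dp
        assert dp_2n == pytest.approx(dp_n, rel=1e-3)

    def test_pressure_magnitude_decreases_with_volume(self, equilibrium_shapes):
        # the fitted bending pressure relaxes monotonically as the cell
        # swells across the six preset equilibrium shapes
        params = BendingParams(KC, KD)
        mags = [
            abs(solve_inverse_bending(curvature_field(s, 200), params).dp)
            for s in equilibrium_shapes
        ]
        assert np.all(np.diff(mags) < 0)


class TestSheetRelation:
    def test_reference_value(self):
        # g = 0.0101 dyn/nm = 101 N/m, h = 4 nm, nu = 0.5
        kc = bending_from_stretching(101.0, 4.0, 0.5)
        assert kc == pytest.approx(101.0 * 16e-18 / 9.0 * 1e7, rel=1e-12)
        assert kc == pytest.approx(1.7956e-9, rel=1e-4)

    def test_scalings(self):
        assert bending_from_stretching(202.0, 4.0, 0.5) == pytest.approx(
            2 * bending_from_stretching(101.0, 4.0, 0.5)
        )
        assert bending_from_stretching(101.0, 8.0, 0.5) == pytest.approx(
            4 * bending_from_stretching(101.0, 4.0, 0.5)
        )
        ratio = bending_from_stretching(101.0, 4.0, 0.0) / bending_from_stretching(
            101.0, 4.0, 0.5
        )
        assert ratio == pytest.approx(0.75, rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bending_from_stretching(101.0, 0.0, 0.3)
        with pytest.raises(ValueError):
            bending_from_stretching(101.0, 4.0, 0.7)


class TestConstantFit:
    def _observations(self, shapes, true_params):
        obs = []
        for s in shapes:
            f = curvature_field(s, 200)
            sol = solve_inverse_bending(f, true_params)
            F = helfrich_energy(f, true_params, sol.lam, sol.dp)
            obs.append(
                ObservedBending(dp=sol.dp, energy=F, lam=sol.lam,
                                volume=ellipsoid_volume(s))
            )
        return obs

    def test_synthetic_recovery_within_one_percent(self, equilibrium_shapes):
        true = BendingParams(KC, KD)
        obs = self._observations(equilibrium_shapes, true)
        start = BendingParams(2.5e-5, 1.5e-5)
        fitted = fit_bending_constants(equilibrium_shapes, start, obs)
        assert fitted.k_c == pytest.approx(true.k_c, rel=0.01)
        assert fitted.k_d == pytest.approx(true.k_d, rel=0.01)

    def test_objective_improves_from_start(self, equilibrium_shapes):
        true = BendingParams(KC, KD)
        obs = self._observations(equilibrium_shapes, true)
        start = BendingParams(3e-5, 2e-5)
        fitted = fit_bending_constants(equilibrium_shapes, start, obs)
        # the fit moved decisively toward the truth from a distant start
        assert abs(fitted.k_c - true.k_c) < 0.1 * abs(start.k_c - true.k_c)

    def test_modulus_stable_across_shape_subsets(self, equilibrium_shapes):
        # fitting disjoint shape subsets recovers the same k_c (< 5% spread)
        true = BendingParams(KC, KD)
        start = BendingParams(2e-5, 1e-5)
        kcs = []
        for subset in (equilibrium_shapes[:3], equilibrium_shapes[3:]):
            obs = self._observations(subset, true)
            kcs.append(fit_bending_constants(subset, start, obs).k_c)
        assert abs(kcs[0] - kcs[1]) / np.mean(kcs) < 0.05

    def test_gaussian_modulus_needs_energy_observations(self, equilibrium_shapes):
        # without energies the shape equation carries no k_d information
        true = BendingParams(KC, KD)
        obs = [
            ObservedBending(dp=solve_inverse_bending(curvature_field(s, 200), true).dp)
            for s in equilibrium_shapes
        ]
        start = BendingParams(2e-5, 1e-5)
        fitted = fit_bending_constants(equilibrium_shapes, start, obs)
        assert fitted.k_c == pytest.approx(true.k_c, rel=0.01)
        assert fitted.k_d == start.k_d

    def test_preconditions(self, equilibrium_shapes):
        with pytest.raises(ValueError):
            fit_bending_constants([equilibrium_shapes[0]], BendingParams(KC), [])
        with pytest.raises(ValueError):
            fit_bending_constants(equilibrium_shapes, BendingParams(KC), [])
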