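import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cosolve import (
    ApelblatFit,
    SurfaceSpec,
    compare_models,
    fit_apelblat,
    fit_jouyban_acree,
    fit_vant_hoff,
    generate_grid,
    predict_yalkowsky,
    rmsd_percent,
)
from cosolve.dataset_io import SolubilityGrid, SolubilitySample
from cosolve.exceptions import (
    InsufficientDataError,
    InvalidInputError,
    MissingEndpointError,
)

TEMPS = np.array([298.2, 303.2, 308.2, 313.2, 323.2])


class TestRmsdPercent:
    def test_zero_iff_exact(self):
        assert rmsd_percent([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert rmsd_percent([1.0, 2.0], [1.0, 2.0001]) > 0.0

    def test_symmetric_relative_deviations(self):
        # +10% and -10% relative errors -> 10.0
        assert rmsd_percent([1.0, 2.0], [1.1, 1.8]) == pytest.approx(10.0)

    def test_overall_is_mean_of_per_series_values(self):
        # the study's published log-linear-rule per-series values average
        # to its published overall 1.26%
        published = [1.47, 1.56, 1.31, 1.25, 1.50, 1.15, 1.23, 1.03, 0.87]
        assert np.mean(published) == pytest.approx(1.26, abs=5e-3)

    def test_length_mismatch_and_zero_observed_rejected(self):
        with pytest.raises(InvalidInputError):
            rmsd_percent([1.0], [1.0, 2.0])
        with pytest.raises(InvalidInputError):
            rmsd_percent([0.0, 1.0], [1.0, 1.0])

    @settings(derandomize=True, max_examples=40)
    @given(st.lists(st.floats(1e-5, 1.0), min_size=1, max_size=10))
    def test_nonnegative(self, obs):
        pred = [v * 1.03 for v in obs]
        assert rmsd_percent(obs, pred) >= 0.0


class TestVantHoff:
    def test_reference_pure_cosolvent_coefficients(self, reference_grid):
        fit = fit_vant_hoff(*reference_grid.series(1.0))
        assert fit.a == pytest.approx(18.21, rel=5e-3)
        assert fit.b == pytest.approx(-6445.3, rel=5e-3)
        assert fit.r_squared > 0.99

    def test_noiseless_line_recovered_exactly(self):
        x = np.exp(15.0 - 7000.0 / TEMPS)
        fit = fit_vant_hoff(TEMPS, x)
        assert fit.a == pytest.approx(15.0, rel=1e-9)
        assert fit.b == pytest.approx(-7000.0, rel=1e-9)
        assert fit.rmsd_percent == pytest.approx(0.0, abs=1e-9)

    def test_two_points_interpolated_exactly(self):
        fit = fit_vant_hoff([300.0, 320.0], [1e-4, 5e-4])
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.rmsd_percent == pytest.approx(0.0, abs=1e-9)

    def test_single_temperature_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_vant_hoff([300.0], [1e-4])


class TestApelblat:
    def test_reference_pure_cosolvent_predictions_within_2_percent(
            self, reference_grid):
        t, x = reference_grid.series(1.0)
        fit = fit_apelblat(t, x)
        assert np.all(np.abs(fit.predict(t) / x - 1.0) < 0.02)
        assert fit.rmsd_percent < 2.0

    def test_with_c_zero_equals_vant_hoff_prediction(self):
        vh = fit_vant_hoff(TEMPS, np.exp(16.0 - 7100.0 / TEMPS))
        apl = ApelblatFit(A=vh.a, B=vh.b, C=0.0, r_squared=1.0,
                          rmsd_percent=0.0)
        np.testing.assert_allclose(
            apl.predict(TEMPS), vh.predict(TEMPS), rtol=1e-12)

    def test_generator_refitter_round_trip(self):
        # model is linear in (A, B, C): noiseless predictions must be
        # reproduced even though the basis is nearly collinear
        x = np.exp(495.0 - 30000.0 / TEMPS - 70.0 * np.log(TEMPS))
        fit = fit_apelblat(TEMPS, x)
        np.testing.assert_allclose(fit.predict(TEMPS), x, rtol=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_idempotent_on_own_predictions(self, reference_grid):
        t, x = reference_grid.series(0.5)
        first = fit_apelblat(t, x)
        second = fit_apelblat(t, first.predict(t))
        np.testing.assert_allclose(
            second.predict(t), first.predict(t), rtol=1e-9)

    def test_two_temperatures_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_apelblat([300.0, 310.0], [1e-4, 2e-4])


class TestYalkowsky:
    def test_reference_prediction(self):
        # blend of the measured pure-solvent solubilities at 298.2 K
        assert predict_yalkowsky(3.15e-2, 2.23e-5, 0.8) == pytest.approx(
            -2.13, abs=5e-3)

    def test_endpoint_identities(self):
        assert predict_yalkowsky(1e-2, 1e-5, 1.0) == pytest.approx(
            np.log10(1e-2))
        assert predict_yalkowsky(1e-2, 1e-5, 0.0) == pytest.approx(
            np.log10(1e-5))

    def test_equal_endpoints_are_composition_independent(self):
        for m in (0.0, 0.3, 0.7, 1.0):
            assert predict_yalkowsky(1e-3, 1e-3, m) == pytest.approx(
                np.log10(1e-3))

    @settings(derandomize=True, max_examples=40)
    @given(m=st.floats(0.0, 1.0), dm=st.floats(0.01, 0.5))
    def test_monotone_in_composition(self, m, dm):
        hi = min(m + dm, 1.0)
        a = predict_yalkowsky(1e-2, 1e-5, m)
        b = predict_yalkowsky(1e-2, 1e-5, hi)
        assert b >= a  # x1 > x2 so log-solubility rises with m

    def test_nonpositive_solubility_rejected(self):
        with pytest.raises(InvalidInputError):
            predict_yalkowsky(0.0, 1e-5, 0.5)


def brute_force_no_intercept(design, y):
    """Normal equations (X'X) J = X'y solved directly."""
    return np.linalg.solve(design.T @ design, design.T @ y)


class TestJouybanAcree:
    def test_zero_noise_round_trip_recovers_coefficients(self):
        spec = SurfaceSpec(A1=18.0, B1=-6400.0, A2=15.0, B2=-7800.0,
                           j_coeffs=(600.0, 200.0, 100.0), noise_cv=0.0)
        fit = fit_jouyban_acree(generate_grid(spec),
                                combined_with_vant_hoff=True)
        np.testing.assert_allclose(fit.j_coeffs, spec.j_coeffs, rtol=1e-6)
        assert fit.A1 == pytest.approx(spec.A1, rel=1e-6)
        assert fit.B2 == pytest.approx(spec.B2, rel=1e-6)

    def test_exact_log_linear_blend_gives_zero_interaction(self):
        spec = SurfaceSpec(j_coeffs=(), noise_cv=0.0)
        fit = fit_jouyban_acree(generate_grid(spec))
        np.testing.assert_allclose(fit.j_coeffs, 0.0, atol=1e-9)
        assert fit.rmsd_percent == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("combined", [False, True])
    def test_reference_overall_rmsd_below_5_percent(
            self, reference_grid, combined):
        fit = fit_jouyban_acree(reference_grid,
                                combined_with_vant_hoff=combined)
        assert fit.rmsd_percent <= 5.0

    def test_interaction_vanishes_at_pure_compositions(self, reference_grid):
        fit = fit_jouyban_acree(reference_grid)
        assert fit.interaction(0.0, 300.0) == 0.0
        assert fit.interaction(1.0, 300.0) == 0.0

    def test_only_leading_term_contributes_at_equal_masses(self):
        spec = SurfaceSpec(j_coeffs=(600.0, 200.0, 100.0), noise_cv=0.0)
        fit = fit_jouyban_acree(generate_grid(spec),
                                combined_with_vant_hoff=True)
        # at m = 0.5, (m1 - m2) = 0 so J1, J2 drop out
        expected = 0.25 * fit.j_coeffs[0] / 300.0
        assert fit.interaction(0.5, 300.0) == pytest.approx(expected)

    def test_matches_brute_force_normal_equations(self, reference_grid):
        fit = fit_jouyban_acree(reference_grid, order=2)
        rows, ys = [], []
        t1, x1 = reference_grid.series(1.0)
        t2, x2 = reference_grid.series(0.0)
        ln1, ln2 = dict(zip(t1, np.log(x1))), dict(zip(t2, np.log(x2)))
        for s in reference_grid.samples:
            m1 = s.mass_fraction_cosolvent
            if m1 in (0.0, 1.0):
                continue
            m2 = 1.0 - m1
            ys.append(np.log(s.x_exp) - m1 * ln1[s.temperature]
                      - m2 * ln2[s.temperature])
            rows.append([m1 * m2 * (m1 - m2) ** i / s.temperature
                         for i in range(3)])
        oracle = brute_force_no_intercept(np.array(rows), np.array(ys))
        np.testing.assert_allclose(fit.j_coeffs, oracle, rtol=1e-8)

    def test_refit_on_own_predictions_is_idempotent(self, reference_grid):
        fit = fit_jouyban_acree(reference_grid, combined_with_vant_hoff=True)
        samples = tuple(
            SolubilitySample(s.mass_fraction_cosolvent, s.temperature,
                             fit.predict(s.mass_fraction_cosolvent,
                                         s.temperature))
            for s in reference_grid.samples
        )
        refit = fit_jouyban_acree(SolubilityGrid(samples=samples),
                                  combined_with_vant_hoff=True)
        np.testing.assert_allclose(refit.j_coeffs, fit.j_coeffs, rtol=1e-6)
        assert refit.rmsd_percent == pytest.approx(0.0, abs=1e-6)

    def test_missing_endpoint_rejected(self, reference_grid):
        samples = tuple(s for s in reference_grid.samples
                        if s.mass_fraction_cosolvent < 1.0)
        with pytest.raises(MissingEndpointError):
            fit_jouyban_acree(SolubilityGrid(samples=samples))


class TestCompareModels:
    def test_reference_all_five_below_5_percent(self, reference_grid):
        comparisons = compare_models(reference_grid)
        assert len(comparisons) == 5
        for c in comparisons:
            assert c.overall_rmsd is not None
            assert c.overall_rmsd <= 5.0
            assert c.overall_rmsd == pytest.approx(
                np.mean(list(c.per_series_rmsd.values())))

    def test_true_model_wins_at_zero_noise(self):
        grid = generate_grid(SurfaceSpec(j_coeffs=(600.0,), noise_cv=0.0))
        by_name = {c.model: c for c in compare_models(grid)}
        javh = by_name["jouyban_acree_vanthoff"].overall_rmsd
        assert javh == pytest.approx(0.0, abs=1e-8)
        others = [c.overall_rmsd for name, c in by_name.items()
                  if name not in ("jouyban_acree_vanthoff", "jouyban_acree")]
        assert all(javh < o for o in others)

    def test_endpoints_only_grid_degrades_gracefully(self, reference_grid):
        samples = tuple(s for s in reference_grid.samples
                        if s.mass_fraction_cosolvent in (0.0, 1.0))
        comparisons = compare_models(SolubilityGrid(samples=samples))
        by_name = {c.model: c for c in comparisons}
        assert by_name["vanthoff"].overall_rmsd is not None
        for name in ("yalkowsky", "jouyban_acree", "jouyban_acree_vanthoff"):
            assert by_name[name].overall_rmsd is None
            assert by_name[name].status != "ok"
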