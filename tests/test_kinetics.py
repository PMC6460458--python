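"""Solver correctness: closed forms, quadrature oracles, conservation."""

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

import dcflux as dc
from conftest import riemann_dln


class TestMigrationRate:
    def test_saline_is_constant(self, canonical):
        for t in (0.0, 1.0, 26.0, 199.0):
            assert dc.migration_rate(t, canonical, "saline") == canonical.mu0

    def test_alum_at_zero_equals_baseline(self, canonical):
        assert dc.migration_rate(0.0, canonical, "alum") == pytest.approx(canonical.mu0)

    def test_canonical_peak_is_tenfold_at_26h(self, canonical):
        peak = dc.migration_rate(1.0 / canonical.m, canonical, "alum")
        assert peak == pytest.approx(10.0 * canonical.mu0, rel=1e-12)

    def test_grid_argmax_matches_1_over_m(self, canonical):
        grid = np.arange(0.0, 200.0, 0.01)
        rate = dc.migration_rate(grid, canonical, "alum")
        assert grid[int(np.argmax(rate))] == pytest.approx(26.0, abs=0.011)

    def test_negative_time_rejected(self, canonical):
        with pytest.raises(ValueError):
            dc.migration_rate(-0.5, canonical, "alum")


class TestCumulativeMigration:
    def test_empty_interval_is_zero(self, canonical):
        assert dc.cumulative_migration(7.0, 7.0, canonical, "alum") == 0.0

    def test_alpha_zero_reduces_to_saline(self, constant_params):
        got = dc.cumulative_migration(3.0, 40.0, constant_params, "alum")
        assert got == pytest.approx(constant_params.mu0 * 37.0, rel=1e-12)

    def test_matches_trapezoid_quadrature(self, canonical):
        s = np.arange(0.0, 48.0 + 1e-12, 0.001)
        oracle = np.trapezoid(dc.migration_rate(s, canonical, "alum"), s)
        got = dc.cumulative_migration(0.0, 48.0, canonical, "alum")
        assert got == pytest.approx(oracle, rel=1e-8)

    def test_reversed_interval_rejected(self, canonical):
        with pytest.raises(ValueError):
            dc.cumulative_migration(5.0, 4.0, canonical, "alum")

    @given(
        t1=st.floats(0.0, 80.0),
        span1=st.floats(0.0, 40.0),
        span2=st.floats(0.0, 40.0),
    )
    @hyp_settings(max_examples=50, deadline=None)
    def test_additive_over_adjacent_intervals(self, t1, span1, span2):
        params = dc.canonical_parameters()
        t2, t3 = t1 + span1, t1 + span1 + span2
        whole = dc.cumulative_migration(t1, t3, params, "alum")
        parts = dc.cumulative_migration(t1, t2, params, "alum") + dc.cumulative_migration(
            t2, t3, params, "alum"
        )
        assert whole == pytest.approx(parts, rel=1e-9, abs=1e-12)


class TestSkinTimecourse:
    def test_equals_x0_at_photoconversion(self, canonical, state12):
        assert dc.skin_timecourse(12.0, state12, canonical, "alum") == state12.x0

    def test_saline_e_fold_at_mean_residence(self, canonical, state12):
        t = state12.t_pc + 1.0 / canonical.mu0  # 132 h horizon
        got = dc.skin_timecourse(t, state12, canonical, "saline")
        assert got == pytest.approx(state12.x0 / np.e, rel=1e-12)

    def test_alum_below_saline_after_switch(self, canonical, state12):
        t = np.linspace(12.5, 96.0, 40)
        alum = dc.skin_timecourse(t, state12, canonical, "alum")
        saline = dc.skin_timecourse(t, state12, canonical, "saline")
        assert np.all(alum < saline)

    def test_non_increasing(self, canonical, state12):
        t = np.linspace(12.0, 150.0, 500)
        x = dc.skin_timecourse(t, state12, canonical, "alum")
        assert np.all(np.diff(x) <= 0)

    def test_before_photoconversion_rejected(self, canonical, state12):
        with pytest.raises(ValueError):
            dc.skin_timecourse(11.9, state12, canonical, "alum")


class TestDlnTimecourse:
    def test_zero_through_transit_window(self, canonical, state12):
        for t in (12.0, 12.0 + canonical.tau / 2, 12.0 + canonical.tau):
            assert dc.dln_timecourse(t, state12, canonical, "alum") == 0.0

    def test_constant_mu_matches_closed_form(self, constant_params, state12):
        """Quadrature vs analytic solution, all stated horizons, < 1e-6 rel."""
        for dt in (5.0, 12.0, 24.0, 48.0, 72.0):
            t = state12.t_pc + dt
            got = dc.dln_timecourse(t, state12, constant_params, "saline")
            want = dc.dln_constant_mu_closed_form(
                t, state12, constant_params.mu0, constant_params.delta_saline,
                constant_params.tau,
            )
            assert got == pytest.approx(want, rel=1e-6)

    def test_time_varying_matches_riemann_oracle(self, canonical, state12):
        """Quadrature vs dt = 0.001 h brute-force Riemann sum, < 1e-5 rel."""
        for t in (24.0, 36.0, 48.0):
            got = dc.dln_timecourse(t, state12, canonical, "alum")
            oracle = riemann_dln(t, state12, canonical, "alum", dt=0.001)
            assert got == pytest.approx(oracle, rel=1e-5)

    def test_nonnegative_everywhere(self, canonical, state12):
        t = np.linspace(12.0, 120.0, 300)
        assert np.all(dc.dln_timecourse(t, state12, canonical, "alum") >= 0)

    def test_alpha_zero_makes_conditions_identical(self, state12):
        params = dc.RateParameters(
            mu0=0.01, alpha=0.0, m=0.0, tau=2.0, delta_alum=0.1, delta_saline=0.1
        )
        t = np.linspace(12.0, 90.0, 25)
        np.testing.assert_allclose(
            dc.dln_timecourse(t, state12, params, "alum"),
            dc.dln_timecourse(t, state12, params, "saline"),
            rtol=1e-12,
        )


class TestClosedFormOracle:
    def test_zero_span_is_zero(self, state12):
        assert dc.dln_constant_mu_closed_form(12.0 + 2.6, state12, 0.01, 0.1, 2.6) == 0.0

    def test_instantaneous_loss_limit(self, state12):
        got = dc.dln_constant_mu_closed_form(40.0, state12, 0.01, 1e6, 2.6)
        assert got == pytest.approx(0.0, abs=1e-5)

    def test_degenerate_limit_matches_lhopital(self):
        state = dc.SkinPoolState(x0=100.0, t_pc=0.0)
        exact = dc.dln_constant_mu_closed_form(10.0, state, 0.1, 0.1, 0.0)
        assert exact == pytest.approx(100.0 * 0.1 * 10.0 * np.exp(-1.0), rel=1e-9)
        for eps in (1e-8, -1e-8):
            near = dc.dln_constant_mu_closed_form(10.0, state, 0.1, 0.1 + eps, 0.0)
            assert near == pytest.approx(exact, rel=1e-6)


class TestConservationAndContinuity:
    def test_mass_conserved_without_dln_loss(self, canonical, state12):
        """With delta = 0, skin + in-transit + dLN = x0 at all times."""
        params = canonical.replace(delta_alum=1e-300, delta_saline=1e-300)
        for t in (12.0, 13.0, 14.6, 20.0, 40.0, 80.0, 150.0):
            total = (
                dc.skin_timecourse(t, state12, params, "alum")
                + dc.in_transit(t, state12, params, "alum")
                + dc.dln_timecourse(t, state12, params, "alum")
            )
            assert total == pytest.approx(state12.x0, rel=1e-6)

    @pytest.mark.parametrize(
        "field", ["mu0", "alpha", "m", "tau", "delta_alum", "delta_saline"]
    )
    def test_predictions_continuous_in_parameters(self, canonical, state12, field):
        t = 36.0
        base = dc.dln_timecourse(t, state12, canonical, "alum")
        bumped = canonical.replace(
            **{field: getattr(canonical, field) * (1.0 + 1e-9)}
        )
        got = dc.dln_timecourse(t, state12, bumped, "alum")
        assert got == pytest.approx(base, rel=1e-6)


class TestPredictObservations:
    def test_skin_harvest_at_tpc_returns_x0(self, canonical):
        design = dc.PhotoconversionDesign("alum", 12.0, (12.0,), sites=("skin",))
        out = dc.predict_observations(design, canonical, 750.0)
        np.testing.assert_allclose(out, [750.0])

    def test_dln_harvest_within_transit_window_is_zero(self, canonical):
        design = dc.PhotoconversionDesign(
            "alum", 12.0, (12.0 + canonical.tau / 2,), sites=("dln",)
        )
        np.testing.assert_allclose(
            dc.predict_observations(design, canonical, 750.0), [0.0]
        )

    def test_matches_solver_pointwise(self, canonical):
        design = dc.PhotoconversionDesign("alum", 12.0, (24.0, 36.0, 48.0, 72.0),
                                          sites=("dln",))
        state = dc.SkinPoolState(x0=1000.0, t_pc=12.0)
        want = [dc.dln_timecourse(t, state, canonical, "alum")
                for t in design.harvest_times]
        np.testing.assert_allclose(
            dc.predict_observations(design, canonical, {design.design_id: 1000.0}),
            want, rtol=1e-12,
        )
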