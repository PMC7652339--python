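import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import killcurve as kc
from killcurve.kinetics import KineticsError, MissingControlError

import naive_oracle
from conftest import make_series


class TestResampleToGrid:
    def test_coinciding_times_preserved_exactly(self, rng):
        s = make_series(rng, n=20, step=2.0)  # 2 h cadence covers every grid time
        g = kc.resample_to_grid(s)
        assert np.all(g.t == 2.0 + 6.0 * np.arange(len(g.t)))
        for name in ("e_live", "red_px", "phase_px"):
            native = getattr(s, name)
            idx = np.searchsorted(s.t, g.t)
            assert np.array_equal(getattr(g, name), native[idx])

    def test_linear_signal_interpolated_exactly(self):
        t = 2.0 + 4.0 * np.arange(12)
        s = kc.WellTimeSeries("W01", "X", 1.0, 0.0, t, 3.0 * t + 7.0,
                              2.0 * t, 10.0 * t + 100.0)
        g = kc.resample_to_grid(s)
        assert np.allclose(g.e_live, 3.0 * g.t + 7.0, rtol=0, atol=1e-9)

    def test_quadratic_midpoint_error_matches_closed_form(self):
        # e = t^2 sampled every 4 h: at a grid time halfway between samples the
        # linear-interpolation residual is (spacing/2)^2 = 4
        t = 2.0 + 4.0 * np.arange(12)
        s = kc.WellTimeSeries("W01", "X", 1.0, 0.0, t, t**2, t, t + 1.0)
        g = kc.resample_to_grid(s)
        midpoints = ~np.isin(g.t, t)
        assert midpoints.any()
        err = g.e_live[midpoints] - g.t[midpoints] ** 2
        assert np.allclose(err, 4.0, rtol=0, atol=1e-9)

    def test_too_short_or_too_coarse_rejected(self, rng):
        s = make_series(rng, n=2, step=2.0)
        with pytest.raises(KineticsError, match="less than one grid step"):
            kc.resample_to_grid(s)
        coarse = make_series(rng, n=10, step=8.0)
        with pytest.raises(KineticsError, match="cadence"):
            kc.resample_to_grid(coarse)


class TestReadoutFormulas:
    def test_fold_proliferation_worked_example(self):
        e = np.array([100.0, 150, 250])
        p = kc.fold_proliferation(e)
        assert p[0] == 1.0
        assert p[-1] == pytest.approx(2.5, rel=1e-12)

    def test_constant_count_gives_unit_fold(self):
        assert np.all(kc.fold_proliferation(np.full(8, 321.0)) == 1.0)

    def test_zero_t0_count_rejected(self):
        with pytest.raises(KineticsError):
            kc.fold_proliferation(np.array([0.0, 10.0]))

    def test_death_fraction_worked_examples(self):
        td = kc.death_fraction(np.array([0.0, 1500.0, 6000.0]),
                               np.array([6000.0, 6000.0, 6000.0]))
        assert td[0] == 0.0
        assert td[1] == pytest.approx(25.0, rel=1e-12)
        assert td[2] == pytest.approx(100.0, rel=1e-12)

    def test_death_fraction_zero_phase_is_nan(self):
        td = kc.death_fraction(np.array([5.0]), np.array([0.0]))
        assert np.isnan(td[0])

    def test_specific_killing_worked_example_and_self_normalisation(self):
        k, clamped = kc.specific_killing(np.array([30.0]), np.array([5.0]))
        assert k[0] == pytest.approx(6.0, rel=1e-12) and not clamped.any()
        td0 = np.array([3.0, 7.0, 11.0])
        k0, _ = kc.specific_killing(td0, td0)
        assert np.all(k0 == 1.0)

    def test_specific_killing_floor_clamps_and_flags(self):
        k, clamped = kc.specific_killing(np.array([10.0]), np.array([0.001]),
                                         floor=np.array([0.1]))
        assert clamped[0]
        assert k[0] == pytest.approx(100.0, rel=1e-12)

    def test_killing_per_tcell_worked_example(self):
        # T_dead(48,c)=40%, E(42,c)=200 vs T_dead(48,0)=2%, E(42,0)=400 -> S=40
        s, _ = kc.killing_per_tcell(np.array([1.0, 40.0]), np.array([200.0, 999.0]),
                                    np.array([1.0, 2.0]), np.array([400.0, 999.0]))
        assert np.isnan(s[0])
        assert s[1] == pytest.approx(40.0, rel=1e-12)

    def test_killing_per_tcell_reduces_to_k_when_counts_equal(self, rng):
        td_c = rng.uniform(1, 50, 10)
        td_0 = rng.uniform(1, 50, 10)
        e = rng.uniform(100, 1000, 10)
        s, _ = kc.killing_per_tcell(td_c, e, td_0, e)
        k, _ = kc.specific_killing(td_c, td_0)
        assert np.allclose(s[1:], k[1:], rtol=1e-12)

    def test_proliferation_rate_examples_and_sign(self):
        r, _ = kc.proliferation_rate(np.array([100.0, 120.0]))
        assert r[1] == pytest.approx(0.8, rel=1e-12)  # 80 %/day
        flat, _ = kc.proliferation_rate(np.full(5, 200.0))
        assert np.all(flat[1:] == 0.0)
        down, _ = kc.proliferation_rate(np.array([100.0, 90.0, 50.0]))
        assert np.all(down[1:] < 0)  # negative rates reported, not clamped

    def test_kill_rate_worked_example_and_zero_dose(self):
        r, _ = kc.kill_rate(np.array([3.0, 6.0]), np.array([100.0, 100.0]))
        assert r[1] == pytest.approx(0.005, rel=1e-12)
        r0, _ = kc.kill_rate(np.ones(6), np.full(6, 50.0))
        assert np.all(r0[1:] == 0.0)

    def test_formulas_match_naive_recoding(self, rng):
        """Vectorised implementations agree with literal re-codings to 1e-12."""
        for _ in range(25):
            n = int(rng.integers(10, 49))
            e_c = rng.integers(50, 5000, n).astype(float)
            e_0 = rng.integers(50, 5000, n).astype(float)
            red = rng.uniform(10, 5e4, n)
            phase = rng.uniform(1e4, 5e5, n)
            td_c = kc.death_fraction(red, phase)
            td_0 = kc.death_fraction(rng.uniform(10, 5e4, n), phase)
            checks = [
                (kc.fold_proliferation(e_c), naive_oracle.fold_proliferation(e_c)),
                (td_c, naive_oracle.death_fraction(red, phase)),
                (kc.specific_killing(td_c, td_0)[0],
                 naive_oracle.specific_killing(td_c, td_0)),
                (kc.killing_per_tcell(td_c, e_c, td_0, e_0)[0],
                 naive_oracle.killing_per_tcell(td_c, e_c, td_0, e_0)),
                (kc.proliferation_rate(e_c)[0], naive_oracle.proliferation_rate(e_c)),
                (kc.kill_rate(td_c, e_c)[0], naive_oracle.kill_rate(td_c, e_c)),
            ]
            for got, want in checks:
                for g, w in zip(got, want):
                    if w is None:
                        assert np.isnan(g)
                    else:
                        assert g == pytest.approx(w, rel=1e-12)


class TestBuildProfiles:
    def test_single_well_equals_per_well_computation(self, rng):
        ctrl = make_series(rng, n=12, concentration=0.0, well_id="A01")
        dosed = make_series(rng, n=12, concentration=1e-7, well_id="A02")
        prof = kc.build_profiles([ctrl, dosed])[0]
        expect_p = kc.fold_proliferation(dosed.e_live)
        assert np.allclose(prof.p_fold[1], expect_p, rtol=1e-12)
        td_c = kc.death_fraction(dosed.red_px, dosed.phase_px)
        td_0 = kc.death_fraction(ctrl.red_px, ctrl.phase_px)
        assert np.allclose(prof.k_specific[1],
                           kc.specific_killing(td_c, td_0)[0], rtol=1e-12)

    def test_duplicate_identical_wells_average_idempotently(self, rng):
        ctrl = make_series(rng, n=12, concentration=0.0, well_id="A01")
        dosed = make_series(rng, n=12, concentration=1e-7, well_id="A02")
        ctrl2 = kc.WellTimeSeries("B01", "X", 1.0, 0.0, ctrl.t, ctrl.e_live,
                                  ctrl.red_px, ctrl.phase_px)
        dosed2 = kc.WellTimeSeries("B02", "X", 1.0, 1e-7, dosed.t, dosed.e_live,
                                   dosed.red_px, dosed.phase_px)
        single = kc.build_profiles([ctrl, dosed])[0]
        double = kc.build_profiles([ctrl, dosed, ctrl2, dosed2])[0]
        assert np.allclose(single.s_per_tcell[1, 1:], double.s_per_tcell[1, 1:],
                           rtol=1e-12)
        assert np.allclose(single.p_fold, double.p_fold, rtol=1e-12)

    def test_missing_control_rejected_with_group_name(self, rng):
        dosed = make_series(rng, n=12, concentration=1e-7, construct="TCR-9")
        with pytest.raises(MissingControlError, match="TCR-9"):
            kc.build_profiles([dosed])

    def test_normalisation_identities_exact(self, small_profile):
        prof = small_profile
        i0 = int(np.flatnonzero(prof.concentrations == 0)[0])
        assert np.all(prof.k_specific[i0] == 1.0)
        assert np.all(prof.s_per_tcell[i0, 1:] == 1.0)
        assert np.all(prof.k_prime[i0, 1:] == 0.0)
        assert np.all(prof.p_fold[:, 0] == 1.0)

    def test_grid_consistency_native_2h_vs_pre_resampled(self, small_config):
        """P, T_dead, K computed from 2 h data then read at 6 h grid times equal
        the same quantities computed after resampling to the 6 h grid."""
        plate = kc.build_platemap(["X"], (1.0,), small_config.concentrations,
                                  replicates=1)
        truth = kc.simulate_plate(small_config, plate)
        prof = kc.build_profiles(truth.wells)[0]
        for s in truth.wells:
            g = kc.resample_to_grid(s)
            i = int(np.flatnonzero(prof.concentrations == s.concentration)[0])
            assert np.allclose(prof.p_fold[i], kc.fold_proliferation(g.e_live),
                               rtol=1e-12)
            assert np.allclose(prof.t_dead_pct[i][~np.isnan(prof.t_dead_pct[i])][1:],
                               kc.death_fraction(g.red_px, g.phase_px)[1:][
                                   ~np.isnan(prof.t_dead_pct[i][1:])], rtol=1e-12)

    def test_zero_floor_clamp_flagged_on_spotless_control(self, rng):
        t = 2.0 + 6.0 * np.arange(8)
        ctrl = kc.WellTimeSeries("A01", "X", 1.0, 0.0, t, np.full(8, 100.0),
                                 np.zeros(8), np.full(8, 1e4))
        dosed = kc.WellTimeSeries("A02", "X", 1.0, 1e-7, t, np.full(8, 100.0),
                                  np.full(8, 500.0), np.full(8, 1e4))
        prof = kc.build_profiles([ctrl, dosed])[0]
        assert any(f.code == "zero_floor_clamp" for f in prof.flags)
        # ratio uses the one-pixel floor: 500 px / 1 px
        assert prof.k_specific[1, 3] == pytest.approx(500.0, rel=1e-12)
        assert np.all(prof.k_specific[0] == 1.0)  # identity survives the clamp

    def test_sign_and_range_invariants(self, small_profile):
        prof = small_profile
        td = prof.t_dead_pct[np.isfinite(prof.t_dead_pct)]
        assert np.all(td >= 0) and np.all(td <= 100.0)
        k = prof.k_specific[np.isfinite(prof.k_specific)]
        s = prof.s_per_tcell[np.isfinite(prof.s_per_tcell)]
        assert np.all(k >= 0) and np.all(s >= 0)

    def test_specific_killing_monotone_in_dose_at_late_times(self, small_config):
        plate = kc.build_platemap(["X"], (1.0,), small_config.concentrations,
                                  replicates=2)
        truth = kc.simulate_plate(small_config, plate)
        prof = kc.build_profiles(truth.wells)[0]
        j48 = int(np.argmin(np.abs(prof.t_grid - 48.0)))
        k = prof.k_specific[:, j48]
        # non-decreasing in dose within sampling error: allow small slack
        assert np.all(np.diff(k) > -0.15 * np.maximum(k[:-1], 1.0))
        assert k[-1] > 3.0 * k[0]


class TestWellTimeSeriesValidation:
    def test_rejects_wrong_start_time(self):
        with pytest.raises(KineticsError, match="settling"):
            kc.WellTimeSeries("W", "X", 1.0, 0.0, np.array([0.0, 6.0]),
                              np.ones(2), np.ones(2), np.ones(2))

    def test_rejects_non_monotone_time(self):
        with pytest.raises(KineticsError, match="strictly increasing"):
            kc.WellTimeSeries("W", "X", 1.0, 0.0, np.array([2.0, 2.0, 8.0]),
                              np.ones(3), np.ones(3), np.ones(3))

    @given(st.integers(3, 30))
    def test_roundtrip_tidy_frame_shape(self, n):
        t = 2.0 + 6.0 * np.arange(n)
        w = kc.WellTimeSeries("W", "X", 1.0, 0.0, t, np.arange(n) + 1.0,
                              np.zeros(n), np.ones(n))
        assert len(w.t) == n
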