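import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import killcurve as kc
from killcurve.config import AnalysisParams
from killcurve.doseresponse import (DoseResponseError, fit_4pl, format_et_ratio,
                                    summarize, summary_text)


def fourpl(c, bottom, top, ec50, slope):
    return bottom + (top - bottom) / (1.0 + (ec50 / c) ** slope)


DOSES_20 = np.array([100e-6 / 3**k for k in range(20)])[::-1]


class TestFit4PL:
    def test_noiseless_recovery_to_1e6(self):
        r = fourpl(DOSES_20, bottom=1.0, top=30.0, ec50=0.05e-6, slope=1.0)
        fit = fit_4pl(DOSES_20, r)
        assert fit.converged
        assert fit.bottom == pytest.approx(1.0, rel=1e-6)
        assert fit.top == pytest.approx(30.0, rel=1e-6)
        assert fit.ec50 == pytest.approx(0.05e-6, rel=1e-6)
        assert fit.hill_slope == pytest.approx(1.0, rel=1e-6)
        assert fit.emax == fit.top

    def test_flat_response_flagged(self):
        fit = fit_4pl(DOSES_20, np.full_like(DOSES_20, 7.0))
        assert "no_dose_dependence" in fit.flags
        assert "ec50_unreliable" in fit.flags

    def test_pure_noise_flagged_no_dose_dependence(self):
        rng = np.random.default_rng(5)
        fit = fit_4pl(DOSES_20, 1.0 + 0.05 * rng.standard_normal(len(DOSES_20)))
        assert "no_dose_dependence" in fit.flags

    def test_order_invariance(self):
        r = fourpl(DOSES_20, 2.0, 12.0, 1e-8, 1.5)
        perm = np.random.default_rng(3).permutation(len(DOSES_20))
        a = fit_4pl(DOSES_20, r)
        b = fit_4pl(DOSES_20[perm], r[perm])
        assert a.ec50 == pytest.approx(b.ec50, rel=1e-9)
        assert a.top == pytest.approx(b.top, rel=1e-9)

    def test_response_rescaling_leaves_ec50_scales_emax(self):
        r = fourpl(DOSES_20, 1.0, 9.0, 3e-8, 1.2)
        a = fit_4pl(DOSES_20, r)
        b = fit_4pl(DOSES_20, 50.0 * r)
        assert b.ec50 == pytest.approx(a.ec50, rel=1e-6)
        assert b.emax == pytest.approx(50.0 * a.emax, rel=1e-6)

    def test_requires_five_distinct_positive_doses(self):
        with pytest.raises(DoseResponseError, match="5 distinct"):
            fit_4pl([1e-9, 1e-8, 1e-7, 1e-6], [1, 2, 3, 4])
        with pytest.raises(DoseResponseError, match="positive"):
            fit_4pl([0.0, 1e-8, 1e-7, 1e-6, 1e-5], [1, 2, 3, 4, 5])

    def test_monte_carlo_recovery_under_5pct_noise(self):
        """100 noisy replicate fits recover EC50 with median |log10 error| < 0.15."""
        rng = np.random.default_rng(42)
        true_ec50 = 0.05e-6
        clean = fourpl(DOSES_20, 1.0, 30.0, true_ec50, 1.0)
        errs = []
        for _ in range(100):
            noisy = clean + rng.normal(0.0, 0.05 * 30.0, size=clean.shape)
            fit = fit_4pl(DOSES_20, noisy)
            errs.append(abs(np.log10(fit.ec50 / true_ec50)))
        assert np.median(errs) < 0.15


class TestExtractPeakResponse:
    def _profile(self, t_grid, concs, **arrays):
        shape = (len(concs), len(t_grid))
        base = {k: np.zeros(shape) for k in
                ("p_fold", "t_dead_pct", "k_specific", "s_per_tcell",
                 "p_prime_pct_day", "k_prime", "e_live")}
        base.update(arrays)
        return kc.KineticProfile(construct="X", et_ratio=1.0,
                                 concentrations=np.asarray(concs, float),
                                 t_grid=np.asarray(t_grid, float), **base)

    def test_constant_curve_peak_is_that_constant(self):
        t = 2.0 + 6.0 * np.arange(16)
        prof = self._profile(t, [0.0, 1e-8, 1e-7], p_fold=np.full((3, 16), 2.5))
        peak = kc.extract_peak_response(prof, "proliferation")
        assert np.all(peak.responses == 2.5)
        assert peak.peak_time_h == 74.0  # grid time nearest 72 h

    def test_killing_read_at_grid_time_nearest_48h(self):
        t = 2.0 + 6.0 * np.arange(16)
        s = np.zeros((2, 16))
        j = int(np.argmin(np.abs(t - 48.0)))
        s[1, j] = 9.0
        prof = self._profile(t, [0.0, 1e-7], s_per_tcell=s)
        peak = kc.extract_peak_response(prof, "specific_killing")
        assert peak.responses[0] == 9.0 and peak.peak_time_h == t[j]

    def test_rate_spike_outside_window_excluded(self):
        t = 2.0 + 6.0 * np.arange(16)
        kp = np.zeros((2, 16))
        kp[1, t == 26.0] = 100.0   # outside [30, 72]
        kp[1, t == 50.0] = 4.0     # inside
        prof = self._profile(t, [0.0, 1e-7], k_prime=kp)
        peak = kc.extract_peak_response(prof, "kill_rate")
        assert peak.responses[0] == 4.0

    def test_unimodal_rate_maximum_matches_analytic_value(self):
        t = 2.0 + 6.0 * np.arange(16)
        concs = [0.0, 1e-8]
        rate = np.vstack([np.zeros_like(t), 10.0 - (t - 44.0) ** 2 / 50.0])
        prof = self._profile(t, concs, p_prime_pct_day=rate)
        peak = kc.extract_peak_response(prof, "proliferation_rate")
        lo, hi = AnalysisParams().rate_window
        grid_in = t[(t >= lo) & (t <= hi)]
        assert peak.responses[0] == pytest.approx(
            np.max(10.0 - (grid_in - 44.0) ** 2 / 50.0), rel=1e-12)

    def test_short_grid_raises_naming_readout(self):
        t = 2.0 + 6.0 * np.arange(4)  # ends at 20 h
        prof = self._profile(t, [0.0, 1e-8])
        with pytest.raises(DoseResponseError, match="proliferation"):
            kc.extract_peak_response(prof, "proliferation")
        with pytest.raises(DoseResponseError, match="kill_rate"):
            kc.extract_peak_response(prof, "kill_rate")


class TestBanding:
    def test_caption_rule_examples(self):
        ec50 = 0.05e-6
        bands = kc.band_concentrations(ec50, [100e-6, 0.2e-6, 0.001 * ec50])
        assert bands[100e-6] == "High"          # 100 uM > 100 x 0.05 uM
        assert bands[0.2e-6] == "Mid"
        assert bands[0.001 * ec50] == "Low"

    def test_boundaries_assigned_upward(self):
        ec50 = 1e-8
        bands = kc.band_concentrations(ec50, [ec50, 100 * ec50])
        assert bands[ec50] == "Mid"
        assert bands[100 * ec50] == "High"

    @given(st.floats(1e-12, 1e-4), st.integers(2, 30))
    def test_partition_of_positive_doses(self, ec50, n):
        doses = np.geomspace(ec50 / 1e4, ec50 * 1e4, n)
        bands = kc.band_concentrations(ec50, doses)
        assert len(bands) == len(doses)
        assert set(bands.values()) <= {"High", "Mid", "Low"}

    def test_invalid_inputs_rejected(self):
        with pytest.raises(DoseResponseError):
            kc.band_concentrations(float("nan"), [1e-8])
        with pytest.raises(DoseResponseError):
            kc.band_concentrations(1e-8, [0.0])


class TestSummarize:
    def _fits(self, n_constructs=3, n_ratios=3):
        fits = []
        for ci in range(n_constructs):
            for ratio in (3.0, 1.0, 1 / 3)[:n_ratios]:
                for readout in kc.doseresponse.READOUTS:
                    fits.append(kc.DoseResponseFit(
                        readout=readout, construct=f"C{ci}", et_ratio=ratio,
                        bottom=1.0, top=5.0, ec50=1e-8, hill_slope=1.0, emax=5.0,
                        rss=0.1, converged=True, n_points=20))
        return fits

    def test_cartesian_row_count(self):
        table = summarize(self._fits())
        assert len(table) == 3 * 3 * 4

    def test_et_ratio_printed_as_ratio_strings(self):
        table = summarize(self._fits(n_constructs=1))
        assert set(table["et_ratio"]) == {"3:1", "1:1", "1:3"}
        assert format_et_ratio(1 / 3) == "1:3"

    def test_non_converged_fit_keeps_row_with_empty_ec50(self):
        fits = self._fits(n_constructs=1, n_ratios=1)
        fits[0] = kc.DoseResponseFit(
            readout=fits[0].readout, construct=fits[0].construct,
            et_ratio=fits[0].et_ratio, bottom=float("nan"), top=float("nan"),
            ec50=float("nan"), hill_slope=float("nan"), emax=float("nan"),
            rss=float("inf"), converged=False, n_points=20,
            flags=["non_convergent"])
        table = summarize(fits)
        row = table[~table["converged"]]
        assert len(row) == 1 and np.isnan(row["ec50_um"].iloc[0])
        text = summary_text(table)
        assert "-" in text and "False" in text
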