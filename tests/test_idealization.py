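"""Filtering, baseline handling, half-amplitude idealization, dwell extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import chanzyme as cz
from chanzyme.core import IdealizedRecord, Trace
from chanzyme.idealization import default_dead_time


class TestGaussianLowpass:
    def test_dc_gain_is_unity(self):
        tr = Trace(np.full(5000, 3.7), 10_000.0)
        out = cz.gaussian_lowpass(tr, 500.0)
        np.testing.assert_allclose(out.samples, 3.7, rtol=1e-10)

    def test_minus_3db_at_cutoff(self):
        fs, fc = 50_000.0, 1000.0
        t = np.arange(int(fs)) / fs
        tr = Trace(np.sin(2 * np.pi * fc * t), fs)
        out = cz.gaussian_lowpass(tr, fc)
        mid = out.samples[5000:-5000]
        attenuation = mid.max()
        assert attenuation == pytest.approx(1 / np.sqrt(2), rel=0.02)

    def test_step_rise_time(self):
        from scipy.stats import norm

        from chanzyme.idealization import gaussian_sigma_seconds

        fs, fc = 100_000.0, 1000.0
        x = np.zeros(20_000)
        x[10_000:] = 1.0
        out = cz.gaussian_lowpass(Trace(x, fs), fc)
        t = np.arange(x.size) / fs
        sigma = gaussian_sigma_seconds(fc)
        # 10-90% rise time: 2 * z_0.9 * sigma (~0.3396/fc)
        t10 = np.interp(0.1, out.samples, t)
        t90 = np.interp(0.9, out.samples, t)
        assert (t90 - t10) == pytest.approx(2 * norm.ppf(0.9) * sigma, rel=0.02)
        # reciprocal-max-slope rise time: sqrt(2*pi) * sigma = 0.3321/fc
        max_slope = np.max(np.diff(out.samples)) * fs
        assert 1.0 / max_slope == pytest.approx(0.3321 / fc, rel=0.02)

    def test_cutoff_at_or_above_nyquist_rejected(self):
        tr = Trace(np.zeros(100), 1000.0)
        with pytest.raises(ValueError):
            cz.gaussian_lowpass(tr, 500.0)


class TestSubtractBaseline:
    def _gated_trace(self, offset=0.0, rng=None):
        rng = rng or np.random.default_rng(0)
        # mostly closed with some openings at -2.5 pA
        x = np.zeros(20_000)
        x[5000:7000] = -2.5
        x[12_000:13_000] = -2.5
        return Trace(x + offset + rng.normal(0, 0.05, x.size), 10_000.0)

    def test_offset_removed(self):
        out = cz.subtract_baseline(self._gated_trace(offset=1.0))
        closed = np.r_[out.samples[:5000], out.samples[7000:12_000]]
        assert abs(closed.mean()) < 0.05

    def test_zeroed_trace_unchanged_within_bin(self):
        tr = self._gated_trace()
        out = cz.subtract_baseline(tr)
        assert abs((out.samples - tr.samples).mean()) < 0.05

    def test_linear_drift_corrected_by_windows(self):
        rng = np.random.default_rng(1)
        n = 100_000
        drift = np.linspace(0.0, 1.0, n)
        x = drift + rng.normal(0, 0.05, n)
        open_mask = np.zeros(n, bool)
        open_mask[40_000:45_000] = True
        x[open_mask] -= 2.5
        out = cz.subtract_baseline(Trace(x, 10_000.0), window_s=1.0)
        resid = out.samples[~open_mask]
        assert abs(resid.mean()) < 0.1

    def test_no_closed_level_warns_and_is_identity(self):
        tr = Trace(np.full(5000, -2.5), 10_000.0)
        with pytest.warns(UserWarning, match="closed level"):
            out = cz.subtract_baseline(tr)
        np.testing.assert_array_equal(out.samples, tr.samples)


class TestIdealize:
    def test_noiseless_square_wave_roundtrip(self):
        fs = 1000.0
        x = np.concatenate([np.zeros(100), np.full(50, -2.5), np.zeros(200),
                            np.full(25, -2.5), np.zeros(10)])
        rec = cz.idealize(Trace(x, fs), -2.5, max_levels=1)
        np.testing.assert_array_equal(rec.levels, [0, 1, 0, 1, 0])
        np.testing.assert_allclose(rec.durations, np.array([100, 50, 200, 25, 10]) / fs)

    def test_half_amplitude_tie_goes_to_lower_level(self):
        # -1.25 pA is exactly half of a -2.5 pA opening
        x = np.array([0.0, -1.25, -2.5])
        rec = cz.idealize(Trace(x, 1000.0), -2.5, max_levels=1)
        assert rec.levels[0] == 0 and rec.levels[-1] == 1
        # the tie sample joined the lower (closed) level event
        assert rec.durations[0] == pytest.approx(2 / 1000.0)

    def test_polarity_independence(self):
        x = np.array([0.0, 2.5, 2.5, 0.0])
        rec = cz.idealize(Trace(x, 1000.0), 2.5, max_levels=1)
        np.testing.assert_array_equal(rec.levels, [0, 1, 0])

    def test_generator_roundtrip_event_for_event(self, nv_scheme):
        fs = 100_000.0
        paths = cz.simulate_ctmc(nv_scheme, 1, 200.0, seed=2)
        # merge sub-sample truth events: they cannot survive discretization
        truth = cz.impose_dead_time(cz.paths_to_idealized(paths), 1.0 / fs)
        tr = cz.render_trace(paths, -2.5, fs)
        rec = cz.idealize(tr, -2.5, max_levels=1)
        # events near one sample long may be kept or dropped depending on
        # where they fall on the grid; everything else must agree
        assert abs(rec.n_events - truth.n_events) <= 0.01 * truth.n_events
        occ_rec = cz.extract_dwells(rec).occupancy
        occ_truth = cz.extract_dwells(truth).occupancy
        for lvl in (0, 1):
            assert occ_rec[lvl] == pytest.approx(occ_truth[lvl], abs=50.0 / fs)
        assert rec.total_duration == pytest.approx(truth.total_duration, abs=1.0 / fs)

    def test_max_levels_exceeded_names_sample_time(self):
        x = np.array([0.0, -2.5, -7.6])
        with pytest.raises(ValueError, match="t=0.002"):
            cz.idealize(Trace(x, 1000.0), -2.5, max_levels=2)


class TestImposeDeadTime:
    def test_zero_dead_time_is_identity(self):
        rec = IdealizedRecord([0, 1, 0], [0.1, 0.2, 0.3])
        out = cz.impose_dead_time(rec, 0.0)
        np.testing.assert_array_equal(out.levels, rec.levels)

    def test_short_event_absorbed_and_neighbours_merged(self):
        rec = IdealizedRecord([0, 1, 0], [0.100, 0.0005, 0.100])
        out = cz.impose_dead_time(rec, 0.001)
        np.testing.assert_array_equal(out.levels, [0])
        assert out.durations[0] == pytest.approx(0.2005)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-4, max_value=0.5), min_size=1, max_size=40),
           st.integers(min_value=0, max_value=3))
    def test_duration_conserved_and_idempotent(self, durs, start_level):
        levels = [(start_level + i) % 2 for i in range(len(durs))]
        rec = IdealizedRecord(levels, durs)
        out = cz.impose_dead_time(rec, 0.005)
        assert out.durations.sum() == pytest.approx(rec.durations.sum(), rel=1e-12)
        again = cz.impose_dead_time(out, 0.005)
        np.testing.assert_array_equal(again.levels, out.levels)
        np.testing.assert_allclose(again.durations, out.durations)
        if out.n_events > 1:
            assert np.all(out.durations >= 0.005)

    def test_default_dead_time_scale(self):
        assert default_dead_time(200.0) == pytest.approx(0.179 / 200.0)


class TestExtractDwells:
    def test_edge_events_censored(self):
        rec = IdealizedRecord([0, 1, 0, 1, 0], [1.0, 2.0, 3.0, 4.0, 5.0])
        table = cz.extract_dwells(rec)
        np.testing.assert_array_equal(np.sort(table.dwells[1]), [2.0, 4.0])
        np.testing.assert_array_equal(table.dwells[0], [3.0])
        assert table.occupancy[1] == pytest.approx(6.0)
        assert table.occupancy[0] == pytest.approx(9.0)

    def test_single_event_record(self):
        rec = IdealizedRecord([0], [7.0])
        table = cz.extract_dwells(rec)
        assert table.dwells[0].size == 0
        assert table.occupancy[0] == pytest.approx(7.0)


class TestMaxOpenLevel:
    def test_basic(self):
        assert cz.max_open_level(IdealizedRecord([0, 2, 1], [1, 1, 1])) == 2
        assert cz.max_open_level(IdealizedRecord([0], [1.0])) == 0

    def test_twelve_channel_patch_reaches_near_top(self, nv_scheme):
        paths = cz.simulate_ctmc(nv_scheme, 12, 300.0, seed=21)
        rec = cz.paths_to_idealized(paths)
        # P(level 12) ~ P_o^12 ~ 2e-4 per instant; 300 s gives a fair chance
        # of touching 12 but level >= 11 is near-certain
        assert cz.max_open_level(rec) >= 11


class TestAmplitudeHistogram:
    def test_two_peak_spacing(self, rng):
        x = np.concatenate([rng.normal(0.0, 0.05, 40_000),
                            rng.normal(-2.5, 0.05, 30_000)])
        fit = cz.fit_amplitude_histogram(Trace(x, 10_000.0))
        assert fit.status == "ok"
        assert fit.unitary_amplitude == pytest.approx(-2.5, abs=0.02)

    def test_three_equally_spaced_peaks(self, rng):
        x = np.concatenate([rng.normal(0.0, 0.1, 30_000),
                            rng.normal(-4.0, 0.1, 30_000),
                            rng.normal(-8.0, 0.1, 20_000)])
        fit = cz.fit_amplitude_histogram(Trace(x, 10_000.0))
        assert fit.unitary_amplitude == pytest.approx(-4.0, abs=0.05)
        assert fit.peak_weights.sum() == pytest.approx(1.0)
        assert np.all(np.diff(fit.peak_means) > 0)

    def test_simulated_two_channel_trace(self, nv_scheme):
        paths = cz.simulate_ctmc(nv_scheme, 2, 60.0, seed=5)
        tr = cz.render_trace(paths, -2.5, 10_000.0, noise_sd=0.4,
                             filter_cutoff=2000.0, seed=6)
        fit = cz.fit_amplitude_histogram(tr)
        assert fit.unitary_amplitude == pytest.approx(-2.5, abs=0.1)

    def test_binomial_occupancy_of_peak_weights(self, nv_scheme):
        paths = cz.simulate_ctmc(nv_scheme, 2, 120.0, seed=8)
        tr = cz.render_trace(paths, -2.5, 10_000.0, noise_sd=0.25, seed=9)
        fit = cz.fit_amplitude_histogram(tr)
        p_o = cz.open_probability(nv_scheme)
        expected = np.array([p_o ** 2, 2 * p_o * (1 - p_o), (1 - p_o) ** 2])
        np.testing.assert_allclose(np.sort(fit.peak_weights), np.sort(expected),
                                   atol=0.07)

    def test_single_component_fails(self, rng):
        x = rng.normal(0.0, 0.1, 20_000)
        fit = cz.fit_amplitude_histogram(Trace(x, 10_000.0))
        assert fit.status == "failed"


def test_single_channel_dwell_distributions_shape(nv_scheme):
    """Open dwells are single-exponential; closed dwells need two components."""
    from scipy import stats

    paths = cz.simulate_ctmc(nv_scheme, 1, 3000.0, seed=17)
    table = cz.extract_dwells(cz.paths_to_idealized(paths))
    open_d = table.dwells[1]
    rate = nv_scheme.k_os + nv_scheme.k_of
    ks = stats.kstest(open_d, "expon", args=(0, 1 / rate))
    assert ks.pvalue > 0.01
    closed = table.dwells[0]
    # one- vs two-exponential likelihood-ratio: two components win decisively
    ll1 = np.sum(stats.expon.logpdf(closed, scale=closed.mean()))

    def ll2(params):
        w, s1, s2 = params
        pdf = w * stats.expon.pdf(closed, scale=s1) + (1 - w) * stats.expon.pdf(closed, scale=s2)
        return -np.sum(np.log(np.clip(pdf, 1e-300, None)))

    from scipy.optimize import minimize
    best = minimize(ll2, [0.5, 0.002, 1.5], method="Nelder-Mead").fun
    lr = 2 * (-best - ll1)
    assert lr > stats.chi2.ppf(0.999, df=2)
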