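"""Composite-generator construction, dwell likelihoods, ML fitting, bursts."""

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad

import chanzyme as cz
from chanzyme.core import DwellTable
from chanzyme.gating import _level_mixture


class TestStationaryDistribution:
    def test_symmetric_two_state_limit(self):
        s = cz.GatingScheme(k_so=1.0, k_os=1.0, k_of=0.0, k_fo=1.0)
        pi = cz.stationary_distribution(s)
        np.testing.assert_allclose(pi, [0.5, 0.5, 0.0], atol=1e-12)

    def test_closed_form_open_probability(self):
        s = cz.GatingScheme(k_so=1.0, k_os=0.5, k_of=100.0, k_fo=500.0)
        # P_o = 1 / (1 + k_os/k_so + k_of/k_fo) = 1/1.7
        assert cz.open_probability(s) == pytest.approx(1 / 1.7, rel=1e-10)

    def test_matches_long_simulation(self, nv_scheme):
        paths = cz.simulate_ctmc(nv_scheme, 1, 10_000.0, seed=3)
        p = paths[0]
        occ_open = p.durations[p.states == 1].sum() / p.durations.sum()
        assert occ_open == pytest.approx(cz.open_probability(nv_scheme), abs=0.02)

    def test_all_zero_rates_rejected(self):
        with pytest.raises(ValueError):
            cz.stationary_distribution(cz.GatingScheme(0, 0, 0, 0))


class TestComposeChannels:
    def test_single_channel_equals_scheme_generator(self, nv_scheme):
        m = cz.compose_channels(nv_scheme, 1)
        # states for N=1 are the unit occupation vectors; map back
        perm = [m.states.index(s) for s in [(1, 0, 0), (0, 1, 0), (0, 0, 1)]]
        Q = m.generator[np.ix_(perm, perm)]
        np.testing.assert_allclose(Q, nv_scheme.rate_matrix())

    @pytest.mark.parametrize("n,expected", [(1, 3), (2, 6), (3, 10), (5, 21)])
    def test_state_count_stars_and_bars(self, nv_scheme, n, expected):
        assert len(cz.compose_channels(nv_scheme, n).states) == expected

    @pytest.mark.parametrize("n", [1, 2, 3, 5, 12])
    def test_rows_sum_to_zero_and_binomial_levels(self, nv_scheme, n):
        m = cz.compose_channels(nv_scheme, n)
        np.testing.assert_allclose(m.generator.sum(axis=1), 0.0, atol=1e-9)
        assert np.all(m.generator - np.diag(np.diag(m.generator)) >= 0)
        p_o = cz.open_probability(nv_scheme)
        expected = stats.binom.pmf(np.arange(n + 1), n, p_o)
        np.testing.assert_allclose(m.level_distribution(), expected, atol=1e-10)

    def test_binomial_matches_null_space_solve(self, nv_scheme):
        # independent cross-check: solve pi Q = 0 on the composite directly
        m = cz.compose_channels(nv_scheme, 3)
        A = np.vstack([m.generator.T, np.ones(len(m.states))])
        b = np.zeros(len(m.states) + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(A, b, rcond=None)
        np.testing.assert_allclose(pi, m.stationary(), atol=1e-9)

    def test_invalid_channel_count_rejected(self, nv_scheme):
        with pytest.raises(ValueError):
            cz.compose_channels(nv_scheme, 0)


class TestLevelDwellPdf:
    def test_top_level_is_exponential_with_analytic_rate(self, nv_scheme):
        for n in (1, 3):
            m = cz.compose_channels(nv_scheme, n)
            rate = n * (nv_scheme.k_os + nv_scheme.k_of)
            t = np.linspace(0.01, 1.0, 20)
            np.testing.assert_allclose(cz.level_dwell_pdf(m, n, t),
                                       rate * np.exp(-rate * t), rtol=1e-8)

    @pytest.mark.parametrize("level", [0, 1, 2])
    def test_density_integrates_to_one(self, nv_scheme, level):
        m = cz.compose_channels(nv_scheme, 2)
        fn = lambda t: cz.level_dwell_pdf(m, level, [t])[0]
        # integrate the fast (flicker) and slow (burst) scales separately
        val = sum(quad(fn, a, b, limit=400)[0]
                  for a, b in [(1e-9, 0.05), (0.05, 200.0)])
        assert val == pytest.approx(1.0, abs=1e-5)

    @pytest.mark.parametrize("n,level", [(1, 0), (2, 0), (2, 1), (5, 2)])
    def test_component_count(self, nv_scheme, n, level):
        m = cz.compose_channels(nv_scheme, n)
        c, lam = _level_mixture(m, level)
        assert lam.size == n - level + 1

    def test_never_entered_level_rejected(self):
        s = cz.GatingScheme(k_so=1.0, k_os=1.0, k_of=0.0, k_fo=0.0)
        m = cz.compose_channels(s, 1)
        # with k_of = 0 the flicker state is unreachable; level 0 only has
        # the C_slow state, which is fine, but a 2-channel top entry works:
        with pytest.raises(ValueError):
            # nonpositive t is rejected before any flux logic
            cz.level_dwell_pdf(m, 1, [0.0])


class TestDwellLoglik:
    def test_single_top_dwell_closed_form(self, nv_scheme):
        n, t = 2, 0.37
        m = cz.compose_channels(nv_scheme, n)
        rate = n * (nv_scheme.k_os + nv_scheme.k_of)
        table = DwellTable({n: np.array([t])}, {n: t})
        assert cz.dwell_loglik(m, table) == pytest.approx(np.log(rate) - rate * t)

    def test_permutation_invariance(self, nv_scheme, rng):
        m = cz.compose_channels(nv_scheme, 2)
        d = rng.exponential(0.3, 50)
        t1 = DwellTable({1: d, 0: d[:10]}, {})
        t2 = DwellTable({1: rng.permutation(d), 0: d[:10][::-1]}, {})
        assert cz.dwell_loglik(m, t1) == pytest.approx(cz.dwell_loglik(m, t2))

    def test_mean_loglik_approaches_negative_entropy(self, nv_scheme):
        # for the (exponential) top level the differential entropy is
        # 1 - log(rate); the mean log-density of simulated dwells must
        # approach its negative
        n = 1
        rate = nv_scheme.k_os + nv_scheme.k_of
        rng = np.random.default_rng(7)
        d = rng.exponential(1 / rate, 20_000)
        m = cz.compose_channels(nv_scheme, n)
        ll = cz.dwell_loglik(m, DwellTable({1: d}, {})) / d.size
        assert ll == pytest.approx(np.log(rate) - 1.0, abs=0.02)

    def test_nonpositive_dwell_rejected(self, nv_scheme):
        m = cz.compose_channels(nv_scheme, 1)
        table = DwellTable({1: np.array([0.1])}, {})
        table.dwells[1] = np.array([-0.1])  # bypass constructor validation
        with pytest.raises(ValueError):
            cz.dwell_loglik(m, table)


class TestBurstStats:
    def test_no_flicker_limit(self):
        s = cz.GatingScheme(k_so=0.5, k_os=2.0, k_of=0.0, k_fo=100.0)
        b = cz.burst_stats(s)
        assert b["tau_b"] == pytest.approx(0.5)
        assert b["openings_per_burst"] == pytest.approx(1.0)
        assert b["tau_ib"] == pytest.approx(2.0)

    def test_reference_scheme_values(self, nv_scheme):
        b = cz.burst_stats(nv_scheme)
        assert b["tau_b"] == pytest.approx(1.50, abs=0.01)
        assert b["tau_ib"] == pytest.approx(1.49, abs=0.01)
        assert b["openings_per_burst"] == pytest.approx(5.0)

    def test_absorbing_flicker_rejected(self):
        with pytest.raises(ValueError, match="absorbing"):
            cz.burst_stats(cz.GatingScheme(1.0, 1.0, 1.0, 0.0))

    @pytest.mark.parametrize("topology", ["C-O-C", "C-C-O"])
    def test_formulas_match_path_segmentation(self, topology):
        if topology == "C-O-C":
            s = cz.GatingScheme(0.67, 0.67, 2.68, 500.0, topology=topology)
        else:
            s = cz.GatingScheme(0.67, 100.0, 3.0, 400.0, topology=topology)
        paths = cz.simulate_ctmc(s, 1, 20_000.0, seed=42)
        seg = cz.segment_bursts(paths[0].states, paths[0].durations,
                                topology=topology)
        b = cz.burst_stats(s)
        assert seg["burst"].size > 1000
        assert seg["burst"].mean() == pytest.approx(b["tau_b"], rel=0.05)
        assert seg["interburst"].mean() == pytest.approx(b["tau_ib"], rel=0.05)


class TestChannelCountPvalue:
    def test_no_evidence(self):
        assert cz.channel_count_pvalue(0.0, 1.0) == 1.0

    def test_ten_interburst_times(self):
        p = cz.channel_count_pvalue(10.0, 1.0)
        assert p == pytest.approx(np.exp(-10), rel=1e-12)
        assert p < 0.001

    def test_invalid_tau_rejected(self):
        with pytest.raises(ValueError):
            cz.channel_count_pvalue(1.0, 0.0)


class TestFitGating:
    def test_single_channel_rate_recovery(self, nv_scheme):
        paths = cz.simulate_ctmc(nv_scheme, 1, 2000.0, seed=11)
        dwells = cz.extract_dwells(cz.paths_to_idealized(paths))
        fit = cz.fit_gating(dwells, 1, seed=3)
        assert fit.convergence == "converged"
        truth = nv_scheme.rates()
        for k, v in fit.rates.rates().items():
            assert v == pytest.approx(truth[k], rel=0.15), k
        assert all(se > 0 and np.isfinite(se) for se in fit.std_errors.values())

    def test_n_below_max_level_rejected(self, nv_scheme):
        dwells = DwellTable({0: np.array([1.0]), 3: np.array([0.5])}, {})
        with pytest.raises(ValueError, match="maximum observed level"):
            cz.fit_gating(dwells, 2)

    def test_no_openings_is_unidentifiable(self):
        dwells = DwellTable({0: np.linspace(0.1, 1, 60)}, {0: 33.0})
        fit = cz.fit_gating(dwells, 1)
        assert fit.convergence == "failed"

    def test_topology_independent_burst_durations(self, nv_scheme):
        paths = cz.simulate_ctmc(nv_scheme, 1, 1500.0, seed=19)
        dwells = cz.extract_dwells(cz.paths_to_idealized(paths))
        fit_coc = cz.fit_gating(dwells, 1, topology="C-O-C", seed=3)
        fit_cco = cz.fit_gating(dwells, 1, topology="C-C-O", seed=3)
        assert fit_cco.tau_b == pytest.approx(fit_coc.tau_b, rel=0.05)
        assert fit_cco.tau_ib == pytest.approx(fit_coc.tau_ib, rel=0.05)
        assert fit_cco.P_o == pytest.approx(fit_coc.P_o, rel=0.05)


def test_top_level_dwells_pass_exponential_ks(nv_scheme):
    """KS test of simulated top-level dwells against Exp(N(k_os+k_of))."""
    n = 2
    paths = cz.simulate_ctmc(nv_scheme, n, 4000.0, seed=29)
    dwells = cz.extract_dwells(cz.paths_to_idealized(paths))
    top = dwells.dwells[n]
    rate = n * (nv_scheme.k_os + nv_scheme.k_of)
    res = stats.kstest(top, "expon", args=(0, 1 / rate))
    assert top.size > 200
    assert res.pvalue > 0.01
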