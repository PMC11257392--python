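"""Batch models: derivative structure, integration, and competition summaries."""

import math

import numpy as np
import pytest

from linphage.response import NutrientResponseParams
from linphage.wellmixed import (
    WellMixedParams,
    WellMixedState,
    competition_outcome,
    default_batch_init,
    derivative,
    final_phage_ratio_separate,
    phage_host_crossing_time,
    simulate_batch,
    sweep_lin_grid,
)

N = 10


def make_state(**kw):
    st = WellMixedState.zeros(N)
    for k, v in kw.items():
        setattr(st, k, v)
    return st


class TestDerivative:
    def test_zero_state_zero_rate(self, default_params):
        d = derivative(make_state(), default_params)
        assert not np.any(d.to_vector())

    def test_uncoupled_growth_without_phage(self, default_params):
        st = make_state(B=1e6, n=1e9)
        d = derivative(st, default_params)
        g = 0.034 * (10.0 / 12.0)
        assert d.B == pytest.approx(g * 1e6, rel=1e-12)
        assert d.n == pytest.approx(-g * 1e6, rel=1e-12)
        assert d.R == d.P == 0.0
        assert not d.I_R.any() and not d.I_P.any() and not d.L.any()

    def test_infection_term_magnitude(self, default_params):
        # division minus adsorption at table defaults
        st = make_state(B=1e6, n=1e9, R=1e3)
        d = derivative(st, default_params)
        expected = 0.034 * (10.0 / 12.0) * 1e6 - 5e-10 * 1e3 * 1e6
        assert d.B == pytest.approx(expected, rel=1e-9)
        assert d.I_R[0] == pytest.approx(5e-10 * 1e3 * 1e6, rel=1e-12)

    def test_model_compartment_consistency_enforced(self):
        p = WellMixedParams(model_id="M0")
        with pytest.raises(ValueError):
            derivative(make_state(B=1.0, P=1.0), p)

    def test_nan_state_rejected(self, default_params):
        with pytest.raises(ValueError):
            derivative(make_state(B=float("nan")), default_params)


class TestSimulateBatch:
    def test_logistic_saturation_without_phage(self):
        """With no phage the culture converts all nutrient into cells:
        B(20 h) = n0 + B0."""
        p = WellMixedParams(model_id="M0")
        ts = simulate_batch(p, default_batch_init(p, R0=0.0))
        assert ts.B[-1] == pytest.approx(1.001e9, rel=1e-6)
        assert ts.n[-1] == pytest.approx(0.0, abs=1.0)

    def test_cell_nutrient_conservation_without_phage(self):
        p = WellMixedParams(model_id="M0")
        ts = simulate_batch(p, default_batch_init(p, R0=0.0), t_end=600.0)
        total = ts.B + ts.n
        assert np.max(np.abs(total - total[0]) / total[0]) < 1e-7

    def test_nonnegative_sampled_states(self, competition_55):
        assert competition_55.series.Y.min() >= 0.0

    def test_erlang_lysis_timing(self):
        """A pulse of freshly infected cells lyses at mean time tau(n): the
        lysis-flux-weighted mean of the N-stage chain."""
        p = WellMixedParams(model_id="M0")
        st = make_state(n=1e9)
        st.I_R[0] = 1e3
        t = np.arange(0.0, 120.0 + 1e-9, 0.25)
        ts = simulate_batch(p, st, t_end=120.0, sample_times=t)
        flux = ts.Y[:, 4 + N - 1]  # lysis flux ∝ I_R[N-1] at fixed n
        mean_t = np.trapezoid(t * flux, t) / np.trapezoid(flux, t)
        assert mean_t == pytest.approx(20.0, rel=1e-3)

    def test_lin_chain_erlang_timing(self):
        """The lysis-inhibited chain lyses at mean time f_tau * tau(n)."""
        f_tau = 5.0
        p = WellMixedParams(model_id="M1", f_tau=f_tau, f_beta=1.0)
        st = make_state(n=1e9)
        st.L[0] = 1e3
        t = np.arange(0.0, 500.0 + 1e-9, 0.25)
        ts = simulate_batch(p, st, t_end=500.0, sample_times=t)
        flux = ts.Y[:, 4 + 3 * N - 1]
        mean_t = np.trapezoid(t * flux, t) / np.trapezoid(flux, t)
        assert mean_t == pytest.approx(f_tau * 20.0, rel=1e-3)

    def test_chain_mass_balance_releases_beta_per_cell(self):
        """Every infected cell eventually releases beta(n0) phages when
        nothing re-adsorbs them."""
        p = WellMixedParams(model_id="M1", eta=1e-30, f_tau=5.0, f_beta=5.0)
        x = 1e3
        st = make_state(n=1e9)
        st.I_P[0] = x
        ts = simulate_batch(p, st, t_end=300.0)
        assert ts.P[-1] == pytest.approx(150.0 * x, rel=1e-6)

    @pytest.mark.parametrize("strain", ["r", "p"])
    def test_competition_model_embeds_single_strain_models(self, strain):
        """MC1 with one strain absent reproduces M0 (or M1) exactly."""
        if strain == "r":
            single = WellMixedParams(model_id="M0")
            init_kw = {"P0": 0.0}
        else:
            single = WellMixedParams(model_id="M1", f_tau=5.0, f_beta=5.0)
            init_kw = {"R0": 0.0}
        mc = WellMixedParams(
            model_id="MC1", f_tau=single.f_tau, f_beta=single.f_beta
        )
        ts_single = simulate_batch(single, default_batch_init(single), t_end=600.0)
        ts_mc = simulate_batch(mc, default_batch_init(mc, **init_kw), t_end=600.0)
        scale = np.abs(ts_single.Y).max()
        assert np.max(np.abs(ts_mc.Y - ts_single.Y)) / scale < 1e-6

    def test_phage_bookkeeping(self):
        """Cumulative production minus cumulative adsorption equals the net
        change of free phage."""
        from linphage.response import burst_size, growth_rate, stage_rate

        p = WellMixedParams(model_id="M0")
        t = np.arange(0.0, 600.0 + 1e-9, 0.5)
        ts = simulate_batch(p, t_end=600.0, sample_times=t)
        rp = p.response
        k = np.array([stage_rate(n, rp, 1.0) for n in ts.n])
        beta = np.array([burst_size(n, rp) for n in ts.n])
        produced = np.trapezoid(beta * k * ts.Y[:, 4 + N - 1], t)
        adsorbed = np.trapezoid(p.eta * ts.R * ts.B_tot, t)
        net = ts.R[-1] - ts.R[0]
        assert net == pytest.approx(produced - adsorbed, rel=5e-3)


class TestSeparateCultureRatio:
    def test_positive_at_unit_factors(self):
        assert final_phage_ratio_separate(1.0, 1.0) > 0.0

    def test_no_advantage_without_burst_increase(self):
        # longer latency alone loses in separate cultures
        assert final_phage_ratio_separate(5.0, 1.0) < 1.0

    def test_advantage_with_burst_increase(self):
        assert final_phage_ratio_separate(5.0, 5.0) > 1.0


class TestCompetition:
    def test_lin_dominates_at_five_five(self, competition_55):
        assert competition_55.ratio > 1.0

    def test_lin_wins_even_without_burst_increase(self):
        # adsorption by lysis-inhibited cells alone beats the r-mutant
        out = competition_outcome(5.0, 1.0)
        assert out.ratio > 1.0

    def test_r_mutant_declines_from_peak(self, competition_55):
        assert 0.0 < competition_55.peak_decline < 1.0

    def test_absent_r_strain_gives_zero_decline(self):
        p = WellMixedParams(model_id="MC1", f_tau=5.0, f_beta=5.0)
        out = competition_outcome(
            5.0, 5.0, init=default_batch_init(p, R0=0.0)
        )
        assert out.peak_decline == 0.0
        assert math.isinf(out.ratio)

    def test_crossing_time_brackets_sign_change(self, competition_55):
        ts = competition_55.series
        t_cross = competition_55.crossing_time
        assert t_cross is not None
        before = np.interp(t_cross - 2.0, ts.times, ts.R + ts.P - ts.B)
        after = np.interp(t_cross + 2.0, ts.times, ts.R + ts.P - ts.B)
        assert before < 0 < after

    def test_no_crossing_reported_as_none(self):
        p = WellMixedParams(model_id="MC1")
        init = default_batch_init(p, R0=1.0, P0=1.0)
        out = competition_outcome(1.0, 1.0, init=init, t_end=30.0)
        assert out.crossing_time is None


class TestSweep:
    def test_single_cell_matches_pointwise_operation(self):
        sw = sweep_lin_grid("competition", [5.0], [5.0], t_end=600.0)
        direct = competition_outcome(5.0, 5.0, t_end=600.0)
        assert 10 ** sw.log10_ratio[0, 0] == pytest.approx(direct.ratio, rel=1e-6)

    def test_separate_mode_monotone_in_f_beta(self):
        """A larger LIN burst can only increase the final LIN phage yield."""
        sw = sweep_lin_grid("separate", [1.0, 3.0, 5.0], [1.0, 3.0, 5.0])
        mat = sw.log10_ratio
        assert not sw.errors
        assert np.all(np.diff(mat, axis=1) > 0)

    def test_contour_separates_signs(self):
        sw = sweep_lin_grid("separate", [3.0], [1.0, 2.0, 3.0])
        # advantage region starts above f_beta = 1 (sign structure)
        assert sw.log10_ratio[0, 0] < 0 < sw.log10_ratio[0, -1]
        assert len(sw.contour) == 1
        assert 1.0 < sw.contour[0, 1] < 3.0

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError):
            sweep_lin_grid("separate", [0.5], [1.0])
        with pytest.raises(ValueError):
            sweep_lin_grid("separate", [], [1.0])
        with pytest.raises(ValueError):
            sweep_lin_grid("bogus", [1.0], [1.0])
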