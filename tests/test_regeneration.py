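"""Unit and property tests for the delayed feedback cell-cycle model."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hbcregen import (
    CellCycleParams,
    OEState,
    RegenerationModel,
    basal_state,
    hill_rate,
    rhs,
    simulate,
)
from hbcregen.regeneration import FitWarning

from conftest import rk4_trajectory


class TestHillRate:
    @pytest.mark.parametrize(
        "D,kmax,K,h,expected",
        [
            (0.0, 2.27, 0.4, 2.0, 2.27),       # no feedback at D = 0
            (0.4, 2.27, 0.4, 2.0, 2.27 / 2),   # half-max at D = K
            (0.8, 2.27, 0.4, 2.0, 0.454),      # 2.27 / (1 + 2**2)
            (1.0, 1.0, 1.0, 1.0, 0.5),
        ],
    )
    def test_values(self, D, kmax, K, h, expected):
        assert hill_rate(D, kmax, K, h) == pytest.approx(expected, rel=1e-12)

    @given(st.floats(0.0, 100.0), st.floats(0.01, 100.0))
    @settings(max_examples=50, deadline=None)
    def test_strictly_decreasing_in_D(self, D, dD):
        k_lo = hill_rate(D + dD, 2.27, 0.4, 2.0)
        k_hi = hill_rate(D, 2.27, 0.4, 2.0)
        assert k_lo < k_hi

    def test_vanishes_at_large_D(self):
        assert hill_rate(1e12, 2.27, 0.4, 2.0) < 1e-12

    @pytest.mark.parametrize("kwargs", [dict(kmax=0.0), dict(K=0.0),
                                        dict(kmax=-1.0), dict(h=0.5)])
    def test_invalid_parameters(self, kwargs):
        args = dict(D=0.1, kmax=1.0, K=1.0, h=2.0)
        args.update(kwargs)
        with pytest.raises(ValueError):
            hill_rate(args["D"], args["kmax"], args["K"], args["h"])


class TestRhs:
    @given(
        st.floats(0.0, 1.0), st.floats(0.0, 1.0), st.floats(0.0, 1.0),
        st.floats(0.0, 5.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_hbc_pool_conserved(self, h1, h2, h3, d):
        params = CellCycleParams()
        dh1, dh2, dh3, _ = rhs(OEState(h1, h2, h3, d), params)
        assert dh1 + dh2 + dh3 == pytest.approx(0.0, abs=1e-12)

    def test_all_in_g1(self, printed_cycle_params):
        p = printed_cycle_params
        d = rhs(OEState(1.0, 0.0, 0.0, 0.0), p)
        assert d == pytest.approx((-p.kmax, p.kmax, 0.0, 0.0))

    def test_flux_balanced_state_is_fixed_point(self, printed_cycle_params):
        # solve the balance k1(D)*H1 = k2*H2 = k3*H3, gamma*D = k3*H3 by hand:
        # pick H3, then H2 = k3*H3/k2, D = k3*H3/gamma, H1 = k3*H3/k1(D)
        p = printed_cycle_params
        h3 = 0.01
        h2 = p.k3 * h3 / p.k2
        D = p.k3 * h3 / p.gamma
        k1 = hill_rate(D, p.kmax, p.K, p.h)
        h1 = p.k3 * h3 / k1
        deriv = rhs(OEState(h1, h2, h3, D), p)
        assert np.abs(deriv).max() < 1e-12

    def test_negative_state_rejected(self):
        with pytest.raises(ValueError):
            OEState(-0.1, 0.5, 0.1, 0.0)


class TestBasalState:
    def test_flux_balance_completion(self, printed_cycle_params):
        s = basal_state(0.065, printed_cycle_params)
        # independent evaluation: H3 = k2*H2/k3 = 1.33*0.065/6
        assert s.H3 == pytest.approx(1.33 * 0.065 / 6.0, rel=1e-12)
        assert s.H3 == pytest.approx(0.0144, abs=5e-5)
        assert s.H1 == pytest.approx(0.9206, abs=5e-5)
        assert s.total_hbc == pytest.approx(1.0, abs=1e-12)
        assert s.D == 0.0

    def test_vanishing_basal_fraction(self, printed_cycle_params):
        s = basal_state(1e-9, printed_cycle_params)
        assert s.H1 == pytest.approx(1.0, abs=1e-8)
        assert s.H3 == pytest.approx(0.0, abs=1e-8)

    @pytest.mark.parametrize("h2", [0.0, 1.0, 0.95, -0.1])
    def test_invalid_basal_fraction(self, h2, printed_cycle_params):
        with pytest.raises(ValueError):
            basal_state(h2, printed_cycle_params)


class TestSimulate:
    def test_delay_longer_than_grid_holds_initial_state(self, printed_cycle_params):
        p = printed_cycle_params.replace(tau=100.0)
        init = basal_state(0.065, p)
        traj = simulate(p, init, np.linspace(0, 14, 29))
        assert np.allclose(traj.values, init.as_vector(), atol=0)

    def test_d_nondecreasing_without_turnover(self, printed_cycle_params):
        p = printed_cycle_params.replace(gamma=0.0)
        init = basal_state(0.065, p)
        traj = simulate(p, init, np.linspace(0, 14, 141))
        assert np.all(np.diff(traj.D) >= -1e-9)

    def test_conservation_and_nonnegativity(self, printed_cycle_params):
        init = basal_state(0.065, printed_cycle_params)
        traj = simulate(printed_cycle_params, init, np.linspace(0, 14, 281))
        total = traj.H1 + traj.H2 + traj.H3
        assert np.abs(total - 1.0).max() < 1e-6
        assert traj.values.min() >= 0.0

    def test_h2_rises_peaks_and_relaxes(self, printed_cycle_params):
        """Post-injury S-phase dynamics: single interior peak, near-basal
        again by day 14, matching the independent RK4 oracle."""
        p = printed_cycle_params
        init = basal_state(0.065, p)
        days = np.arange(0.0, 14.5, 0.5)
        traj = simulate(p, init, days)
        h2 = traj.H2
        i_peak = int(h2.argmax())
        assert 0 < i_peak < len(days) - 1
        assert days[i_peak] > p.tau
        # single interior maximum: rises up to the peak, falls after
        assert np.all(np.diff(h2[days >= p.tau][: i_peak - np.searchsorted(days, p.tau) + 1]) > 0)
        assert np.all(np.diff(h2[i_peak:]) < 0)
        assert h2[-1] < 0.2 * h2[i_peak]
        # oracle agreement: fixed-step RK4 at 1e-4 day from tau
        t_check = np.array([1.0, 2.0, 5.0, 14.0])
        oracle = rk4_trajectory(p, init.as_vector(), p.tau, t_check)
        model = traj.values[np.searchsorted(days, t_check)]
        assert np.abs(oracle - model).max() < 1e-5

    def test_steady_state_is_fixed_point(self, printed_cycle_params):
        p = printed_cycle_params
        h3 = 0.01
        D = p.k3 * h3 / p.gamma
        k1 = hill_rate(D, p.kmax, p.K, p.h)
        init = OEState(p.k3 * h3 / k1, p.k3 * h3 / p.k2, h3, D)
        traj = simulate(p, init, np.linspace(0, 10, 11))
        assert np.abs(traj.values - init.as_vector()).max() < 1e-7

    def test_bad_grid_rejected(self, printed_cycle_params):
        init = basal_state(0.065, printed_cycle_params)
        with pytest.raises(ValueError):
            simulate(printed_cycle_params, init, [0.0, 2.0, 1.0])
        with pytest.raises(ValueError):
            simulate(printed_cycle_params, init, [-1.0, 2.0])


class TestFit:
    def _noiseless_data(self, params, days=(0.0, 1, 2, 3, 5, 7, 14)):
        days = np.asarray(days, dtype=float)
        traj = simulate(params, basal_state(0.065, params), np.unique(np.r_[0.0, days]))
        h2 = np.interp(days, traj.times, traj.H2)
        return pd.DataFrame({"day": days, "fraction": h2})

    def test_recovers_kmax_from_noiseless_data(self, printed_cycle_params):
        data = self._noiseless_data(printed_cycle_params)
        model = RegenerationModel(data, params0=printed_cycle_params.replace(kmax=1.0),
                                  h2_basal=0.065)
        res = model.fit(free=("kmax",))
        assert res.params.kmax == pytest.approx(2.27, rel=1e-4)
        assert res.ssr < 1e-12

    def test_zero_residual_with_nothing_free(self, printed_cycle_params):
        data = self._noiseless_data(printed_cycle_params)
        res = RegenerationModel(data, params0=printed_cycle_params,
                                h2_basal=0.065).fit(free=())
        assert res.ssr == pytest.approx(0.0, abs=1e-16)

    def test_integer_hill_search_recovers_h(self, printed_cycle_params):
        data = self._noiseless_data(printed_cycle_params)
        model = RegenerationModel(
            data, params0=printed_cycle_params.replace(kmax=1.0, h=1.0),
            h2_basal=0.065)
        res = model.fit(free=("kmax", "h"))
        assert res.params.h == 2.0
        assert res.params.kmax == pytest.approx(2.27, rel=1e-3)

    def test_counts_and_fraction_inputs_agree(self, printed_cycle_params):
        data = self._noiseless_data(printed_cycle_params)
        counts = pd.DataFrame({
            "day": data["day"],
            "n_cells": 10_000_000,
            "n_positive": np.round(data["fraction"] * 10_000_000).astype(int),
        })
        r1 = RegenerationModel(data, printed_cycle_params.replace(kmax=1.5),
                               h2_basal=0.065).fit(free=("kmax",))
        r2 = RegenerationModel(counts, printed_cycle_params.replace(kmax=1.5),
                               h2_basal=0.065).fit(free=("kmax",))
        assert r1.params.kmax == pytest.approx(r2.params.kmax, rel=1e-4)

    def test_underdetermined_configuration_rejected(self, printed_cycle_params):
        data = pd.DataFrame({"day": [2.0], "fraction": [0.4]})
        with pytest.raises(ValueError):
            RegenerationModel(data, printed_cycle_params).fit(free=("kmax", "tau"))

    def test_flat_objective_flagged(self, printed_cycle_params):
        # with data only at day 0 = basal, kmax has no leverage before tau
        data = pd.DataFrame({"day": [0.0], "fraction": [0.065]})
        model = RegenerationModel(data, printed_cycle_params, h2_basal=0.065)
        with pytest.warns(FitWarning):
            res = model.fit(free=("kmax",))
        assert res.flat_objective

    def test_noisy_recovery_bounded(self, printed_cycle_params):
        """Median kmax recovery error from binomially sampled counts
        (200 cells/day) stays near the sampling-noise floor (~10%,
        by the Monte-Carlo sampling distribution over these seeds)."""
        from hbcregen import gen_edu_timecourse

        rel_err = []
        for s in range(50):
            df, _ = gen_edu_timecourse(printed_cycle_params, 0.065,
                                       [0.0, 1, 2, 3, 5, 7, 14], 200, seed=s)
            res = RegenerationModel(df, printed_cycle_params.replace(kmax=1.0),
                                    h2_basal=0.065).fit(free=("kmax",))
            rel_err.append(abs(res.params.kmax - 2.27) / 2.27)
        assert np.median(rel_err) < 0.15

    def test_summary_mentions_free_parameters(self, printed_cycle_params):
        data = self._noiseless_data(printed_cycle_params)
        res = RegenerationModel(data, printed_cycle_params, h2_basal=0.065).fit(free=("kmax",))
        text = res.summary()
        assert "kmax" in text and "residual sum of squares" in text
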