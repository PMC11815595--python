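"""Integrator accuracy and trajectory-level invariants."""

import math

import numpy as np
import pytest

import violakin as vk
from violakin.simulate import integrate_rk4

MS = vk.BATCH_FIT_MONOD_SIGMOID
MT = vk.ModelType


def exponential_rhs(mu):
    def rhs(t, y):
        return (mu * y[0], 0.0, 0.0, 0.0)

    return rhs


class TestIntegrateRK4:
    def test_exponential_closed_form(self):
        init = vk.CultureState(7.0, 1.0, 1.0, 1.0)
        traj = integrate_rk4(exponential_rhs(0.3), init, 0.0, 1.0, 0.01)
        assert traj.biomass[-1] == pytest.approx(7.0 * math.exp(0.3),
                                                 rel=1e-9)

    def test_zero_field_constant_state(self):
        init = vk.CultureState(3.0, 2.0, 1.0, 1.5)
        traj = integrate_rk4(lambda t, y: (0.0,) * 4, init, 0.0, 5.0, 0.1)
        assert np.allclose(traj.states, traj.states[0])

    def test_fourth_order_convergence(self):
        """Halving the step divides the global error by ~16."""
        init = vk.CultureState(7.0, 1.0, 1.0, 1.0)
        exact = 7.0 * math.exp(0.3)
        errors = {}
        for dt in (0.02, 0.01):
            traj = integrate_rk4(exponential_rhs(0.3), init, 0.0, 1.0, dt)
            errors[dt] = abs(traj.biomass[-1] - exact)
        ratio = errors[0.02] / errors[0.01]
        assert ratio == pytest.approx(16.0, rel=0.1)

    def test_nonfinite_derivative_reports_time(self):
        def bad(t, y):
            return (float("nan"), 0.0, 0.0, 0.0) if t > 0.5 \
                else (0.1, 0.0, 0.0, 0.0)

        init = vk.CultureState(1.0, 1.0, 1.0, 1.0)
        with pytest.raises(vk.IntegrationError, match="t="):
            integrate_rk4(bad, init, 0.0, 1.0, 0.01)

    def test_invalid_time_grid_rejected(self):
        init = vk.CultureState(1.0, 1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            integrate_rk4(exponential_rhs(0.1), init, 1.0, 1.0, 0.01)
        with pytest.raises(ValueError):
            integrate_rk4(exponential_rhs(0.1), init, 0.0, 1.0, 2.0)

    def test_t_eval_exact_sampling(self):
        init = vk.CultureState(7.0, 1.0, 1.0, 1.0)
        times = [0.0, 0.3, 1.7, 2.0]
        traj = integrate_rk4(exponential_rhs(0.3), init, 0.0, 2.0, 0.01,
                             t_eval=times)
        assert np.allclose(traj.times, times)
        assert traj.biomass[2] == pytest.approx(7.0 * math.exp(0.3 * 1.7),
                                                rel=1e-9)


class TestSimulateBatch:
    def test_substrates_monotone_biomass_grows(self, ms_params, ms_model,
                                               batch_init):
        traj = vk.simulate_batch(ms_params, ms_model, batch_init, 20.0)
        assert np.all(np.diff(traj.sucrose) <= 1e-12)
        assert np.all(np.diff(traj.kno3) <= 1e-12)
        growing = (traj.sucrose[:-1] > 1e-9) & (traj.kno3[:-1] > 1e-9)
        assert np.all(np.diff(traj.biomass)[growing] >= -1e-12)
        assert np.all(traj.states >= 0.0)

    def test_nitrate_limited_plateau_bound(self, ms_params, ms_model,
                                           batch_init):
        """Yield conservation caps biomass at x0 + Y_X/S2 * s2(0)."""
        traj = vk.simulate_batch(ms_params, ms_model, batch_init, 20.0)
        cap = batch_init.x + ms_params.y_xs2 * batch_init.s2  # 23.19
        assert traj.biomass[-1] <= cap + 1e-6
        assert traj.biomass[-1] > 20.0  # and the culture actually grew

    def test_first_integral_without_maintenance(self, ms_model, batch_init):
        p = MS.with_(m_s1=0.0, m_s2=0.0)
        traj = vk.simulate_batch(p, ms_model, batch_init, 4.0)
        inv1 = traj.biomass + p.y_xs1 * traj.sucrose
        inv2 = traj.biomass + p.y_xs2 * traj.kno3
        assert np.max(np.abs(inv1 / inv1[0] - 1)) < 1e-6
        assert np.max(np.abs(inv2 / inv2[0] - 1)) < 1e-6

    def test_no_sucrose_no_growth(self, ms_params, ms_model):
        init = vk.CultureState(7.0, 0.0, 2.1, 1.2)
        traj = vk.simulate_batch(ms_params, ms_model, init, 5.0)
        assert np.allclose(traj.biomass, 7.0)

    def test_step_independence(self, ms_params, ms_model, batch_init):
        times = np.arange(1.0, 21.0)
        a = vk.simulate_batch(ms_params, ms_model, batch_init, 20.0,
                              0.01, t_eval=times)
        b = vk.simulate_batch(ms_params, ms_model, batch_init, 20.0,
                              0.005, t_eval=times)
        rel = np.abs(a.states[:, :3] - b.states[:, :3]) / (
            np.abs(b.states[:, :3]) + 1e-12)
        assert rel.max() < 1e-5


class TestSimulateFedbatch:
    def test_zero_flow_identical_to_batch(self, ms_params, ms_model,
                                          batch_init):
        feed = vk.FeedStrategy(v0=1.2, t_feed_start=10, t_end=17,
                               flow=0.0, feed_s1=250, feed_s2=15)
        fb = vk.simulate_fedbatch(ms_params, ms_model, feed,
                                  init=batch_init,
                                  t_eval=np.arange(1.0, 18.0))
        b = vk.simulate_batch(ms_params, ms_model, batch_init, 17.0,
                              t_eval=np.arange(1.0, 18.0))
        assert np.allclose(fb.states[:, :3], b.states[:, :3],
                           rtol=1e-12, atol=1e-12)

    def test_linear_volume_growth(self, ms_params, ms_model, paper_feed):
        traj = vk.simulate_fedbatch(ms_params, ms_model, paper_feed)
        assert traj.volume[-1] == pytest.approx(1.2 + 0.072 * 7, rel=1e-9)
        before = traj.volume[traj.times <= 10.0]
        assert np.allclose(before, 1.2)

    def test_total_biomass_accounting(self, ms_params, ms_model,
                                      paper_feed):
        """VX(t) - VX(0) = integral of mu V X dt: no biomass enters with
        the feed, so total biomass grows only by growth itself."""
        from scipy.integrate import cumulative_trapezoid

        traj = vk.simulate_fedbatch(ms_params, ms_model, paper_feed)
        vx = traj.volume * traj.biomass
        mu = np.array([
            vk.specific_growth_rate(ms_params, ms_model, s1, s2)
            for s1, s2 in zip(traj.sucrose, traj.kno3)
        ])
        integral = cumulative_trapezoid(mu * vx, traj.times, initial=0.0)
        assert np.allclose(vx - vx[0], integral, rtol=1e-3, atol=5e-3)

    def test_substrate_total_accounting(self, ms_params, ms_model,
                                        paper_feed):
        """V S1 balances consumption against the fed sucrose mass."""
        from scipy.integrate import cumulative_trapezoid

        traj = vk.simulate_fedbatch(ms_params, ms_model, paper_feed)
        mu = np.array([
            vk.specific_growth_rate(ms_params, ms_model, s1, s2)
            for s1, s2 in zip(traj.sucrose, traj.kno3)
        ])
        consumption = (mu / ms_params.y_xs1 + ms_params.m_s1) * \
            traj.biomass * traj.volume
        fed = paper_feed.feed_s1 * (traj.volume - traj.volume[0])
        balance = cumulative_trapezoid(-consumption, traj.times,
                                       initial=0.0) + fed
        vs1 = traj.volume * traj.sucrose
        assert np.allclose(vs1 - vs1[0], balance, rtol=1e-3, atol=0.02)

    def test_all_states_nonnegative(self, ms_params, ms_model, paper_feed):
        traj = vk.simulate_fedbatch(ms_params, ms_model, paper_feed)
        assert np.all(traj.states >= 0.0)

    def test_mismatched_init_volume_rejected(self, ms_params, ms_model,
                                             paper_feed):
        init = vk.CultureState(7.0, 45.6, 2.1, 2.0)
        with pytest.raises(ValueError):
            vk.simulate_fedbatch(ms_params, ms_model, paper_feed,
                                 init=init)


class TestTrajectoryContainer:
    def test_csv_round_trip(self, ms_params, ms_model, batch_init,
                            tmp_path):
        traj = vk.simulate_batch(ms_params, ms_model, batch_init, 5.0,
                                 t_eval=np.arange(1.0, 6.0))
        path = tmp_path / "traj.csv"
        traj.write_csv(path)
        header = path.read_text().splitlines()[0]
        assert header == "time_d,biomass_gDW_L,sucrose_g_L,kno3_g_L,volume_L"
        df = traj.to_dataframe()
        assert len(df) == len(traj.times)

    def test_non_monotone_times_rejected(self):
        with pytest.raises(ValueError):
            vk.Trajectory(np.array([0.0, 1.0, 1.0]), np.zeros((3, 4)))
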