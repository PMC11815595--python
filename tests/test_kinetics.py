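"""Growth-kernel and vector-field unit/property tests."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import violakin as vk
from violakin.kinetics import fedbatch_rhs, batch_rhs

MS = vk.BATCH_FIT_MONOD_SIGMOID
MT = vk.ModelType


class TestLuongFactor:
    @pytest.mark.parametrize(
        "s, s_m, n, expected",
        [
            (0.0, 179.24, 0.60, 1.0),  # no substrate, no inhibition
            (179.24, 179.24, 0.60, 0.0),  # at the ceiling growth stops
            (200.0, 179.24, 0.60, 0.0),  # clamped above the ceiling
            # arithmetic oracle: 1 - (45.6/179.24)**0.60
            (45.6, 179.24, 0.60, 0.5601365),
            # and for the nitrate ceiling: 1 - (2.1/16.14)**1.07
            (2.1, 16.14, 1.07, 0.8871977),
        ],
    )
    def test_values(self, s, s_m, n, expected):
        assert vk.luong_factor(s, s_m, n) == pytest.approx(expected,
                                                           abs=1e-6)

    @pytest.mark.parametrize(
        "s, s_m, n",
        [(-1.0, 10.0, 1.0), (1.0, 0.0, 1.0), (1.0, -5.0, 1.0),
         (1.0, 10.0, -0.5)],
    )
    def test_domain_errors(self, s, s_m, n):
        with pytest.raises(ValueError):
            vk.luong_factor(s, s_m, n)

    @given(
        s=st.floats(0, 500),
        s_m=st.floats(1e-3, 500),
        n=st.floats(0, 5),
    )
    def test_bounded_unit_interval(self, s, s_m, n):
        assert 0.0 <= vk.luong_factor(s, s_m, n) <= 1.0

    def test_monotone_decreasing_in_s(self):
        grid = np.linspace(0, 179.24, 50)
        vals = [vk.luong_factor(s, 179.24, 0.6) for s in grid]
        assert all(a >= b for a, b in zip(vals, vals[1:]))


class TestSpecificGrowthRate:
    def test_zero_without_sucrose(self):
        assert vk.specific_growth_rate(MS, MT.MONOD_SIGMOID, 0.0, 2.1) == 0.0

    def test_zero_at_nitrate_ceiling(self):
        assert vk.specific_growth_rate(MS, MT.MONOD_SIGMOID, 45.6,
                                       MS.s_m2) == 0.0

    def test_optimized_medium_rate(self):
        # frozen from the hand-evaluated kernel product:
        # 0.37 * 0.763052 * 0.998981 * 0.560136 * 0.887198 = 0.140161
        mu = vk.specific_growth_rate(MS, MT.MONOD_SIGMOID, 45.6, 2.1)
        assert mu == pytest.approx(0.140161, abs=1e-5)

    @given(s1=st.floats(0, 400), s2=st.floats(0, 40))
    def test_bounded_by_mu_max(self, s1, s2):
        mu = vk.specific_growth_rate(MS, MT.MONOD_SIGMOID, s1, s2)
        assert 0.0 <= mu <= MS.mu_max

    @given(s1=st.floats(179.24, 500), s2=st.floats(0.1, 15))
    def test_zero_at_or_above_sucrose_ceiling(self, s1, s2):
        assert vk.specific_growth_rate(MS, MT.MONOD_SIGMOID, s1, s2) == 0.0

    @given(s1=st.floats(0.01, 150), s2=st.floats(0.01, 12))
    def test_model_type_limit_equivalences(self, s1, s2):
        """Sigmoid kernels with unit exponents collapse onto Monod."""
        p_unit = MS.with_(n1=1.0, n2=1.0)
        mu_monod = vk.specific_growth_rate(p_unit, MT.MONOD, s1, s2)
        mu_msig = vk.specific_growth_rate(p_unit, MT.MONOD_SIGMOID, s1, s2)
        mu_sig = vk.specific_growth_rate(p_unit, MT.SIGMOID, s1, s2)
        assert mu_msig == pytest.approx(mu_monod, rel=1e-12)
        assert mu_sig == pytest.approx(mu_monod, rel=1e-12)


class TestUptakeRates:
    def test_no_cells_no_uptake(self):
        assert vk.uptake_rates(MS, 0.0, 0.0) == (0.0, 0.0)

    def test_maintenance_only(self):
        ds1, ds2 = vk.uptake_rates(MS, 0.0, 10.0)
        assert ds1 == pytest.approx(-0.6)
        assert ds2 == pytest.approx(-2.88e-3)

    def test_growth_coupled_consumption(self):
        p = MS.with_(y_xs1=0.5, m_s1=0.0)
        ds1, _ = vk.uptake_rates(p, 0.2, 10.0)
        assert ds1 == pytest.approx(-4.0)

    @given(mu=st.floats(0, 0.37), x=st.floats(0, 50))
    def test_both_nonpositive(self, mu, x):
        ds1, ds2 = vk.uptake_rates(MS, mu, x)
        assert ds1 <= 0.0 and ds2 <= 0.0


class TestBatchRHS:
    def test_no_biomass_all_zero(self):
        state = vk.CultureState(0.0, 45.6, 2.1, 1.0)
        assert batch_rhs(MS, MT.MONOD_SIGMOID, state) == (0, 0, 0, 0)

    def test_conservation_direction(self):
        """Without maintenance, x + Y*s is a first integral of the field."""
        p = MS.with_(m_s1=0.0, m_s2=0.0)
        state = vk.CultureState(7.0, 45.6, 2.1, 1.0)
        dx, ds1, ds2, _ = batch_rhs(p, MT.MONOD_SIGMOID, state)
        assert dx + p.y_xs1 * ds1 == pytest.approx(0.0, abs=1e-12)
        assert dx + p.y_xs2 * ds2 == pytest.approx(0.0, abs=1e-12)

    def test_growth_rate_at_start(self):
        state = vk.CultureState(7.0, 45.6, 2.1, 1.5)
        dx, *_ = batch_rhs(MS, MT.MONOD_SIGMOID, state)
        assert dx == pytest.approx(7.0 * 0.140161, rel=1e-4)

    def test_depleted_substrate_not_consumed(self):
        state = vk.CultureState(10.0, 0.0, 2.1, 1.0)
        _, ds1, _, _ = batch_rhs(MS, MT.MONOD_SIGMOID, state)
        assert ds1 == 0.0


class TestFedbatchRHS:
    def test_zero_flow_equals_batch(self, paper_feed):
        feed = vk.FeedStrategy(v0=1.2, t_feed_start=10, t_end=17,
                               flow=0.0, feed_s1=250, feed_s2=15)
        state = vk.CultureState(15.0, 20.0, 1.0, 1.2)
        assert fedbatch_rhs(MS, MT.MONOD_SIGMOID, state, feed, 12.0) == \
            batch_rhs(MS, MT.MONOD_SIGMOID, state)

    def test_dilution_rate_arithmetic(self):
        feed = vk.FeedStrategy(v0=1.2, t_feed_start=0, t_end=20,
                               flow=0.072, feed_s1=0, feed_s2=0)
        state = vk.CultureState(10.0, 20.0, 1.0, 1.2)
        dx_b, *_ = batch_rhs(MS, MT.MONOD_SIGMOID, state)
        dx_f, *_ = fedbatch_rhs(MS, MT.MONOD_SIGMOID, state, feed, 5.0)
        d = 0.072 / 1.2  # = 0.06 d^-1
        assert dx_b - dx_f == pytest.approx(d * state.x, rel=1e-12)

    @given(
        x=st.floats(0.1, 40), s1=st.floats(0.1, 100),
        s2=st.floats(0.1, 10), v=st.floats(0.5, 2.4),
        t=st.floats(10, 17),
    )
    def test_total_biomass_identity(self, x, s1, s2, v, t, paper_feed):
        """d(VX)/dt = mu V X: the dilution term cancels against dV/dt."""
        state = vk.CultureState(x, s1, s2, v)
        dx, _, _, dv = fedbatch_rhs(MS, MT.MONOD_SIGMOID, state,
                                    paper_feed, t)
        mu = vk.specific_growth_rate(MS, MT.MONOD_SIGMOID, s1, s2)
        assert v * dx + x * dv == pytest.approx(mu * v * x, rel=1e-9,
                                                abs=1e-12)

    def test_outside_window_is_batch(self, paper_feed):
        state = vk.CultureState(10.0, 30.0, 1.5, 1.2)
        assert fedbatch_rhs(MS, MT.MONOD_SIGMOID, state, paper_feed,
                            5.0) == batch_rhs(MS, MT.MONOD_SIGMOID, state)


class TestParameterValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [dict(y_xs1=0.0), dict(y_xs2=0.0), dict(s_m1=0.0), dict(s_m2=0.0),
         dict(mu_max=-0.1), dict(k_s1=float("nan"))],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        base = dict(
            y_xs1=0.5, y_xs2=7.7, mu_max=0.37, k_s1=14.0, k_s2=0.17,
            m_s1=0.06, m_s2=3e-4, s_m1=179.0, s_m2=16.0,
        )
        base.update(kwargs)
        with pytest.raises(ValueError):
            vk.KineticParameters(**base)

    def test_free_parameter_counts(self):
        assert len(vk.free_parameter_names(MT.MONOD)) == 11
        assert len(vk.free_parameter_names(MT.MONOD_SIGMOID)) == 12
        assert len(vk.free_parameter_names(MT.SIGMOID)) == 13

    def test_invalid_state_rejected(self):
        with pytest.raises(ValueError):
            vk.CultureState(-1.0, 1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            vk.CultureState(1.0, 1.0, 1.0, 0.0)
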