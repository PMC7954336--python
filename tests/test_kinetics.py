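"""Closed-form kinetics, steady states and their linear-algebra oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from nfsim import (
    EightStateRates,
    InvalidParameterError,
    KineticRates,
    PhosphoKinetics,
    SixPhosphoRates,
    mean_velocity,
    mm_per_day_to_um_per_s,
    phospho_equilibrium,
    phospho_weighted_velocity,
    q2_eight,
    q_coefficients_six,
    steady_state,
    steady_state_numeric,
    transition_matrix,
    um_per_s_to_mm_per_day,
)

rate = st.floats(1e-6, 1.0)
on_rate = st.floats(1e-5, 5e-3)
phospho_rate = st.floats(5e-2, 1.0)


def random_eight(draw_tuple):
    g10, g01, goff, gar, gra, gon1, gon2, gph, gde = draw_tuple
    return EightStateRates(
        base=KineticRates(
            gamma_10=g10, gamma_01=g01, gamma_off=goff, gamma_ar=gar, gamma_ra=gra
        ),
        gamma_on1=min(gon1, gon2),
        gamma_on2=max(gon1, gon2),
        phospho=PhosphoKinetics(gamma_ph=gph, gamma_de=gde),
    )


class TestQCoefficients:
    def test_canonical_defaults(self, base_rates):
        q = q_coefficients_six(base_rates)
        assert q.q1 == pytest.approx(2.1875)
        assert q.q3 == pytest.approx(0.3)

    def test_equal_off_on_gives_unit_q2(self):
        r = KineticRates(gamma_on=4.45e-3, gamma_off=4.45e-3)
        assert q_coefficients_six(r).q2 == pytest.approx(1.0)

    @pytest.mark.parametrize("g", [0.01, 0.5])
    def test_symmetric_pause_rates_give_unit_q1(self, g):
        r = KineticRates(gamma_10=g, gamma_01=g)
        assert q_coefficients_six(r).q1 == pytest.approx(1.0)

    def test_rejects_nonpositive_rates(self):
        with pytest.raises(InvalidParameterError):
            KineticRates(gamma_on=0.0)
        with pytest.raises(InvalidParameterError):
            KineticRates(gamma_10=-0.1)
        with pytest.raises(InvalidParameterError):
            KineticRates(v_r=0.36)


class TestQ2Eight:
    def test_internode_configuration(self, eight_internode):
        # 2*0.00445 / ((8/9)*2.75e-4 + (1/9)*5.16e-3)
        assert q2_eight(eight_internode) == pytest.approx(10.883152, rel=1e-6)

    def test_equal_on_rates_reduce_to_six_state_form(self):
        r = EightStateRates(gamma_on1=1e-3, gamma_on2=1e-3)
        assert q2_eight(r) == pytest.approx(2 * 4.45e-3 / 1e-3)

    def test_symmetric_phospho_averages_on_rates(self):
        r = EightStateRates(
            gamma_on1=1e-4,
            gamma_on2=4e-4,
            phospho=PhosphoKinetics(gamma_ph=0.3, gamma_de=0.3),
        )
        assert q2_eight(r) == pytest.approx(4 * 4.45e-3 / 5e-4)


class TestSteadyState:
    def test_eight_state_internode_occupancies(self, eight_internode):
        ss = steady_state(eight_internode)
        assert ss["Pap1"] == pytest.approx(0.603, rel=2e-2)
        assert ss["Pap2"] == pytest.approx(0.0754, rel=2e-2)
        assert ss["Prp1"] == pytest.approx(0.1809, rel=2e-2)
        assert ss["Prp2"] == pytest.approx(0.0226, rel=2e-2)

    def test_eight_state_node_occupancies(self, eight_node):
        ss = steady_state(eight_node)
        assert ss["Pa"] == pytest.approx(2.17e-1, rel=2e-2)
        assert ss["Pa0"] == pytest.approx(4.74e-1, rel=2e-2)

    @given(
        st.tuples(rate, rate, rate, rate, rate, on_rate, on_rate, phospho_rate, phospho_rate)
    )
    def test_probabilities_sum_to_one(self, params):
        ss = steady_state(random_eight(params))
        assert abs(ss.probabilities.sum() - 1.0) < 1e-10
        assert np.all(ss.probabilities >= 0)

    @given(st.tuples(rate, rate, rate, rate, rate, on_rate))
    def test_six_state_closed_form_is_null_eigenvector(self, params):
        g10, g01, goff, gar, gra, gon = params
        r = KineticRates(
            gamma_10=g10, gamma_01=g01, gamma_on=gon, gamma_off=goff,
            gamma_ar=gar, gamma_ra=gra,
        )
        closed = steady_state(r).probabilities
        numeric = steady_state_numeric(r).probabilities
        np.testing.assert_allclose(closed, numeric, atol=1e-9)
        M = transition_matrix(r)
        np.testing.assert_allclose(M @ closed, 0.0, atol=1e-12)

    @given(
        st.tuples(rate, rate, st.floats(1e-4, 5e-3), rate, rate, on_rate, on_rate,
                  phospho_rate, phospho_rate)
    )
    def test_eight_state_closed_form_matches_eigenvector_when_phospho_fast(
        self, params
    ):
        """The alpha-split of the off-track states is the fast-exchange
        approximation; with phospho rates well above the on/off rates it
        must agree with the exact null eigenvector."""
        r = random_eight(params)
        closed = steady_state(r, method="closed_form").probabilities
        numeric = steady_state_numeric(r).probabilities
        np.testing.assert_allclose(closed, numeric, atol=0.02)

    def test_six_phospho_requires_numeric(self):
        r = SixPhosphoRates()
        ss = steady_state(r)  # auto -> numeric
        assert ss.model_variant == "six_phospho"
        assert abs(ss.probabilities.sum() - 1.0) < 1e-10

    @given(
        st.tuples(rate, rate, rate, rate, rate, on_rate, on_rate, phospho_rate, phospho_rate)
    )
    def test_transition_matrix_columns_sum_to_zero(self, params):
        M = transition_matrix(random_eight(params))
        np.testing.assert_allclose(M.sum(axis=0), 0.0, atol=1e-15)

    def test_transition_matrix_columns_sum_to_zero_all_variants(self):
        for rates in (KineticRates(), SixPhosphoRates(), SixPhosphoRates(exchange_off_track=True)):
            M = transition_matrix(rates)
            np.testing.assert_allclose(M.sum(axis=0), 0.0, atol=1e-15)


class TestMeanVelocity:
    def test_six_state_internode_velocity(self, base_rates):
        assert mean_velocity(base_rates, units="mm/day") == pytest.approx(0.71, rel=2e-2)

    def test_eight_state_regional_velocities(self, eight_internode, eight_node):
        assert mean_velocity(eight_internode) == pytest.approx(0.0117, rel=2e-2)
        assert mean_velocity(eight_node) == pytest.approx(0.0890, rel=2e-2)

    def test_velocity_equals_occupancy_weighted_run_speeds(
        self, base_rates, eight_internode
    ):
        for r in (base_rates, eight_internode):
            ss = steady_state(r)
            assert mean_velocity(r) == pytest.approx(
                ss.velocity(r.v_a, r.v_r), rel=1e-12
            )

    def test_monotone_in_on_track_rate(self):
        vels = [
            mean_velocity(KineticRates(gamma_on=g))
            for g in np.logspace(-5, -1, 12)
        ]
        assert np.all(np.diff(vels) > 0)

    def test_monotone_in_gamma_on2(self):
        vels = [
            mean_velocity(EightStateRates(gamma_on2=g))
            for g in np.logspace(-4, -1, 12)
        ]
        assert np.all(np.diff(vels) > 0)

    def test_unit_conversion_round_trip(self):
        v = 0.0117
        assert mm_per_day_to_um_per_s(um_per_s_to_mm_per_day(v)) == pytest.approx(v)
        assert mm_per_day_to_um_per_s(1.0) == pytest.approx(1000.0 / 86400.0)


class TestPhospho:
    def test_equilibrium_fractions(self, phospho_internode):
        f_de, f_ph = phospho_equilibrium(phospho_internode)
        assert f_de == pytest.approx(1 / 9)
        assert f_ph == pytest.approx(8 / 9)

    def test_symmetric_rates_split_evenly(self):
        assert phospho_equilibrium(PhosphoKinetics(0.3, 0.3)) == pytest.approx((0.5, 0.5))

    def test_weighted_velocity_node_and_internode(
        self, phospho_node, phospho_internode
    ):
        v = 1.0  # slow velocity sets the scale
        v_node = phospho_weighted_velocity(7.6 * v, v, phospho_node)
        v_inter = phospho_weighted_velocity(7.6 * v, v, phospho_internode)
        assert v_node == pytest.approx(61.8 / 9)
        assert v_inter == pytest.approx(15.6 / 9)
        assert v_node / v_inter == pytest.approx(3.96, abs=5e-3)

    def test_limits_of_phospho_ratio(self):
        v_fast, v_slow = 7.6, 1.0
        heavy = PhosphoKinetics(gamma_ph=1e6, gamma_de=1e-6)
        none = PhosphoKinetics(gamma_ph=1e-6, gamma_de=1e6)
        assert phospho_weighted_velocity(v_fast, v_slow, heavy) == pytest.approx(v_slow, rel=1e-5)
        assert phospho_weighted_velocity(v_fast, v_slow, none) == pytest.approx(v_fast, rel=1e-5)

    def test_rejects_invalid(self):
        with pytest.raises(InvalidParameterError):
            PhosphoKinetics(gamma_ph=0.0, gamma_de=0.0)
        with pytest.raises(InvalidParameterError):
            phospho_weighted_velocity(1.0, 2.0, PhosphoKinetics(0.1, 0.1))

    def test_gamma_on1_above_gamma_on2_warns(self):
        with pytest.warns(UserWarning):
            EightStateRates(gamma_on1=1e-2, gamma_on2=1e-4)
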