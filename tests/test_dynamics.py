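"""Unit tests of the model right-hand sides and the promoter response."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hisicc import observe, promoter_response, rhs_ta1415, rhs_ta2445
from hisicc.params import QuorumParams


Q = QuorumParams(k_A=1913.7, d_A=0.1489, K_A=1.596, K_u=0.02268,
                 n_A=1.752, n_u=1.597)


class TestPromoterResponse:
    def test_quarter_at_both_dissociation_constants(self):
        assert promoter_response(Q.K_A, Q.K_u, Q) == pytest.approx(0.25)

    @pytest.mark.parametrize("A,u", [(0.0, 1.0), (5.0, 0.0), (0.0, 0.0)])
    def test_zero_when_either_ligand_absent(self, A, u):
        assert promoter_response(A, u, Q) == 0.0

    def test_value_one_decade_above_both_constants(self):
        # hand evaluation of 10^n/(10^n+1) for each Hill factor
        assert promoter_response(10 * Q.K_A, 10 * Q.K_u, Q) == pytest.approx(
            0.958366836017356, rel=1e-12)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            promoter_response(-1.0, 0.1, Q)
        with pytest.raises(ValueError):
            promoter_response(1.0, -0.1, Q)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(A=st.floats(1e-3, 1e3), u=st.floats(1e-4, 10.0),
           dA=st.floats(1e-3, 10.0), du=st.floats(1e-4, 1.0))
    def test_strictly_increasing_in_both_ligands_and_below_one(self, A, u, dA, du):
        z = promoter_response(A, u, Q)
        assert 0.0 < z < 1.0
        assert promoter_response(A + dA, u, Q) > z
        assert promoter_response(A, u + du, Q) > z

    def test_vectorized_over_arrays(self):
        z = promoter_response(np.array([0.0, Q.K_A]), np.array([1.0, Q.K_u]), Q)
        np.testing.assert_allclose(z, [0.0, 0.25])


class TestRhsTa1415:
    def setup_method(self):
        from hisicc import ta1415_model
        self.p = ta1415_model().shared

    def test_quiescent_state_has_zero_derivatives(self):
        d = rhs_ta1415([0.0, 0.0, 0.3, 0.0, 1.0], 1.0, self.p)
        np.testing.assert_array_equal(d, np.zeros(5))

    def test_uninduced_dynamics_make_no_enzyme(self):
        state = [0.8, 0.05, 0.1, 0.0, 0.0]
        d = rhs_ta1415(state, 0.0, self.p)
        v2 = self.p.k2 * state[1] * (state[2] + state[3])
        assert d[3] == 0.0
        assert d[2] == pytest.approx(v2)

    def test_initial_state_derivative_matches_scalar_evaluation(self):
        # independent term-by-term values at the published initial state, u=0
        state = [1 - 0.0572 - 0.02, 0.0572, 0.02, 0.0, 0.0]
        d = rhs_ta1415(state, 0.0, self.p)
        np.testing.assert_allclose(
            d, [-0.033995804352, 0.032956022752, 0.0010397816, 0.0, 0.0],
            rtol=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(S=st.floats(0, 1), XA=st.floats(0, 0.5), XG=st.floats(0, 1),
           E=st.floats(0, 0.2), u=st.sampled_from([0.0, 1.0]))
    def test_biomass_pool_conserved(self, S, XA, XG, E, u):
        d = rhs_ta1415([S, XA, XG, E, 0.0], u, self.p)
        assert d[:4].sum() == pytest.approx(0.0, abs=1e-15)
        assert d[4] >= 0.0


class TestRhsTa2445:
    def setup_method(self):
        from hisicc import ta2445_model
        m = ta2445_model()
        self.p, self.q = m.shared, m.quorum

    def test_no_ahl_means_no_activation(self):
        d = rhs_ta2445([0.9, 0.05, 0.05, 0.0, 0.0, 0.0], 0.05, self.p, self.q)
        assert d[3] == 0.0   # dE
        assert d[5] == 0.0   # dA

    def test_no_iptg_means_no_activation(self):
        # z carries the IPTG Hill factor, so u = 0 forces z = 0
        d = rhs_ta2445([0.9, 0.05, 0.05, 0.0, 0.0, 10.0], 0.0, self.p, self.q)
        assert d[3] == 0.0
        assert d[5] == pytest.approx(-self.q.d_A * 10.0)

    def test_ahl_decays_first_order_without_biomass(self):
        d = rhs_ta2445([0.9, 0.1, 0.0, 0.0, 0.0, 2.0], 0.05, self.p, self.q)
        assert d[5] == pytest.approx(-self.q.d_A * 2.0)
        assert d[5] < 0

    def test_initial_state_derivative_matches_scalar_evaluation(self):
        # independent evaluation at the published initial state, u = 0.05 mM
        state = [1 - 0.024 - 0.005, 0.024, 0.005, 0.0, 0.0, 0.01]
        d = rhs_ta2445(state, 0.05, self.p, self.q)
        np.testing.assert_allclose(
            d, [-0.0127434746953573, 0.0126234746953573, 0.000119999754556158,
                2.45443841951788e-10, 0.0, -0.000458943244861544],
            rtol=1e-10, atol=1e-22)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(S=st.floats(0, 1), XA=st.floats(0, 0.5), XG=st.floats(0, 1),
           E=st.floats(0, 0.2), A=st.floats(0, 100), u=st.floats(0, 1))
    def test_biomass_pool_conserved(self, S, XA, XG, E, A, u):
        d = rhs_ta2445([S, XA, XG, E, 0.0, A], u, self.p, self.q)
        assert d[:4].sum() == pytest.approx(0.0, abs=1e-15)


class TestObserve:
    def test_od600_proportional_to_inactive_compartment(self, ta1415):
        y1, y2 = observe([0.9, 0.05, 0.02, 0.0, 3.5], ta1415.shared)
        assert y1 == pytest.approx(0.02 * 5.4651)
        assert y2 == 3.5

    def test_zero_biomass_zero_od(self, ta1415):
        y1, _ = observe([1.0, 0.0, 0.0, 0.0, 0.0], ta1415.shared)
        assert y1 == 0.0
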