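"""Unit and property tests for the model's right-hand side."""

import math

import pytest
from hypothesis import given, strategies as st

from landpop import (
    DomainError,
    ModelParameters,
    SystemState,
    agri_efficiency,
    derivatives,
    perception_u_A,
    perception_u_NA,
    perception_u_ND,
)

nonneg = st.floats(min_value=0.0, max_value=50.0, allow_nan=False)
unit = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)


@st.composite
def random_params(draw, base):
    return base.replace(
        p_N=draw(unit),
        p_A=draw(unit),
        eta_N=draw(st.floats(0.0, 3.0)),
        eta_A=draw(st.floats(0.0, 3.0)),
        d_N=draw(st.floats(0.0, 0.02)),
        c_ND=draw(st.floats(0.0, 0.005)),
        c_AN=draw(st.floats(0.0, 0.005)),
        E_A=draw(st.floats(0.0, 3.0)),
        phi=draw(st.floats(0.0, 2.0)),
    )


@st.composite
def random_states(draw, L=13.0):
    n = draw(st.floats(0.0, 1.0))
    a = draw(st.floats(0.0, 1.0))
    d = draw(st.floats(0.0, 1.0))
    total = n + a + d
    if total == 0.0:
        n, total = 1.0, 1.0
    scale = L / total
    return SystemState(N=n * scale, A=a * scale, D=d * scale,
                       H=draw(st.floats(0.0, 20.0)))


class TestPerception:
    def test_symmetric_full_perception_collapses_to_zero(self, params):
        p = params.replace(eta_N=1.0, eta_A=1.0, p_N=1.0, p_A=1.0)
        for N, A, H in [(1.0, 2.0, 3.0), (5.0, 5.0, 0.0), (0.0, 0.0, 7.0)]:
            assert perception_u_NA(N, A, H, p) == 0.0

    def test_u_NA_hand_value(self, params):
        p = params.replace(eta_N=2.0, eta_A=1.0, p_N=1.0, p_A=1.0, L=10.0, N_th=5.0)
        assert perception_u_NA(5.0, 5.0, 1.0, p) == pytest.approx(0.1)

    def test_u_NA_clamps_at_zero(self, params):
        p = params.replace(eta_N=0.0, eta_A=1.0, p_N=1.0, p_A=0.0, L=10.0, N_th=5.0)
        assert perception_u_NA(3.0, 0.5, 1.0, p) == 0.0

    def test_u_ND_full_perception_ignores_N(self, params):
        p = params.replace(p_N=1.0, eta_N=1.5)
        for N in (0.0, 4.0, 12.0):
            assert perception_u_ND(N, 2.0, p) == pytest.approx(1.5 * 2.0 / p.L)

    def test_u_ND_hand_value_clamped(self, params):
        p = params.replace(eta_N=1.0, p_N=0.5, L=10.0, N_th=5.0)
        assert perception_u_ND(10.0, 4.0, p) == 0.0

    def test_u_ND_zero_population(self, params):
        p = params.replace(p_N=0.5)
        assert perception_u_ND(3.0, 0.0, p) == 0.0

    def test_u_A_boundary_exact_balance(self, params):
        p = params.replace(eta_A=0.5, p_A=0.8)
        # eta_A * H == (1 - p_A) * A exactly
        assert perception_u_A(5.0, 2.0, p) == pytest.approx(0.0, abs=1e-12)

    def test_u_A_hand_value(self, params):
        p = params.replace(eta_A=0.5, p_A=0.8, L=13.0)
        assert perception_u_A(5.0, 10.0, p) == pytest.approx(4.0 / 13.0)

    def test_u_A_full_perception_ignores_A(self, params):
        p = params.replace(p_A=1.0, eta_A=0.9)
        for A in (0.0, 3.0, 11.0):
            assert perception_u_A(A, 2.0, p) == pytest.approx(0.9 * 2.0 / p.L)

    def test_negative_inputs_rejected(self, params):
        with pytest.raises(DomainError):
            perception_u_NA(-1.0, 1.0, 1.0, params)
        with pytest.raises(DomainError):
            perception_u_ND(1.0, -1.0, params)
        with pytest.raises(DomainError):
            perception_u_A(-0.1, 1.0, params)

    @given(data=st.data())
    def test_perception_never_negative(self, params, data):
        p = data.draw(random_params(params))
        s = data.draw(random_states())
        assert perception_u_NA(s.N, s.A, s.H, p) >= 0.0
        assert perception_u_ND(s.N, s.H, p) >= 0.0
        assert perception_u_A(s.A, s.H, p) >= 0.0

    @given(data=st.data())
    def test_zero_perception_weights_give_pure_supply_demand(self, params, data):
        """With p_N = p_A = 0 the values are plain demand-minus-supply imbalances."""
        p = data.draw(random_params(params)).replace(p_N=0.0, p_A=0.0)
        s = data.draw(random_states())
        expect = max(0.0, (p.eta_N * s.H - s.N - p.eta_A * s.H + s.A) / p.L)
        assert perception_u_NA(s.N, s.A, s.H, p) == pytest.approx(expect)
        assert perception_u_ND(s.N, s.H, p) == pytest.approx(
            max(0.0, (p.eta_N * s.H - s.N) / p.L))
        assert perception_u_A(s.A, s.H, p) == pytest.approx(
            max(0.0, (p.eta_A * s.H - s.A) / p.L))


class TestAgriEfficiency:
    def test_threshold_identity(self, params):
        assert agri_efficiency(params.N_th, params) == pytest.approx(params.E_A)

    def test_phi_zero_is_flat(self, params):
        p = params.replace(phi=0.0)
        for N in (0.0, 2.0, 10.0):
            assert agri_efficiency(N, p) == pytest.approx(p.E_A)

    def test_hand_value_clamped(self, params):
        p = params.replace(E_A=0.5, phi=0.2, N_th=5.0)
        assert agri_efficiency(0.0, p) == 0.0

    def test_exceeds_baseline_above_threshold_unless_capped(self, params):
        N = params.N_th + 1.0
        uncapped = agri_efficiency(N, params)
        assert uncapped == pytest.approx(params.E_A + params.phi)
        assert agri_efficiency(N, params, cap=True) == pytest.approx(params.E_A)

    @given(n1=st.floats(0.0, 13.0), n2=st.floats(0.0, 13.0))
    def test_non_decreasing_in_N(self, params, n1, n2):
        lo, hi = sorted((n1, n2))
        assert agri_efficiency(lo, params) <= agri_efficiency(hi, params) + 1e-15


class TestDerivatives:
    def test_human_free_limit(self, params):
        """With H = 0 and A = 0 only regeneration and disturbance remain."""
        s = SystemState(N=4.0, A=0.0, D=9.0, H=0.0)
        d = derivatives(s, params)
        assert d.dN == pytest.approx(params.r * 9.0 - params.delta_N * 4.0)
        assert d.dA == 0.0
        assert d.dH == 0.0

    @given(data=st.data())
    def test_conservation_exact(self, params, data):
        p = data.draw(random_params(params))
        s = data.draw(random_states())
        d = derivatives(s, p)
        assert d.dN + d.dA + d.dD == 0.0  # exact by construction

    @given(data=st.data())
    def test_zero_pools_never_driven_negative(self, params, data):
        """Every sink is proportional to its own pool."""
        p = data.draw(random_params(params))
        s = data.draw(random_states())
        zeroed = SystemState(N=0.0, A=s.A, D=s.D, H=s.H)
        assert derivatives(zeroed, p).dN >= 0.0
        zeroed = SystemState(N=s.N, A=0.0, D=s.D, H=s.H)
        assert derivatives(zeroed, p).dA >= 0.0
        zeroed = SystemState(N=s.N, A=s.A, D=0.0, H=s.H)
        assert derivatives(zeroed, p).dD >= 0.0
        zeroed = SystemState(N=s.N, A=s.A, D=s.D, H=0.0)
        assert derivatives(zeroed, p).dH == 0.0

    def test_term_by_term_hand_evaluation(self, params):
        """Full numeric cross-check of every flux term, written out independently."""
        p = params.replace(
            r=0.002, delta_N=0.003, delta_A=0.004, d_N=0.001, d_A=0.002,
            c_NA=0.01, c_ND=0.02, c_AN=0.03, c_AD=0.04,
            p_N=0.3, p_A=0.6, eta_N=1.1, eta_A=0.8,
            b=0.05, beta=0.4, m=0.02, q=0.15, q_N=1.5, q_A=2.5,
            E_N=0.6, E_A=1.3, phi=0.25, N_th=5.0, L=13.0,
        )
        N, A, D, H = 6.0, 2.0, 5.0, 4.0

        u_na = max(0.0, (1.1 * 4 - 0.7 * 6 - 0.8 * 4 + 0.4 * 2) / 13.0)
        u_nd = max(0.0, (1.1 * 4 - 0.7 * 6) / 13.0)
        u_a = max(0.0, (0.8 * 4 - 0.4 * 2) / 13.0)
        dN = (0.002 * 5 + 0.01 * u_na * 4 * 2 + 0.02 * u_nd * 4 * 5
              - 0.03 * u_a * 6 * 4 - 0.001 * 4 * 6 - 0.003 * 6)
        dA = (0.03 * u_a * 6 * 4 + 0.04 * u_a * 4 * 5 - 0.01 * u_na * 4 * 2
              - 0.002 * math.exp(-6 / 5.0) * 4 * 2 - 0.004 * 2)
        eps = max(0.0, 1.3 - 0.25 * (5.0 - 6.0))
        dH = (0.05 * math.exp(-0.4 * 1.1) * (1 - math.exp(-1.5 * 6 - 2.5 * 2))
              - 0.02 * math.exp(0.15 * (1.1 * 4 - 0.6 * 6 + 0.8 * 4 - eps * 2))) * 4

        d = derivatives(SystemState(N=N, A=A, D=D, H=H), p)
        assert d.dN == pytest.approx(dN, rel=1e-12)
        assert d.dA == pytest.approx(dA, rel=1e-12)
        assert d.dD == pytest.approx(-(dN + dA), rel=1e-12)
        assert d.dH == pytest.approx(dH, rel=1e-12)

    def test_negative_state_rejected(self, params):
        with pytest.raises(DomainError):
            derivatives(SystemState(N=-1.0, A=1.0, D=1.0, H=1.0), params)


class TestParameterValidation:
    def test_perception_weight_range_enforced(self, params):
        with pytest.raises(DomainError, match="p_A"):
            params.replace(p_A=1.5)

    def test_negative_rate_rejected(self, params):
        with pytest.raises(DomainError, match="d_N"):
            params.replace(d_N=-0.1)

    def test_threshold_must_be_inside_land_area(self, params):
        with pytest.raises(DomainError, match="N_th"):
            params.replace(N_th=params.L + 1.0)

    def test_unknown_name_rejected(self, params):
        with pytest.raises(KeyError):
            params.replace(nonexistent=1.0)

    def test_round_trip_dict(self, params):
        assert ModelParameters.from_dict(params.as_dict()) == params
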