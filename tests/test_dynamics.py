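import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dormancy._kernel import VARIANT_CODES, _rhs, pack_parameters
from dormancy.dynamics import (
    SystemState,
    gompertz_term,
    mixed_parameters,
    rhs_heterogeneous,
    rhs_proliferative,
    rhs_quiescent,
)
from dormancy.errors import DomainError
from dormancy.parameters import ParameterSet


def state(Cp=0.0, Cq=0.0, N=0.0, T=0.0, t=0.0):
    return SystemState(t=t, Cp=Cp, Cq=Cq, N=N, T=T)


class TestGompertz:
    def test_vanishes_at_capacity(self):
        assert gompertz_term(0.038, 1e9, 1e9, 1e9) == 0.0

    def test_vanishes_for_empty_tumor(self):
        assert gompertz_term(0.038, 0.0, 0.0, 1e9) == 0.0

    def test_closed_form_value(self):
        # independent closed-form evaluation: 0.038 * 5e4 * ln(1e9 / 5e4)
        expected = 0.038 * 5e4 * math.log(1e9 / 5e4)  # = 18816.626...
        got = gompertz_term(0.038, 5e4, 5e4, 1e9)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(1.8817e4, rel=1e-4)

    def test_beyond_capacity_is_domain_error(self):
        with pytest.raises(DomainError):
            gompertz_term(0.038, 2e9, 2e9, 1e9)

    def test_compartment_exceeding_total_is_domain_error(self):
        with pytest.raises(DomainError):
            gompertz_term(0.038, 2.0, 1.0, 1e9)


class TestMixedParameters:
    def test_collapses_to_proliferative_when_quiescent_absent(self, params):
        mixed = mixed_parameters(1e4, 0.0, params)
        assert mixed == (params.a1, params.b1, params.eta1, params.r1, params.u1)

    def test_equal_populations_give_arithmetic_mean(self, params):
        mixed = mixed_parameters(2.5e4, 2.5e4, params)
        assert mixed.a1h == pytest.approx((0.038 + 0.0174) / 2, rel=1e-12)
        assert mixed.a1h == pytest.approx(0.0277, rel=1e-12)

    def test_weighted_mean_value(self, params):
        # direct evaluation: (0.038*1e3 + 0.0174*4.9e4) / 5e4
        mixed = mixed_parameters(1e3, 4.9e4, params)
        assert mixed.a1h == pytest.approx(890.6 / 5e4, rel=1e-12)
        assert mixed.a1h == pytest.approx(0.017812, rel=1e-6)

    def test_extinct_tumor_is_degenerate(self, params):
        with pytest.raises(DomainError):
            mixed_parameters(0.0, 0.0, params)

    @given(
        Cp=st.floats(min_value=1e-3, max_value=1e9),
        Cq=st.floats(min_value=1e-3, max_value=1e9),
    )
    def test_mixed_values_are_convex_combinations(self, Cp, Cq):
        params = ParameterSet()
        mixed = mixed_parameters(Cp, Cq, params)
        for value, one, two in [
            (mixed.a1h, params.a1, params.a2),
            (mixed.b1h, params.b1, params.b2),
            (mixed.eta1h, params.eta1, params.eta2),
            (mixed.r1h, params.r1, params.r2),
            (mixed.u1h, params.u1, params.u2),
        ]:
            lo, hi = min(one, two), max(one, two)
            assert lo - 1e-15 <= value <= hi + 1e-15


class TestSinglePopulationRhs:
    def test_tumor_free_nk_equilibrium(self, params):
        # dN/dt = 0 at N = s / f (~3.1553e5 cells) with no tumor, no CTL
        eq = params.s / params.f
        assert eq == pytest.approx(3.1553e5, rel=1e-4)
        for rhs in (rhs_proliferative, rhs_quiescent):
            deriv = rhs(state(N=eq), params)
            assert np.all(deriv == 0.0)

    def test_empty_system_sources_nk_only(self, params):
        deriv = rhs_proliferative(state(), params)
        assert deriv[2] == params.s == 1.3e4
        assert deriv[0] == deriv[1] == deriv[3] == 0.0

    def test_proliferative_inoculum_derivative(self, params):
        # term-by-term oracle: growth - NK kill - CTL kill
        growth = 0.038 * 5e4 * math.log(1e9 / 5e4)
        nk_kill = 1.56e-8 * 2.5e5 * 5e4  # = 195
        t_kill = 2.1e-8 * 5.2e5 * 5e4  # = 546
        deriv = rhs_proliferative(state(Cp=5e4, N=2.5e5, T=5.2e5), params)
        assert deriv[0] == pytest.approx(growth - nk_kill - t_kill, rel=1e-12)
        assert deriv[0] == pytest.approx(1.80756e4, rel=1e-4)

    def test_quiescent_inoculum_derivative(self, params):
        growth = 0.0174 * 5e4 * math.log(1e9 / 5e4)  # ~8616
        nk_kill = 5.2e-8 * 2.5e5 * 5e4  # = 650
        t_kill = 2.8e-7 * 5.2e5 * 5e4  # = 7280
        deriv = rhs_quiescent(state(Cq=5e4, N=2.5e5, T=5.2e5), params)
        assert deriv[1] == pytest.approx(growth - nk_kill - t_kill, rel=1e-12)
        assert deriv[1] == pytest.approx(686, rel=2e-3)

    def test_growth_nonpositive_at_capacity(self, params):
        deriv = rhs_quiescent(state(Cq=1e9, N=1e3, T=1e3), params)
        assert deriv[1] <= 0.0

    def test_wrong_compartment_rejected(self, params):
        with pytest.raises(DomainError):
            rhs_proliferative(state(Cp=1.0, Cq=1.0), params)
        with pytest.raises(DomainError):
            rhs_quiescent(state(Cp=1.0, Cq=1.0), params)

    def test_negative_state_rejected(self, params):
        with pytest.raises(DomainError):
            rhs_proliferative(state(Cp=-1.0), params)


class TestHeterogeneousRhs:
    @pytest.mark.parametrize("tumor", [(0.0, 3.2e4), (3.2e4, 0.0)])
    def test_collapses_to_single_population_model(self, params, tumor):
        Cp, Cq = tumor
        s = state(Cp=Cp, Cq=Cq, N=2.1e5, T=4.4e5)
        single = rhs_quiescent if Cp == 0.0 else rhs_proliferative
        np.testing.assert_array_equal(
            rhs_heterogeneous(s, params), single(s, params)
        )

    def test_quiescent_compartment_uses_total_burden(self, params):
        # oracle: a2*Cq*ln(Cmax/(Cp+Cq)) - b2*N*Cq - eta2*T*Cq  (~672)
        expected = (
            0.0174 * 4.9e4 * math.log(1e9 / 5e4)
            - 5.2e-8 * 2.5e5 * 4.9e4
            - 2.8e-7 * 5.2e5 * 4.9e4
        )
        deriv = rhs_heterogeneous(
            state(Cp=1e3, Cq=4.9e4, N=2.5e5, T=5.2e5), params
        )
        assert deriv[1] == pytest.approx(expected, rel=1e-12)
        assert deriv[1] == pytest.approx(672, rel=2e-3)

    def test_extinct_tumor_skips_mixing(self, params):
        deriv = rhs_heterogeneous(state(N=1e5, T=1e5), params)
        assert deriv[0] == deriv[1] == 0.0
        assert deriv[2] == params.s - params.f * 1e5
        assert deriv[3] == -params.m * 1e5

    def test_derivatives_vanish_for_empty_populations(self, params):
        """The flow cannot push a population below zero: tumor derivatives
        are exactly zero at zero and dN/dt >= s > 0."""
        deriv = rhs_heterogeneous(state(Cq=1e3, N=0.0, T=0.0), params)
        assert deriv[0] == 0.0
        assert deriv[2] >= params.s > 0.0
        assert deriv[3] >= 0.0


def test_recruitment_saturation_monotone_bounded(params):
    C = np.logspace(0, 10, 200)
    factor = C**2 / (params.h + C**2)
    assert np.all(np.diff(factor) > 0)
    assert factor[0] >= 0.0 and factor[-1] < 1.0


@pytest.mark.parametrize("variant", ["proliferative", "quiescent", "heterogeneous"])
@pytest.mark.parametrize(
    "populations",
    [
        (0.0, 5e4, 2.5e5, 5.2e5),
        (5e4, 0.0, 2.5e5, 5.2e5),
        (1e3, 4.9e4, 3.1e5, 1.9e6),
        (0.0, 0.0, 1e5, 1e5),
        (2.5e8, 1e2, 7e5, 3e6),
    ],
)
def test_kernel_matches_pure_rhs(params, variant, populations):
    """The JIT-compiled integrator kernel and the reference right-hand
    sides are the same function."""
    Cp, Cq, N, T = populations
    if variant == "proliferative" and Cq != 0.0:
        Cq = 0.0
    if variant == "quiescent" and Cp != 0.0:
        Cp = 0.0
    from dormancy.dynamics import rhs as dispatch

    expected = dispatch(variant, state(Cp=Cp, Cq=Cq, N=N, T=T), params)
    got = _rhs(Cp, Cq, N, T, pack_parameters(params), VARIANT_CODES[variant])
    np.testing.assert_allclose(np.array(got), expected, rtol=1e-14, atol=0.0)
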