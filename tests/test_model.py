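"""Vector fields, birth pulses, mixtures and impulse maps."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from impulsepm import (
    BirthPulse,
    PulseMixture,
    SystemParams,
    SystemState,
    birth_pesticide_impulse,
    evaluate_pulse,
    mixture_births,
    predator_release_impulse,
    system1_field,
)
from impulsepm.model import ModelDomainError


def make_params(**kw):
    base = dict(
        b1=1.0, b2=0.8, alpha=0.2, beta=0.3, r1=1.2, r2=1.0,
        b3=0.6, d=0.3, p=0.5, T=1.0,
    )
    base.update(kw)
    return SystemParams(**base)


class TestSystem1Field:
    def test_origin_is_equilibrium(self):
        assert np.allclose(system1_field((0, 0, 0), make_params()), 0)

    def test_pest_free_subsystem_is_predator_decay(self):
        params = make_params(b3=0.7)
        d = system1_field((0, 0, 3.0), params)
        assert d[0] == 0 and d[1] == 0
        assert d[2] == pytest.approx(-0.7 * 3.0)

    def test_interior_equilibrium_annihilates_field(self):
        # brute-force the coexistence point from the per-capita balance
        # (a linear 3x3 system in standard mode), then evaluate the field
        params = make_params(
            b1=1.5, b2=1.55, alpha=0.4, beta=0.3, r1=0.6, r2=0.8, b3=0.5, d=0.5
        )
        A = np.array(
            [
                [1.0, params.alpha, params.r1],
                [1.0, params.beta, params.r2],
                [params.d * params.r1, params.d * params.r2, 0.0],
            ]
        )
        rhs = np.array([params.b1, params.b2, params.b3])
        eq = np.linalg.solve(A, rhs)
        assert (eq > 0).all(), "fixture parameters must give a coexistence point"
        assert np.allclose(system1_field(eq, params), 0, atol=1e-12)

    def test_as_printed_modes_change_terms(self):
        state = (0.5, 0.7, 0.9)
        std = make_params()
        printed = make_params(
            conversion_sign_mode="as_printed", x2_growth_mode="as_printed"
        )
        d_std = system1_field(state, std)
        d_pr = system1_field(state, printed)
        # x2 equation: leading factor x1 instead of x2
        per_capita = std.b2 - state[0] - std.beta * state[1] - std.r2 * state[2]
        assert d_std[1] == pytest.approx(state[1] * per_capita)
        assert d_pr[1] == pytest.approx(state[0] * per_capita)
        # predator equation: first conversion term flips sign
        flip = 2 * std.d * std.r1 * state[0] * state[2]
        assert d_std[2] - d_pr[2] == pytest.approx(flip)

    def test_nonfinite_state_rejected(self):
        with pytest.raises(ModelDomainError):
            system1_field((np.nan, 0, 0), make_params())

    @given(
        x1=st.floats(0, 5), x2=st.floats(0, 5), y=st.floats(0, 5),
    )
    def test_zero_components_never_pushed_negative(self, x1, x2, y):
        # each derivative carries its own component as a factor (standard mode)
        d = system1_field((0.0, x2, y), make_params())
        assert d[0] == 0.0
        d = system1_field((x1, 0.0, y), make_params())
        assert d[1] == 0.0
        d = system1_field((x1, x2, 0.0), make_params())
        assert d[2] == 0.0


class TestPredatorRelease:
    @pytest.mark.parametrize(
        "state,p,expected",
        [
            ((1, 2, 3), 0.0, (1, 2, 3)),
            ((0, 0, 0), 5.0, (0, 0, 5)),
            ((1, 1, 2), 0.5, (1, 1, 2.5)),
        ],
    )
    def test_additive_map(self, state, p, expected):
        assert predator_release_impulse(state, p) == SystemState(*expected)

    def test_negative_release_rejected(self):
        with pytest.raises(ModelDomainError):
            predator_release_impulse((1, 1, 1), -0.1)


class TestBirthPulse:
    def test_beverton_holt_value(self):
        assert evaluate_pulse(BirthPulse("beverton_holt", 2.0, 1.0), 0.0, 1.0) == 1.0

    def test_no_mature_prey_no_births(self):
        for pulse in (BirthPulse("beverton_holt", 3.0, 2.0), BirthPulse("ricker", 3.0)):
            assert evaluate_pulse(pulse, 1.5, 0.0) == 0.0

    def test_beverton_holt_saturates_at_b(self):
        pulse = BirthPulse("beverton_holt", 2.0, 1.0)
        assert evaluate_pulse(pulse, 0.3, 1e12) == pytest.approx(2.0, rel=1e-9)

    def test_ricker_formula(self):
        pulse = BirthPulse("ricker", 1.7)
        assert evaluate_pulse(pulse, 0.4, 0.9) == pytest.approx(
            1.7 * 0.9 * math.exp(-1.3)
        )

    def test_negative_density_rejected(self):
        with pytest.raises(ModelDomainError):
            evaluate_pulse(BirthPulse("ricker", 1.0), -0.1, 1.0)

    def test_invalid_construction(self):
        with pytest.raises(ModelDomainError):
            BirthPulse("beverton_holt", 1.0)  # missing q
        with pytest.raises(ModelDomainError):
            BirthPulse("logistic", 1.0, 1.0)


class TestMixture:
    B1 = BirthPulse("beverton_holt", 2.0, 0.5)
    B2 = BirthPulse("beverton_holt", 3.0, 4.0)

    def test_degenerate_mixture_is_single_pulse(self):
        mix = PulseMixture.single(self.B1)
        assert mixture_births(mix, 0.3, 0.8) == evaluate_pulse(self.B1, 0.3, 0.8)

    def test_convexity_identity(self):
        mix = PulseMixture(((0.5, self.B1), (0.5, self.B1)))
        assert mixture_births(mix, 0.2, 0.9) == pytest.approx(
            evaluate_pulse(self.B1, 0.2, 0.9), abs=1e-15
        )

    def test_weighted_sum_matches_componentwise(self):
        mix = PulseMixture(((0.25, self.B1), (0.75, self.B2)))
        expected = 0.25 * evaluate_pulse(self.B1, 0.4, 1.1) + 0.75 * evaluate_pulse(
            self.B2, 0.4, 1.1
        )
        assert mixture_births(mix, 0.4, 1.1) == pytest.approx(expected, abs=1e-15)

    def test_weight_sum_invariant(self):
        with pytest.raises(ModelDomainError, match="sum to 1"):
            PulseMixture(((0.6, self.B1), (0.5, self.B2)))

    @given(
        pi=st.floats(0, 1),
        x1=st.floats(0, 10),
        x2=st.floats(0, 10),
    )
    def test_mixture_between_component_extremes(self, pi, x1, x2):
        mix = PulseMixture.two_component(pi, self.B1, self.B2)
        v1 = evaluate_pulse(self.B1, x1, x2)
        v2 = evaluate_pulse(self.B2, x1, x2)
        m = mixture_births(mix, x1, x2)
        assert min(v1, v2) - 1e-12 <= m <= max(v1, v2) + 1e-12

    @given(scale=st.floats(1.0, 3.0))
    def test_monotone_in_magnitude(self, scale):
        bigger = BirthPulse("beverton_holt", self.B1.b * scale, self.B1.q)
        mix_small = PulseMixture.two_component(0.5, self.B1, self.B2)
        mix_big = PulseMixture.two_component(0.5, bigger, self.B2)
        assert mixture_births(mix_big, 0.3, 1.2) >= mixture_births(
            mix_small, 0.3, 1.2
        )


class TestBirthPesticideImpulse:
    B1 = BirthPulse("beverton_holt", 3.0, 1.0)

    def test_total_kill_empties_immature_class(self):
        mix = PulseMixture.single(self.B1)
        out = birth_pesticide_impulse((2.0, 1.5, 0.7), mix, 1.0)
        assert out.x1 == 0.0 and out.x2 == 1.5 and out.y == 0.7

    def test_identity_without_births_or_kill(self):
        mix = PulseMixture.single(BirthPulse("beverton_holt", 0.0, 1.0))
        out = birth_pesticide_impulse((1.0, 2.0, 3.0), mix, 0.0)
        assert out == SystemState(1.0, 2.0, 3.0)

    def test_direct_substitution(self):
        mix = PulseMixture.single(self.B1)
        out = birth_pesticide_impulse((1.0, 2.0, 0.0), mix, 0.5)
        assert out.x1 == pytest.approx((1.0 + 3.0 * 2.0 / (1.0 + 1.0 + 2.0)) * 0.5)

    def test_efficacy_domain(self):
        with pytest.raises(ModelDomainError):
            birth_pesticide_impulse((1, 1, 1), None, 1.5)

    def test_optional_action_on_mature_and_predator(self):
        out = birth_pesticide_impulse(
            (1.0, 2.0, 3.0), None, 0.25, kill_mature=True, kill_predator=True
        )
        assert out == SystemState(0.75, 1.5, 2.25)

    @given(e1=st.floats(0, 1), e2=st.floats(0, 1))
    def test_immature_outcome_non_increasing_in_efficacy(self, e1, e2):
        lo, hi = sorted((e1, e2))
        mix = PulseMixture.single(self.B1)
        out_lo = birth_pesticide_impulse((0.8, 1.4, 0.2), mix, lo)
        out_hi = birth_pesticide_impulse((0.8, 1.4, 0.2), mix, hi)
        assert out_hi.x1 <= out_lo.x1 + 1e-15
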