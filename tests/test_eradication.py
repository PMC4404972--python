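"""Pest-free orbit, invasion thresholds and critical efficacy."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy.integrate import quad

from impulsepm import (
    BirthPulse,
    EradicationScenario,
    ImpulseEvent,
    ImpulseSchedule,
    PulseMixture,
    StagePreyParams,
    SystemParams,
    SystemState,
    assess_eradication,
    critical_efficacy,
    critical_release,
    invasion_exponent,
    period_average_predator,
    pest_free_orbit,
    prey_eradicated,
    simulate,
)
from impulsepm.eradication import (
    NoFiniteCriticalRelease,
    NonMonotoneEfficacyError,
)
from impulsepm.integrate import Trajectory
from impulsepm.model import ModelDomainError


def decay_params(b3, p, T):
    return SystemParams(
        b1=0, b2=0, alpha=0, beta=0, r1=0, r2=0, b3=b3, d=0, p=p, T=T
    )


RELEASE_1 = ImpulseSchedule(1.0, (ImpulseEvent("predator_release"),))


class TestPestFreeOrbit:
    def test_geometric_half_decay(self):
        assert pest_free_orbit(math.log(2.0), 1.0, 1.0, 0.0) == pytest.approx(2.0)

    def test_no_release_no_orbit(self):
        t = np.linspace(0, 1, 7)
        assert np.all(pest_free_orbit(1.3, 0.0, 1.0, t) == 0.0)

    def test_long_run_simulation_converges_to_formula(self):
        b3, p, T = 0.9, 2.4, 0.8
        sched = ImpulseSchedule(T, (ImpulseEvent("predator_release"),))
        traj = simulate(
            decay_params(b3, p, T), sched, SystemState(0, 0, 7.0), 200,
            rtol=1e-12, atol=1e-12, method="DOP853",
        )
        tail = simulate(
            decay_params(b3, p, T), sched, traj.final_state, 1,
            rtol=1e-12, atol=1e-12, method="DOP853", samples_per_period=40,
        )
        errs = [
            abs(s[2] - pest_free_orbit(b3, p, T, t))
            for t, s, side in zip(tail.times, tail.states, tail.limit_side)
            if t < T
        ]
        assert max(errs) < 1e-8

    def test_domain_errors(self):
        with pytest.raises(ModelDomainError):
            pest_free_orbit(0.0, 1.0, 1.0, 0.0)
        with pytest.raises(ModelDomainError):
            pest_free_orbit(1.0, 1.0, 1.0, 2.0)


class TestPeriodAverage:
    def test_quadrature_identity(self):
        b3, p, T = 1.0, 1.0, 2.7
        integral, _ = quad(
            lambda t: pest_free_orbit(b3, p, T, t), 0, T,
            epsabs=1e-13, epsrel=1e-13,
        )
        assert integral == pytest.approx(p / b3, abs=1e-10)
        assert period_average_predator(b3, p, T) == pytest.approx(
            integral / T, abs=1e-10
        )

    def test_zero_release(self):
        assert period_average_predator(2.0, 0.0, 1.0) == 0.0

    def test_linear_in_release(self):
        assert period_average_predator(0.7, 4.0, 1.3) == pytest.approx(
            2 * period_average_predator(0.7, 2.0, 1.3)
        )


class TestInvasionExponent:
    def params(self, **kw):
        base = dict(
            b1=1.0, b2=0.8, alpha=0.2, beta=0.3, r1=1.2, r2=1.0,
            b3=0.6, d=0.3, p=0.5, T=1.0,
        )
        base.update(kw)
        return SystemParams(**base)

    def test_no_release_gives_pure_growth(self):
        p = self.params(p=0.0)
        assert invasion_exponent(1, p) == pytest.approx(p.b1 * p.T)
        assert invasion_exponent(2, p) == pytest.approx(p.b2 * p.T)

    def test_boundary_release_zeroes_exponent(self):
        base = self.params()
        p_star = base.b1 * base.b3 * base.T / base.r1
        assert invasion_exponent(1, self.params(p=p_star)) == pytest.approx(0.0)

    def test_critical_release_formula(self):
        p = self.params(b1=1.0, b3=1.0, T=1.0, r1=2.0, b2=0.0, r2=1.0)
        assert critical_release(p, prey=(1,)) == pytest.approx(0.5)

    def test_symmetric_prey_equal_thresholds(self):
        p = self.params(b1=0.9, b2=0.9, r1=1.1, r2=1.1)
        assert critical_release(p, prey=(1,)) == critical_release(p, prey=(2,))

    def test_unpredated_growing_prey_has_no_threshold(self):
        with pytest.raises(NoFiniteCriticalRelease):
            critical_release(self.params(r1=0.0))


def synthetic_trajectory(prey_values, period=1.0):
    """Trajectory stub with one sample per period (x2 = y = 0)."""
    n = len(prey_values)
    times = np.arange(n, dtype=float) * period
    states = np.column_stack(
        [np.asarray(prey_values, dtype=float), np.zeros(n), np.zeros(n)]
    )
    return Trajectory(
        times=times,
        states=states,
        event_kind=["none"] * n,
        limit_side=[""] * n,
        events=[],
        period=period,
        n_periods=n,
    )


class TestAssessEradication:
    def test_zero_prey_is_eradicated(self):
        traj = synthetic_trajectory([0.0] * 30)
        assert assess_eradication(traj, 1e-6, 10).eradicated

    def test_constant_prey_above_epsilon_is_not(self):
        traj = synthetic_trajectory([2e-6] * 30)
        out = assess_eradication(traj, 1e-6, 10)
        assert not out.eradicated
        assert out.terminal_prey_max == pytest.approx(2e-6)

    def test_decaying_prey_flips_with_horizon(self):
        decay = [math.exp(-t) for t in range(40)]
        assert not assess_eradication(synthetic_trajectory(decay[:15]), 1e-6, 5).eradicated
        assert assess_eradication(synthetic_trajectory(decay), 1e-6, 5).eradicated

    def test_short_trajectory_rejected(self):
        with pytest.raises(ValueError):
            assess_eradication(synthetic_trajectory([0.0] * 5), 1e-6, 10)


def stage_scenario(**kw):
    params = StagePreyParams(
        death_immature=0.2, maturation=0.8, death_mature=0.25,
        r1=0.4, r2=0.6, b3=0.5, d=0.3, E=0.0, T=1.0, p=0.3,
    )
    mixture = PulseMixture.two_component(
        0.5,
        BirthPulse("beverton_holt", 2.0, 0.5),
        BirthPulse("beverton_holt", 2.0, 5.0),
    )
    sched = ImpulseSchedule(
        1.0,
        (ImpulseEvent("birth_pesticide"), ImpulseEvent("predator_release")),
    )
    base = dict(
        params=params, schedule=sched, state0=SystemState(0.5, 0.5, 1.0),
        mixture=mixture, horizon=80, window=10, epsilon=1e-6,
        rtol=1e-6, atol=1e-9,
    )
    base.update(kw)
    return EradicationScenario(**base)


class TestCriticalEfficacy:
    def test_no_births_no_pesticide_needed(self):
        sc = stage_scenario(
            mixture=PulseMixture.single(BirthPulse("beverton_holt", 0.0, 1.0))
        )
        res = critical_efficacy(sc)
        assert res.E_star == 0.0 and res.converged

    def test_saturation_when_horizon_cannot_confirm(self):
        # nearly immortal mature prey: even total kill of the immature
        # class cannot push total prey below epsilon within the horizon
        params = StagePreyParams(
            death_immature=1e-4, maturation=1e-4, death_mature=1e-4,
            r1=0.0, r2=0.0, b3=0.5, d=0.0, E=0.0, T=1.0, p=0.0,
        )
        sc = stage_scenario(params=params, horizon=12, window=10)
        res = critical_efficacy(sc)
        assert res.E_star == 1.0 and not res.converged

    def test_bisection_matches_grid_search(self):
        sc = stage_scenario()
        res = critical_efficacy(sc, tol=1e-3)
        # exhaustive ascending scan at the same resolution
        grid = np.arange(0.0, 1.0 + 1e-12, 1e-3)
        e_grid = next(E for E in grid if prey_eradicated(sc, float(E)))
        assert res.converged
        assert abs(res.E_star - e_grid) <= 1e-3 + 1e-12

    def test_monotone_in_release(self):
        sc_lo = stage_scenario()
        sc_hi = stage_scenario(
            params=replace(sc_lo.params, p=0.6)
        )
        assert (
            critical_efficacy(sc_hi).E_star
            <= critical_efficacy(sc_lo).E_star + 1e-3
        )

    def test_non_monotone_scenario_aborts_loudly(self):
        # pesticide that only harms the predator, with the pest living in
        # the mature class (untouched by spraying): E=0 lets the released
        # predator eradicate the pest, E=1 culls the predator every period
        # and the pest persists
        params = SystemParams(
            b1=0.0, b2=1.0, alpha=0.0, beta=0.0, r1=0.0, r2=1.2,
            b3=0.6, d=0.0, p=0.9, T=1.0,
        )
        sched = ImpulseSchedule(
            1.0,
            (ImpulseEvent("birth_pesticide"), ImpulseEvent("predator_release")),
        )
        sc = EradicationScenario(
            params=params, schedule=sched, state0=SystemState(0.0, 0.1, 1.5),
            mixture=None, horizon=200, window=15, epsilon=1e-6,
            rtol=1e-8, atol=1e-10, kill_predator=True,
        )
        with pytest.raises(NonMonotoneEfficacyError):
            critical_efficacy(sc)


class TestFastPathAgreement:
    def test_fast_and_reference_indicator_agree(self):
        sc = stage_scenario()
        for E in np.linspace(0.0, 1.0, 9):
            assert prey_eradicated(sc, float(E), fast=True) == prey_eradicated(
                sc, float(E), fast=False
            )

    def test_indicator_matches_full_simulation_assessment(self):
        sc = stage_scenario()
        for E in (0.2, 0.9):  # far from the threshold on both sides
            traj = simulate(
                sc.params, sc.schedule, sc.state0, sc.horizon,
                mixture=sc.mixture, efficacy=E, rtol=sc.rtol, atol=sc.atol,
                samples_per_period=4,
            )
            assessed = assess_eradication(traj, sc.epsilon, sc.window).eradicated
            assert prey_eradicated(sc, E) == assessed
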