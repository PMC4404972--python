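"""Pest-eradication analysis: the pest-free orbit, invasion exponents,
critical predator release, and the critical pesticide efficacy E*.

With prey absent, the predator obeys ``y' = -b3 y`` between releases and
jumps by ``p`` at each release, so it settles onto the unique attracting
T-periodic orbit

.. math:: y^*(t) = \\frac{p\\, e^{-b_3 t}}{1 - e^{-b_3 T}},
          \\qquad 0 \\le t < T,

with ``t`` measured from just after a release. Linearizing a prey equation
about this orbit gives the per-period invasion exponent

.. math:: \\lambda_i = b_i T - r_i \\, p / b_3,

(the integral over one period of the linearized per-capita growth
``b_i - r_i y^*(t)``); prey ``i`` dies out along the pest-free solution
when :math:`\\lambda_i < 0`, which yields the critical release
``p_c = max_i b_i b_3 T / r_i``.

Eradication itself — the pest eventually dying out — is operationalized
numerically: a scenario is "eradicated" when the maximum total prey
density over the final assessment window of periods falls below a small
threshold epsilon. The critical efficacy E* is found by bisection in E,
assuming (and spot-checking) that the eradication indicator is monotone
in E.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .integrate import (
    ImpulseSchedule,
    IntegrationError,
    Trajectory,
    integrate_segment,
    simulate,
)
from .model import (
    ModelDomainError,
    PulseMixture,
    StagePreyParams,
    SystemParams,
    SystemState,
    make_field,
)

__all__ = [
    "EradicationAssessment",
    "EfficacyResult",
    "EradicationScenario",
    "NoFiniteCriticalRelease",
    "NonMonotoneEfficacyError",
    "pest_free_orbit",
    "period_average_predator",
    "invasion_exponent",
    "critical_release",
    "assess_eradication",
    "prey_eradicated",
    "critical_efficacy",
]

DEFAULT_EPSILON = 1e-6
DEFAULT_WINDOW = 50
DEFAULT_HORIZON = 500
DEFAULT_E_TOL = 1e-3

#: per-period prey maximum beyond which a run is declared non-eradicating
ESCAPE_FACTOR = 1e4


class NoFiniteCriticalRelease(ValueError):
    """A prey species grows (b_i > 0) but is never predated (r_i = 0)."""


class NonMonotoneEfficacyError(RuntimeError):
    """Eradication holds at E=0 but fails at E=1: bisection is invalid."""


# ---------------------------------------------------------------------------
# pest-free subsystem, closed forms
# ---------------------------------------------------------------------------

def pest_free_orbit(b3: float, p: float, T: float, t) -> np.ndarray | float:
    """Predator density along the pest-free periodic orbit at phase ``t``.

    ``t`` (scalar or array) is measured from just after a release and must
    lie in ``[0, T]``.
    """
    if b3 <= 0:
        raise ModelDomainError(f"b3 must be > 0 for a periodic orbit, got {b3!r}")
    if T <= 0 or p < 0:
        raise ModelDomainError(f"need T > 0 and p >= 0, got T={T!r}, p={p!r}")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or np.any(t > T):
        raise ModelDomainError("phase t must lie in [0, T]")
    out = p * np.exp(-b3 * t) / (1.0 - np.exp(-b3 * T))
    return float(out) if out.ndim == 0 else out


def period_average_predator(b3: float, p: float, T: float) -> float:
    """Mean of the pest-free orbit over one period: p / (b3 * T).

    (The integral of ``y*`` over a full period is exactly ``p / b3``.)
    """
    if b3 <= 0:
        raise ModelDomainError(f"b3 must be > 0, got {b3!r}")
    if T <= 0 or p < 0:
        raise ModelDomainError(f"need T > 0 and p >= 0, got T={T!r}, p={p!r}")
    return p / (b3 * T)


def invasion_exponent(i: int, params: SystemParams) -> float:
    """Per-period growth exponent of prey ``i`` (1 or 2) along the
    pest-free orbit: ``b_i*T - r_i*p/b3``. Negative means the prey cannot
    invade (local extinction)."""
    if i not in (1, 2):
        raise ValueError(f"prey index must be 1 or 2, got {i!r}")
    if params.b3 <= 0:
        raise ModelDomainError("b3 must be > 0 for a pest-free orbit")
    b = params.b1 if i == 1 else params.b2
    r = params.r1 if i == 1 else params.r2
    return b * params.T - r * params.p / params.b3


def critical_release(
    params: SystemParams, prey: Sequence[int] = (1, 2)
) -> float:
    """Smallest release amount p making every considered prey's invasion
    exponent non-positive: ``max_i b_i*b3*T/r_i``."""
    if params.b3 <= 0:
        raise ModelDomainError("b3 must be > 0 for a pest-free orbit")
    thresholds = []
    for i in prey:
        b = params.b1 if i == 1 else params.b2
        r = params.r1 if i == 1 else params.r2
        if r == 0:
            if b > 0:
                raise NoFiniteCriticalRelease(
                    f"prey {i} grows (b={b}) but is not predated (r=0); "
                    "no finite release eradicates it"
                )
            thresholds.append(0.0)
        else:
            thresholds.append(b * params.b3 * params.T / r)
    return max(thresholds)


# ---------------------------------------------------------------------------
# numeric eradication assessment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EradicationAssessment:
    """Outcome of the numeric eradication test on a trajectory."""

    eradicated: bool
    terminal_prey_max: float
    periods_simulated: int
    epsilon: float
    window: int


@dataclass(frozen=True)
class EfficacyResult:
    """Critical pesticide efficacy found by bisection."""

    E_star: float
    bracket_width: float
    converged: bool
    evaluations: int


def _prey_total(states: np.ndarray) -> np.ndarray:
    return states[:, 0] + states[:, 1]


def assess_eradication(
    trajectory: Trajectory,
    epsilon: float = DEFAULT_EPSILON,
    window: int = DEFAULT_WINDOW,
) -> EradicationAssessment:
    """Declare eradication when the total prey maximum over the last
    ``window`` periods of the trajectory stays below ``epsilon``."""
    if trajectory.n_periods < window:
        raise ValueError(
            f"trajectory covers {trajectory.n_periods} periods; "
            f"assessment window needs >= {window}"
        )
    tail = trajectory.window_slice(window)
    m = float(_prey_total(tail).max())
    return EradicationAssessment(
        eradicated=m < epsilon,
        terminal_prey_max=m,
        periods_simulated=trajectory.n_periods,
        epsilon=epsilon,
        window=window,
    )


@dataclass(frozen=True)
class EradicationScenario:
    """Everything needed to ask "does efficacy E eradicate the pest?".

    Bundles the parameter set, impulse schedule, birth-pulse mixture,
    initial state, and the numeric operationalization (horizon, window,
    epsilon, integrator tolerances).
    """

    params: SystemParams | StagePreyParams
    schedule: ImpulseSchedule
    state0: SystemState
    mixture: PulseMixture | None = None
    horizon: int = DEFAULT_HORIZON
    window: int = DEFAULT_WINDOW
    epsilon: float = DEFAULT_EPSILON
    rtol: float = 1e-8
    atol: float = 1e-10
    method: str = "RK45"
    samples_per_period: int = 4
    kill_mature: bool = False
    kill_predator: bool = False

    def with_mixture(self, mixture: PulseMixture) -> "EradicationScenario":
        return replace(self, mixture=mixture)


def _pack_fast(scenario: EradicationScenario, efficacy: float):
    """Pack a scenario into plain arrays for the compiled indicator."""
    from . import _fast
    from .integrate import _event_times

    sc = scenario
    if isinstance(sc.params, SystemParams):
        family = _fast.FAMILY_LOTKA
        p = sc.params
        pars = np.array([
            p.b1, p.b2, p.alpha, p.beta, p.r1, p.r2, p.b3, p.d,
            -1.0 if p.conversion_sign_mode == "as_printed" else 1.0,
            1.0 if p.x2_growth_mode == "as_printed" else 0.0,
        ])
    else:
        family = _fast.FAMILY_STAGE
        p = sc.params
        pars = np.array([
            p.death_immature, p.maturation, p.death_mature,
            p.r1, p.r2, p.b3, p.d,
        ])
    ev_time, ev_kind = [], []
    for t_off, evs in _event_times(sc.schedule, 1):
        for ev in evs:
            ev_time.append(t_off)
            ev_kind.append(0 if ev.kind == "predator_release" else 1)
    if sc.mixture is None:
        mw = np.empty(0)
        mf = np.empty(0, dtype=np.int64)
        mb = np.empty(0)
        mq = np.empty(0)
    else:
        comps = sc.mixture.components
        mw = np.array([w for w, _ in comps])
        mf = np.array(
            [0 if b.form == "beverton_holt" else 1 for _, b in comps],
            dtype=np.int64,
        )
        mb = np.array([b.b for _, b in comps])
        mq = np.array([b.q if b.q is not None else 0.0 for _, b in comps])
    state0 = np.asarray(sc.state0, dtype=float)
    escape = ESCAPE_FACTOR * max(1.0, state0[0] + state0[1])
    return (
        family, pars, state0, sc.schedule.period,
        np.asarray(ev_time, dtype=float), np.asarray(ev_kind, dtype=np.int64),
        float(sc.params.p), mw, mf, mb, mq, float(efficacy),
        sc.kill_mature, sc.kill_predator,
        sc.horizon, sc.window, sc.epsilon, escape, sc.rtol, sc.atol,
    )


def prey_eradicated(
    scenario: EradicationScenario, efficacy: float, fast: bool = True
) -> bool:
    """Eradication indicator with early exit.

    Simulates period by period; stops as soon as ``window`` consecutive
    per-period prey maxima fall below epsilon (success) or the prey maximum
    exceeds ``ESCAPE_FACTOR`` times its initial scale (failure). Otherwise
    runs to the horizon and applies the last-window criterion, identical to
    :func:`assess_eradication` on a full trajectory.

    ``fast=True`` (default) runs the compiled Dormand–Prince loop of
    :mod:`impulsepm._fast`; ``fast=False`` uses the scipy-based reference
    path (also used whenever a non-RK45 method is requested).
    """
    if not 0.0 <= efficacy <= 1.0:
        raise ModelDomainError(f"efficacy must lie in [0, 1], got {efficacy!r}")
    if fast and scenario.method == "RK45":
        from ._fast import eradicated_loop

        out = eradicated_loop(*_pack_fast(scenario, efficacy))
        if out < 0:
            raise IntegrationError(
                "compiled integrator failed (step-size underflow or "
                "negative state beyond tolerance)"
            )
        return bool(out)
    return _prey_eradicated_reference(scenario, efficacy)


def _prey_eradicated_reference(
    scenario: EradicationScenario, efficacy: float
) -> bool:
    """scipy-based reference implementation of :func:`prey_eradicated`."""
    sc = scenario
    field = make_field(sc.params)
    from .integrate import _apply_events, _clamp, _event_times  # noqa: PLC0415

    T = sc.schedule.period
    state = SystemState.from_array(sc.state0)
    escape = ESCAPE_FACTOR * max(1.0, state.x1 + state.x2)
    n_eval = max(2, sc.samples_per_period)
    recent: list[float] = []
    breaks_one = _event_times(sc.schedule, 1)

    for n in range(sc.horizon):
        period_max = 0.0
        t_cursor = n * T
        state_records: list = []
        for t_off, evs in breaks_one:
            t_ev = n * T + t_off
            if t_ev > t_cursor:
                t_eval = np.linspace(t_cursor, t_ev, n_eval)
                state, seg_t, seg_y = integrate_segment(
                    field, state, t_cursor, t_ev, sc.rtol, sc.atol, sc.method,
                    t_eval=t_eval[1:-1],
                )
                state = _clamp(state, sc.atol)
                period_max = max(period_max, float(_prey_total(seg_y).max()))
                t_cursor = t_ev
            period_max = max(period_max, state.x1 + state.x2)
            state = _apply_events(
                state, evs, t_ev, sc.params, sc.mixture, efficacy,
                sc.kill_mature, sc.kill_predator, state_records,
            )
            state = _clamp(state, sc.atol)
            period_max = max(period_max, state.x1 + state.x2)
        if t_cursor < (n + 1) * T:
            t_eval = np.linspace(t_cursor, (n + 1) * T, n_eval)
            state, seg_t, seg_y = integrate_segment(
                field, state, t_cursor, (n + 1) * T, sc.rtol, sc.atol,
                sc.method, t_eval=t_eval[1:-1],
            )
            state = _clamp(state, sc.atol)
            period_max = max(period_max, float(_prey_total(seg_y).max()))

        recent.append(period_max)
        if len(recent) > sc.window:
            recent.pop(0)
        if len(recent) == sc.window and max(recent) < sc.epsilon:
            return True
        if period_max > escape:
            return False
    return len(recent) == sc.window and max(recent) < sc.epsilon


def critical_efficacy(
    scenario: EradicationScenario,
    tol: float = DEFAULT_E_TOL,
    fast: bool = True,
) -> EfficacyResult:
    """Smallest pesticide efficacy (within ``tol``) that eradicates.

    Bisection on E in [0, 1]. E=1 is tested first: if even total kill
    fails within the horizon the result is ``E_star=1, converged=False``
    (after confirming E=0 also fails; success at E=0 with failure at E=1
    raises :class:`NonMonotoneEfficacyError`). The E=0 endpoint is tested
    only when the bracket collapses onto it, in which case ``E_star=0``.
    """
    if not 0 < tol < 1:
        raise ValueError(f"tol must lie in (0, 1), got {tol!r}")
    evals = 0

    def ok(E: float) -> bool:
        nonlocal evals
        evals += 1
        return prey_eradicated(scenario, E, fast=fast)

    if not ok(1.0):
        if ok(0.0):
            raise NonMonotoneEfficacyError(
                "scenario eradicates at E=0 but not at E=1; "
                "the eradication indicator is not monotone in E"
            )
        return EfficacyResult(1.0, 1.0, False, evals)

    lo, hi = 0.0, 1.0  # invariant: ok(hi) is True; lo untested-or-False
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if ok(mid):
            hi = mid
        else:
            lo = mid
    if hi <= tol and lo == 0.0 and ok(0.0):
        return EfficacyResult(0.0, hi - lo, True, evals)
    return EfficacyResult(hi, hi - lo, True, evals)


def simulate_scenario(
    scenario: EradicationScenario, efficacy: float | None = None
) -> Trajectory:
    """Full trajectory of a scenario (convenience wrapper)."""
    return simulate(
        scenario.params,
        scenario.schedule,
        scenario.state0,
        scenario.horizon,
        mixture=scenario.mixture,
        efficacy=efficacy,
        rtol=scenario.rtol,
        atol=scenario.atol,
        method=scenario.method,
        samples_per_period=scenario.samples_per_period,
        kill_mature=scenario.kill_mature,
        kill_predator=scenario.kill_predator,
    )
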