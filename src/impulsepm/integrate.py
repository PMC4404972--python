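"""Piecewise-smooth integration of the impulsive systems.

Impulse times are known a priori (``n*T + offset``), so the integrator uses
hard segmentation: it integrates the smooth vector field up to each event
time, applies the impulse map, and restarts. No event-detection root
finding is involved, which keeps runs bit-reproducible. Event times are
always computed by multiplication (``n * T + offset``), never by
accumulating step sizes.

Events with a positive phase offset fire at ``n*T + offset`` for
``n = 0, ..., n_periods - 1``; events at offset 0 fire at the period
boundaries ``T, 2T, ..., n_periods*T`` (the classic "impulse at t = nT,
n a positive integer" convention). Trajectories record both the left limit
``x(t)`` and the right limit ``x(t+)`` at every event.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .model import (
    ModelDomainError,
    PulseMixture,
    StagePreyParams,
    SystemParams,
    SystemState,
    birth_pesticide_impulse,
    make_field,
    predator_release_impulse,
)

__all__ = [
    "ImpulseEvent",
    "ImpulseSchedule",
    "TrajectoryEvent",
    "Trajectory",
    "IntegrationError",
    "integrate_segment",
    "simulate",
]

logger = logging.getLogger(__name__)

EVENT_KINDS = ("predator_release", "birth_pesticide")

#: components whose post-step magnitude falls below this are snapped to 0
CLAMP_TOL = 1e-13


class IntegrationError(RuntimeError):
    """The ODE solver failed to advance a segment."""


class ScheduleError(ValueError):
    """An impulse schedule violates its invariants."""


@dataclass(frozen=True)
class ImpulseEvent:
    """One impulse per period: a kind and a phase offset in [0, T)."""

    kind: str
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ScheduleError(
                f"unknown event kind {self.kind!r}; expected one of {EVENT_KINDS}"
            )
        if self.offset < 0:
            raise ScheduleError(f"offset must be >= 0, got {self.offset!r}")


@dataclass(frozen=True)
class ImpulseSchedule:
    """Periodic impulse program: period T plus per-period events.

    Offsets must be non-decreasing and lie in ``[0, T)``; events sharing an
    offset are applied in listed order.
    """

    period: float
    events: tuple[ImpulseEvent, ...]

    def __post_init__(self) -> None:
        if not self.period > 0:
            raise ScheduleError(f"period must be > 0, got {self.period!r}")
        object.__setattr__(self, "events", tuple(self.events))
        prev = -np.inf
        for ev in self.events:
            if ev.offset >= self.period:
                raise ScheduleError(
                    f"offset {ev.offset!r} not in [0, {self.period!r})"
                )
            if ev.offset < prev:
                raise ScheduleError("event offsets must be non-decreasing")
            prev = ev.offset

    def kinds(self) -> tuple[str, ...]:
        return tuple(ev.kind for ev in self.events)


@dataclass(frozen=True)
class TrajectoryEvent:
    """Record of one applied impulse with its left and right limits."""

    time: float
    kind: str
    state_before: SystemState
    state_after: SystemState


@dataclass
class Trajectory:
    """Piecewise-continuous solution samples plus impulse records.

    ``times``/``states`` contain the sampled solution including *two* rows
    per applied impulse (left limit then right limit at the same time).
    ``event_kind[i]`` is the impulse kind at row i (``"none"`` elsewhere)
    and ``limit_side[i]`` is ``"left"``/``"right"`` at impulse rows.
    """

    times: np.ndarray
    states: np.ndarray
    event_kind: list[str]
    limit_side: list[str]
    events: list[TrajectoryEvent] = dc_field(default_factory=list)
    period: float = np.nan
    n_periods: int = 0

    @property
    def final_state(self) -> SystemState:
        return SystemState.from_array(self.states[-1])

    def window_slice(self, n_last_periods: int) -> np.ndarray:
        """States sampled during the last ``n_last_periods`` periods."""
        t_lo = (self.n_periods - n_last_periods) * self.period
        return self.states[self.times >= t_lo - 1e-12 * self.period]


def integrate_segment(
    field: Callable[[float, np.ndarray], np.ndarray],
    state0: Sequence[float],
    t0: float,
    t1: float,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "RK45",
    t_eval: np.ndarray | None = None,
) -> tuple[SystemState, np.ndarray, np.ndarray]:
    """Integrate the smooth field over [t0, t1] with no impulses inside.

    Returns ``(state_at_t1, sample_times, sample_states)`` where the
    samples include the endpoints (and ``t_eval`` points, if given).
    """
    if not t1 > t0:
        raise ValueError(f"need t1 > t0, got [{t0!r}, {t1!r}]")
    if rtol <= 0 or atol <= 0:
        raise ValueError("tolerances must be positive")
    if t_eval is not None:
        t_eval = np.unique(np.concatenate(([t0], np.asarray(t_eval), [t1])))
    sol = solve_ivp(
        field,
        (t0, t1),
        np.asarray(state0, dtype=float),
        method=method,
        rtol=rtol,
        atol=atol,
        t_eval=t_eval,
        dense_output=False,
    )
    if not sol.success:
        raise IntegrationError(
            f"solver {method} failed on [{t0}, {t1}]: {sol.message}"
        )
    return SystemState.from_array(sol.y[:, -1]), sol.t, sol.y.T


def _clamp(state: SystemState, atol: float) -> SystemState:
    """Snap numerically-zero components to exactly zero.

    Tiny magnitudes (below ``CLAMP_TOL``) and small negative excursions of
    the order of the solver's absolute tolerance are both mapped to 0 so
    that the multiplicative fields cannot amplify spurious negatives.
    """
    out = []
    clamped = False
    floor = -100.0 * atol
    for v in state:
        if abs(v) < CLAMP_TOL or (floor < v < 0.0):
            out.append(0.0)
            clamped = clamped or v != 0.0
        elif v < 0.0:
            raise IntegrationError(
                f"state component {v!r} went negative beyond tolerance"
            )
        else:
            out.append(v)
    if clamped:
        logger.debug("clamped near-zero state components to 0: %r", state)
    return SystemState(*out)


def _event_times(schedule: ImpulseSchedule, n_periods: int):
    """Yield (time, [events]) in increasing time over the whole horizon."""
    T = schedule.period
    zero = [ev for ev in schedule.events if ev.offset == 0.0]
    positive = [ev for ev in schedule.events if ev.offset > 0.0]
    out: list[tuple[float, list[ImpulseEvent]]] = []
    for n in range(n_periods):
        grouped: list[tuple[float, list[ImpulseEvent]]] = []
        for ev in positive:
            t = n * T + ev.offset
            if grouped and grouped[-1][0] == t:
                grouped[-1][1].append(ev)
            else:
                grouped.append((t, [ev]))
        out.extend(grouped)
        if zero:
            out.append(((n + 1) * T, list(zero)))
    return out


def _apply_events(
    state: SystemState,
    events: Sequence[ImpulseEvent],
    time: float,
    params,
    mixture: PulseMixture | None,
    efficacy: float,
    kill_mature: bool,
    kill_predator: bool,
    records: list[TrajectoryEvent],
) -> SystemState:
    for ev in events:
        before = state
        if ev.kind == "predator_release":
            state = predator_release_impulse(state, params.p)
        else:
            state = birth_pesticide_impulse(
                state,
                mixture,
                efficacy,
                kill_mature=kill_mature,
                kill_predator=kill_predator,
            )
        records.append(TrajectoryEvent(time, ev.kind, before, state))
    return state


def simulate(
    params: SystemParams | StagePreyParams,
    schedule: ImpulseSchedule,
    state0: Sequence[float],
    n_periods: int,
    *,
    mixture: PulseMixture | None = None,
    efficacy: float | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "RK45",
    samples_per_period: int = 0,
    kill_mature: bool = False,
    kill_predator: bool = False,
) -> Trajectory:
    """Simulate ``n_periods`` periods of the impulsive system.

    Alternates smooth integration and impulse maps; integration always
    stops exactly at event times. ``efficacy`` defaults to ``params.E``
    when the parameter family carries one, else 0. ``samples_per_period``
    adds that many evenly spaced interior samples per period to the
    trajectory (0 keeps only segment endpoints and impulse rows).
    """
    if n_periods < 1:
        raise ValueError(f"n_periods must be >= 1, got {n_periods!r}")
    T = schedule.period
    if abs(getattr(params, "T") - T) > 1e-12 * T:
        raise ScheduleError(
            f"params.T={params.T!r} disagrees with schedule period {T!r}"
        )
    if efficacy is None:
        efficacy = float(getattr(params, "E", 0.0))
    if not 0.0 <= efficacy <= 1.0:
        raise ModelDomainError(f"efficacy must lie in [0, 1], got {efficacy!r}")

    field = make_field(params)
    state = _clamp(SystemState.from_array(state0), atol)

    times: list[float] = [0.0]
    states: list[SystemState] = [state]
    kinds: list[str] = ["none"]
    sides: list[str] = [""]
    records: list[TrajectoryEvent] = []

    horizon = n_periods * T
    breakpoints = _event_times(schedule, n_periods)

    def eval_points(a: float, b: float) -> np.ndarray | None:
        if samples_per_period <= 0:
            return np.empty(0)  # endpoints only
        n_int = max(0, int(np.ceil(samples_per_period * (b - a) / T)) - 1)
        return np.linspace(a, b, n_int + 2)[1:-1] if n_int else np.empty(0)

    t_cursor = 0.0
    for t_ev, evs in breakpoints:
        if t_ev > t_cursor:
            state, seg_t, seg_y = integrate_segment(
                field, state, t_cursor, t_ev, rtol, atol, method,
                t_eval=eval_points(t_cursor, t_ev),
            )
            state = _clamp(state, atol)
            for ti, yi in zip(seg_t[1:-1], seg_y[1:-1]):
                times.append(float(ti))
                states.append(SystemState.from_array(yi))
                kinds.append("none")
                sides.append("")
            t_cursor = t_ev
        for ev in evs:
            before = state
            state = _apply_events(
                state, [ev], t_ev, params, mixture, efficacy,
                kill_mature, kill_predator, records,
            )
            state = _clamp(state, atol)
            times.extend([t_ev, t_ev])
            states.extend([before, state])
            kinds.extend([ev.kind, ev.kind])
            sides.extend(["left", "right"])
    if t_cursor < horizon:
        state, seg_t, seg_y = integrate_segment(
            field, state, t_cursor, horizon, rtol, atol, method,
            t_eval=eval_points(t_cursor, horizon),
        )
        state = _clamp(state, atol)
        for ti, yi in zip(seg_t[1:-1], seg_y[1:-1]):
            times.append(float(ti))
            states.append(SystemState.from_array(yi))
            kinds.append("none")
            sides.append("")
        times.append(horizon)
        states.append(state)
        kinds.append("none")
        sides.append("")

    return Trajectory(
        times=np.asarray(times),
        states=np.asarray(states, dtype=float),
        event_kind=kinds,
        limit_side=sides,
        events=records,
        period=T,
        n_periods=n_periods,
    )
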