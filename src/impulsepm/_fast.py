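"""Compiled fast path for the eradication indicator.

The Monte-Carlo weight-selection loop evaluates the "does efficacy E
eradicate?" predicate tens of thousands of times; each evaluation is a
short impulsive simulation. This module runs that whole loop — an adaptive
Dormand–Prince 5(4) stepper for the two built-in vector fields plus the
impulse maps and the windowed eradication test — under numba, mirroring
the semantics of the scipy-based reference path in
:mod:`impulsepm.eradication` (which remains the documented integrator and
is cross-checked against this path in the test suite).

Error control follows the standard embedded-pair scheme: a step is
accepted when the RMS of the component errors scaled by
``atol + rtol * |y|`` is at most 1, and the step size is adapted with the
usual fifth-order safety rule.
"""

from __future__ import annotations

import numpy as np
from numba import njit

FAMILY_LOTKA = 0
FAMILY_STAGE = 1

CLAMP_TOL = 1e-13

# Dormand–Prince 5(4) tableau
_A21 = 1.0 / 5.0
_A31, _A32 = 3.0 / 40.0, 9.0 / 40.0
_A41, _A42, _A43 = 44.0 / 45.0, -56.0 / 15.0, 32.0 / 9.0
_A51, _A52, _A53, _A54 = (
    19372.0 / 6561.0,
    -25360.0 / 2187.0,
    64448.0 / 6561.0,
    -212.0 / 729.0,
)
_A61, _A62, _A63, _A64, _A65 = (
    9017.0 / 3168.0,
    -355.0 / 33.0,
    46732.0 / 5247.0,
    49.0 / 176.0,
    -5103.0 / 18656.0,
)
_B1, _B3, _B4, _B5, _B6 = (
    35.0 / 384.0,
    500.0 / 1113.0,
    125.0 / 192.0,
    -2187.0 / 6784.0,
    11.0 / 84.0,
)
_E1, _E3, _E4, _E5, _E6, _E7 = (
    71.0 / 57600.0,
    -71.0 / 16695.0,
    71.0 / 1920.0,
    -17253.0 / 339200.0,
    22.0 / 525.0,
    -1.0 / 40.0,
)


@njit(cache=True)
def _field(family, pars, y, out):
    x1, x2, yp = y[0], y[1], y[2]
    if family == FAMILY_LOTKA:
        b1, b2, alpha, beta, r1, r2, b3, d, s1, lead = (
            pars[0], pars[1], pars[2], pars[3], pars[4],
            pars[5], pars[6], pars[7], pars[8], pars[9],
        )
        out[0] = x1 * (b1 - x1 - alpha * x2 - r1 * yp)
        factor = x1 if lead > 0.5 else x2
        out[1] = factor * (b2 - x1 - beta * x2 - r2 * yp)
        out[2] = yp * (-b3 + s1 * d * r1 * x1 + d * r2 * x2)
    else:
        d1, m, d2, r1, r2, b3, d = (
            pars[0], pars[1], pars[2], pars[3], pars[4], pars[5], pars[6],
        )
        out[0] = -(d1 + m) * x1 - r1 * x1 * yp
        out[1] = m * x1 - d2 * x2 - r2 * x2 * yp
        out[2] = yp * (-b3 + d * (r1 * x1 + r2 * x2))


@njit(cache=True)
def _integrate(family, pars, y, t0, t1, rtol, atol):
    """Advance y in place from t0 to t1; return (prey_max, ok_flag)."""
    k1 = np.empty(3)
    k2 = np.empty(3)
    k3 = np.empty(3)
    k4 = np.empty(3)
    k5 = np.empty(3)
    k6 = np.empty(3)
    k7 = np.empty(3)
    ytmp = np.empty(3)
    ynew = np.empty(3)

    prey_max = y[0] + y[1]
    t = t0
    h = 0.1 * (t1 - t0)
    _field(family, pars, y, k1)
    steps = 0
    while t < t1:
        steps += 1
        if steps > 200000:
            return prey_max, False
        if h > t1 - t:
            h = t1 - t
        for i in range(3):
            ytmp[i] = y[i] + h * _A21 * k1[i]
        _field(family, pars, ytmp, k2)
        for i in range(3):
            ytmp[i] = y[i] + h * (_A31 * k1[i] + _A32 * k2[i])
        _field(family, pars, ytmp, k3)
        for i in range(3):
            ytmp[i] = y[i] + h * (_A41 * k1[i] + _A42 * k2[i] + _A43 * k3[i])
        _field(family, pars, ytmp, k4)
        for i in range(3):
            ytmp[i] = y[i] + h * (
                _A51 * k1[i] + _A52 * k2[i] + _A53 * k3[i] + _A54 * k4[i]
            )
        _field(family, pars, ytmp, k5)
        for i in range(3):
            ytmp[i] = y[i] + h * (
                _A61 * k1[i] + _A62 * k2[i] + _A63 * k3[i]
                + _A64 * k4[i] + _A65 * k5[i]
            )
        _field(family, pars, ytmp, k6)
        for i in range(3):
            ynew[i] = y[i] + h * (
                _B1 * k1[i] + _B3 * k3[i] + _B4 * k4[i]
                + _B5 * k5[i] + _B6 * k6[i]
            )
        _field(family, pars, ynew, k7)
        err = 0.0
        for i in range(3):
            ei = h * (
                _E1 * k1[i] + _E3 * k3[i] + _E4 * k4[i]
                + _E5 * k5[i] + _E6 * k6[i] + _E7 * k7[i]
            )
            sc = atol + rtol * max(abs(y[i]), abs(ynew[i]))
            err += (ei / sc) ** 2
        err = (err / 3.0) ** 0.5
        if err <= 1.0:
            t = t + h
            for i in range(3):
                y[i] = ynew[i]
                k1[i] = k7[i]  # FSAL
            prey = y[0] + y[1]
            if prey > prey_max:
                prey_max = prey
        if err == 0.0:
            factor = 5.0
        else:
            factor = 0.9 * err ** -0.2
            if factor > 5.0:
                factor = 5.0
            elif factor < 0.2:
                factor = 0.2
        h *= factor
        if h <= 1e-14 * (t1 - t0):
            return prey_max, False
    return prey_max, True


@njit(cache=True)
def _clamp3(y, atol):
    """Snap near-zero / tolerably negative components to exactly 0."""
    floor = -100.0 * atol
    for i in range(3):
        v = y[i]
        if abs(v) < CLAMP_TOL or (floor < v < 0.0):
            y[i] = 0.0
        elif v < 0.0:
            return False
    return True


@njit(cache=True)
def _apply_impulse(
    kind, y, p_release, mix_w, mix_form, mix_b, mix_q, efficacy,
    kill_mature, kill_predator,
):
    if kind == 0:  # predator release
        y[2] += p_release
    else:  # joint birth pulse + pesticide, pre-impulse state throughout
        x1, x2 = y[0], y[1]
        births = 0.0
        for j in range(mix_w.shape[0]):
            if mix_form[j] == 0:
                births += mix_w[j] * mix_b[j] * x2 / (mix_q[j] + x1 + x2)
            else:
                births += mix_w[j] * mix_b[j] * x2 * np.exp(-(x1 + x2))
        y[0] = (x1 + births) * (1.0 - efficacy)
        if kill_mature:
            y[1] = x2 * (1.0 - efficacy)
        if kill_predator:
            y[2] = y[2] * (1.0 - efficacy)


@njit(cache=True)
def eradicated_loop(
    family,
    pars,
    state0,
    T,
    ev_time,
    ev_kind,
    p_release,
    mix_w,
    mix_form,
    mix_b,
    mix_q,
    efficacy,
    kill_mature,
    kill_predator,
    horizon,
    window,
    epsilon,
    escape,
    rtol,
    atol,
):
    """Windowed eradication test with early exit.

    Returns 1 (eradicated), 0 (not eradicated), or -1 (integrator failure).
    Mirrors the reference implementation: per-period prey maxima are
    tracked; success as soon as ``window`` consecutive maxima stay below
    epsilon, failure when a maximum exceeds ``escape`` or the horizon ends
    without the last window staying below epsilon.
    """
    y = state0.copy()
    recent = np.empty(window)
    filled = 0
    for n in range(horizon):
        period_max = 0.0
        t_cursor = n * T
        for j in range(ev_time.shape[0]):
            t_ev = n * T + ev_time[j]
            if t_ev > t_cursor:
                pm, ok = _integrate(family, pars, y, t_cursor, t_ev, rtol, atol)
                if not ok or not _clamp3(y, atol):
                    return -1
                if pm > period_max:
                    period_max = pm
                t_cursor = t_ev
            _apply_impulse(
                ev_kind[j], y, p_release, mix_w, mix_form, mix_b, mix_q,
                efficacy, kill_mature, kill_predator,
            )
            if not _clamp3(y, atol):
                return -1
            prey = y[0] + y[1]
            if prey > period_max:
                period_max = prey
        if t_cursor < (n + 1) * T:
            pm, ok = _integrate(
                family, pars, y, t_cursor, (n + 1) * T, rtol, atol
            )
            if not ok or not _clamp3(y, atol):
                return -1
            if pm > period_max:
                period_max = pm

        if filled < window:
            recent[filled] = period_max
            filled += 1
        else:
            for i in range(window - 1):
                recent[i] = recent[i + 1]
            recent[window - 1] = period_max
        if filled == window:
            worst = recent[0]
            for i in range(1, window):
                if recent[i] > worst:
                    worst = recent[i]
            if worst < epsilon:
                return 1
        if period_max > escape:
            return 0
    if filled == window:
        worst = recent[0]
        for i in range(1, window):
            if recent[i] > worst:
                worst = recent[i]
        if worst < epsilon:
            return 1
    return 0
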