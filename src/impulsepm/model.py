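"""Continuous vector fields, birth-pulse functions and impulse maps.

Two model families are provided:

* A one-predator, two-prey Lotka–Volterra competition system with periodic
  predator release: between impulses the densities follow

  .. math::

      x_1' &= x_1 (b_1 - x_1 - \\alpha x_2 - r_1 y), \\\\
      x_2' &= x_2 (b_2 - x_1 - \\beta x_2 - r_2 y), \\\\
      y'   &= y (-b_3 + d r_1 x_1 + d r_2 x_2),

  and at each impulse time the predator receives a release ``y -> y + p``.
  Historic presentations of this system carry an :math:`x_1` leading factor
  in the :math:`x_2` equation and a negative conversion term
  :math:`-d r_1 x_1` in the predator equation; both variants are available
  behind ``x2_growth_mode`` / ``conversion_sign_mode`` flags, with the
  standard competition form as the default.

* A stage-structured prey model (immature ``x1``, mature ``x2``, predator
  ``y``) in which reproduction happens only through discrete birth pulses:
  at impulse times the immature class jumps by

  .. math:: x_1(t^+) = \\Bigl(x_1 + \\sum_k \\pi_k B_k(x_1, x_2)\\Bigr)(1 - E),

  where the :math:`B_k` are density-dependent birth-pulse functions
  (Beverton–Holt or Ricker), :math:`\\pi_k` are convex mixture weights and
  :math:`E \\in [0, 1]` is the pesticide efficacy (fraction of the
  post-birth immature class removed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "SystemState",
    "SystemParams",
    "StagePreyParams",
    "BirthPulse",
    "PulseMixture",
    "system1_field",
    "stage_field",
    "make_field",
    "predator_release_impulse",
    "evaluate_pulse",
    "mixture_births",
    "birth_pesticide_impulse",
]

WEIGHT_SUM_TOL = 1e-12


class ModelDomainError(ValueError):
    """A parameter or state lies outside the model's domain."""


class SystemState(NamedTuple):
    """Population densities: two prey classes and one predator.

    For the Lotka–Volterra family ``x1``/``x2`` are two competing prey
    species; for the stage-structured family they are the immature and
    mature stages of a single pest.
    """

    x1: float
    x2: float
    y: float

    @staticmethod
    def from_array(a: Sequence[float]) -> "SystemState":
        return SystemState(float(a[0]), float(a[1]), float(a[2]))


def _require_nonneg(name: str, value: float) -> None:
    if not np.isfinite(value) or value < 0:
        raise ModelDomainError(f"{name} must be finite and >= 0, got {value!r}")


@dataclass(frozen=True)
class SystemParams:
    """Rate constants of the Lotka–Volterra pest system with releases.

    Parameters
    ----------
    b1, b2 : intrinsic prey growth rates (1/time).
    alpha, beta : interspecific competition factors (1/density).
    r1, r2 : predation rates (1/(density * time)).
    b3 : predator per-capita death rate (1/time).
    d : conversion efficiency of kills into predator births.
    p : predator release amount added at each release impulse (density).
    T : impulse period (time).
    conversion_sign_mode : ``"standard"`` credits the predator for kills of
        both prey (+, +); ``"as_printed"`` reproduces the historic
        (-, +) sign pattern literally.
    x2_growth_mode : leading factor of the second prey equation,
        ``"standard"`` for ``x2 * (...)`` or ``"as_printed"`` for
        ``x1 * (...)``.
    """

    b1: float
    b2: float
    alpha: float
    beta: float
    r1: float
    r2: float
    b3: float
    d: float
    p: float
    T: float
    conversion_sign_mode: str = "standard"
    x2_growth_mode: str = "standard"

    def __post_init__(self) -> None:
        for name in ("b1", "b2", "alpha", "beta", "r1", "r2", "b3", "d", "p"):
            _require_nonneg(name, getattr(self, name))
        if not self.T > 0:
            raise ModelDomainError(f"T must be > 0, got {self.T!r}")
        for name in ("conversion_sign_mode", "x2_growth_mode"):
            if getattr(self, name) not in ("standard", "as_printed"):
                raise ModelDomainError(
                    f"{name} must be 'standard' or 'as_printed', "
                    f"got {getattr(self, name)!r}"
                )


@dataclass(frozen=True)
class StagePreyParams:
    """Stage-structured pest with pulsed births and predator releases.

    The continuous part has no reproduction; all prey births enter the
    immature class at impulse times through the birth-pulse mixture.

    Parameters
    ----------
    death_immature : immature prey per-capita death rate (1/time).
    maturation : immature -> mature transition rate (1/time).
    death_mature : mature prey per-capita death rate (1/time).
    r1, r2 : predation rates on the immature / mature stage.
    b3 : predator per-capita death rate (1/time).
    d : conversion efficiency of kills into predator births.
    E : pesticide efficacy, fraction of the post-birth immature class
        removed at each birth/pesticide impulse; in [0, 1].
    T : impulse period (time).
    p : predator release amount (density), 0 when no releases occur.
    """

    death_immature: float
    maturation: float
    death_mature: float
    r1: float
    r2: float
    b3: float
    d: float
    E: float
    T: float
    p: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "death_immature",
            "maturation",
            "death_mature",
            "r1",
            "r2",
            "b3",
            "d",
            "p",
        ):
            _require_nonneg(name, getattr(self, name))
        if not 0.0 <= self.E <= 1.0:
            raise ModelDomainError(f"E must lie in [0, 1], got {self.E!r}")
        if not self.T > 0:
            raise ModelDomainError(f"T must be > 0, got {self.T!r}")


@dataclass(frozen=True)
class BirthPulse:
    """A density-dependent birth-pulse function.

    ``beverton_holt`` (rational, saturating):
        ``B(x1, x2) = b * x2 / (q + x1 + x2)``
    ``ricker`` (exponentially damped):
        ``B(x1, x2) = b * x2 * exp(-(x1 + x2))``

    ``b`` is the pulse magnitude (births per unit mature density at low
    density); ``q`` is the Beverton–Holt half-saturation constant (density).
    """

    form: str
    b: float
    q: float | None = None

    def __post_init__(self) -> None:
        if self.form not in ("beverton_holt", "ricker"):
            raise ModelDomainError(
                f"form must be 'beverton_holt' or 'ricker', got {self.form!r}"
            )
        _require_nonneg("b", self.b)
        if self.form == "beverton_holt":
            if self.q is None or not self.q > 0:
                raise ModelDomainError(
                    f"beverton_holt requires q > 0, got {self.q!r}"
                )

    def replace_magnitude(self, b: float) -> "BirthPulse":
        return BirthPulse(self.form, b, self.q)


@dataclass(frozen=True)
class PulseMixture:
    """Convex combination of birth-pulse functions.

    ``components`` is an ordered sequence of ``(weight, BirthPulse)`` pairs
    with weights in [0, 1] summing to 1 (within 1e-12).
    """

    components: tuple[tuple[float, BirthPulse], ...]

    def __post_init__(self) -> None:
        comps = tuple((float(w), p) for w, p in self.components)
        object.__setattr__(self, "components", comps)
        if len(comps) < 1:
            raise ModelDomainError("mixture needs at least one component")
        for w, _ in comps:
            if not 0.0 <= w <= 1.0:
                raise ModelDomainError(f"mixture weight {w!r} outside [0, 1]")
        total = math.fsum(w for w, _ in comps)
        if abs(total - 1.0) > WEIGHT_SUM_TOL:
            raise ModelDomainError(
                f"mixture weights must sum to 1 (got {total!r})"
            )

    @staticmethod
    def two_component(pi: float, b1: BirthPulse, b2: BirthPulse) -> "PulseMixture":
        """Mixture with weight ``pi`` on the first pulse and ``1 - pi`` on
        the second."""
        if not 0.0 <= pi <= 1.0:
            raise ModelDomainError(f"pi must lie in [0, 1], got {pi!r}")
        return PulseMixture(((pi, b1), (1.0 - pi, b2)))

    @staticmethod
    def single(pulse: BirthPulse) -> "PulseMixture":
        return PulseMixture(((1.0, pulse),))


# ---------------------------------------------------------------------------
# continuous vector fields
# ---------------------------------------------------------------------------

def system1_field(state: Sequence[float], params: SystemParams) -> np.ndarray:
    """Time derivative of the Lotka–Volterra pest system between impulses."""
    x1, x2, y = float(state[0]), float(state[1]), float(state[2])
    if not (np.isfinite(x1) and np.isfinite(x2) and np.isfinite(y)):
        raise ModelDomainError(f"non-finite state {(x1, x2, y)!r}")
    s1 = -1.0 if params.conversion_sign_mode == "as_printed" else 1.0
    lead = x1 if params.x2_growth_mode == "as_printed" else x2
    dx1 = x1 * (params.b1 - x1 - params.alpha * x2 - params.r1 * y)
    dx2 = lead * (params.b2 - x1 - params.beta * x2 - params.r2 * y)
    dy = y * (-params.b3 + s1 * params.d * params.r1 * x1 + params.d * params.r2 * x2)
    return np.array([dx1, dx2, dy])


def stage_field(state: Sequence[float], params: StagePreyParams) -> np.ndarray:
    """Time derivative of the stage-structured pest system between impulses."""
    x1, x2, y = float(state[0]), float(state[1]), float(state[2])
    if not (np.isfinite(x1) and np.isfinite(x2) and np.isfinite(y)):
        raise ModelDomainError(f"non-finite state {(x1, x2, y)!r}")
    dx1 = -(params.death_immature + params.maturation) * x1 - params.r1 * x1 * y
    dx2 = params.maturation * x1 - params.death_mature * x2 - params.r2 * x2 * y
    dy = y * (-params.b3 + params.d * (params.r1 * x1 + params.r2 * x2))
    return np.array([dx1, dx2, dy])


def make_field(params):
    """Return the ``f(t, state)`` callable for either parameter family."""
    if isinstance(params, SystemParams):
        return lambda t, s: system1_field(s, params)
    if isinstance(params, StagePreyParams):
        return lambda t, s: stage_field(s, params)
    raise TypeError(f"unsupported parameter type {type(params).__name__}")


# ---------------------------------------------------------------------------
# impulse maps
# ---------------------------------------------------------------------------

def predator_release_impulse(state: Sequence[float], p: float) -> SystemState:
    """Add ``p`` predators; prey classes pass through unchanged."""
    if p < 0:
        raise ModelDomainError(f"release amount p must be >= 0, got {p!r}")
    x1, x2, y = state
    return SystemState(float(x1), float(x2), float(y) + float(p))


def evaluate_pulse(pulse: BirthPulse, x1: float, x2: float) -> float:
    """Births produced by one pulse function at prey densities (x1, x2)."""
    if x1 < 0 or x2 < 0:
        raise ModelDomainError(f"densities must be >= 0, got {(x1, x2)!r}")
    if pulse.form == "beverton_holt":
        return pulse.b * x2 / (pulse.q + x1 + x2)
    return pulse.b * x2 * math.exp(-(x1 + x2))


def mixture_births(mix: PulseMixture | None, x1: float, x2: float) -> float:
    """Weighted births of the mixture; 0 for an absent mixture."""
    if mix is None:
        return 0.0
    return math.fsum(w * evaluate_pulse(p, x1, x2) for w, p in mix.components)


def birth_pesticide_impulse(
    state: Sequence[float],
    mix: PulseMixture | None,
    E: float,
    *,
    kill_mature: bool = False,
    kill_predator: bool = False,
) -> SystemState:
    """Joint birth-pulse + pesticide map.

    The immature class becomes ``(x1 + sum_k pi_k B_k(x1, x2)) * (1 - E)``,
    with all pulses evaluated at the pre-impulse (left-limit) state: births
    and spraying form one simultaneous map, not a sequential pair. By
    default the mature class and the predator pass through unchanged;
    ``kill_mature`` / ``kill_predator`` additionally scale them by
    ``1 - E``.
    """
    if not 0.0 <= E <= 1.0:
        raise ModelDomainError(f"efficacy E must lie in [0, 1], got {E!r}")
    x1, x2, y = float(state[0]), float(state[1]), float(state[2])
    new_x1 = (x1 + mixture_births(mix, x1, x2)) * (1.0 - E)
    new_x2 = x2 * (1.0 - E) if kill_mature else x2
    new_y = y * (1.0 - E) if kill_predator else y
    return SystemState(new_x1, new_x2, new_y)
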