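"""Self-contained scenario generators for experiments and tests.

Three named fixtures are provided:

``baseline_system1``
    The one-predator, two-prey release-only system parameterized at its
    eradication boundary (the embedded release amount equals the critical
    release, so nudging ``p`` up or down flips the outcome).
``stage_mixture``
    The stage-structured pest with a two-component Beverton–Holt birth
    pulse mixture, joint birth/pesticide impulse and predator release.
``stochastic_sweep``
    The full stochastic experiment: three average-birth-rate levels
    (low/medium/high) crossed with uniform and exponential priors, swept
    over a grid of mixture weights.

All numeric scales (horizons, windows, Monte-Carlo draw counts) are the
package's scaled study sizes, documented in the methods note.
"""

from __future__ import annotations

import math
from dataclasses import replace

from .config import EradicationOptions, IntegratorOptions, ScenarioConfig
from .eradication import critical_release
from .integrate import ImpulseEvent, ImpulseSchedule
from .model import BirthPulse, PulseMixture, StagePreyParams, SystemParams, SystemState
from .stochastic import MixtureDesign, PriorSpec

__all__ = ["make_fixture", "FIXTURE_NAMES"]

FIXTURE_NAMES = ("baseline_system1", "stage_mixture", "stochastic_sweep")

#: low/medium/high average birth-rate levels (pulse-magnitude units);
#: illustrative scales, not field-calibrated values
PRIOR_LEVELS = {"low": 0.5, "medium": 2.0, "high": 5.0}

PI_GRID = (0.0, 0.25, 0.5, 0.75, 1.0)


def _baseline_system1(seed: int) -> ScenarioConfig:
    base = SystemParams(
        b1=1.0, b2=0.8, alpha=0.2, beta=0.3, r1=1.2, r2=1.0,
        b3=0.6, d=0.3, p=0.0, T=1.0,
    )
    p_c = critical_release(base)
    params = replace(base, p=p_c)
    return ScenarioConfig(
        model="lotka_volterra_ipm",
        params=params,
        schedule=ImpulseSchedule(1.0, (ImpulseEvent("predator_release", 0.0),)),
        initial_state=SystemState(
            0.3, 0.3, params.p / (1.0 - math.exp(-params.b3 * params.T))
        ),
        efficacy=0.0,
        integrator=IntegratorOptions(rtol=1e-8, atol=1e-10, samples_per_period=4),
        eradication=EradicationOptions(horizon=400, window=20, epsilon=1e-6),
    )


def _stage_mixture(seed: int) -> ScenarioConfig:
    params = StagePreyParams(
        death_immature=0.2,
        maturation=0.8,
        death_mature=0.25,
        r1=0.4,
        r2=0.6,
        b3=0.5,
        d=0.3,
        E=0.4,
        T=1.0,
        p=0.3,
    )
    mixture = PulseMixture.two_component(
        0.5,
        BirthPulse("beverton_holt", b=2.0, q=0.5),
        BirthPulse("beverton_holt", b=2.0, q=5.0),
    )
    return ScenarioConfig(
        model="stage_structured",
        params=params,
        schedule=ImpulseSchedule(
            1.0,
            (
                ImpulseEvent("birth_pesticide", 0.0),
                ImpulseEvent("predator_release", 0.0),
            ),
        ),
        initial_state=SystemState(0.5, 0.5, 1.0),
        efficacy=0.4,
        mixture=mixture,
        integrator=IntegratorOptions(rtol=1e-6, atol=1e-9, samples_per_period=4),
        eradication=EradicationOptions(horizon=80, window=10, epsilon=1e-6),
    )


def _stochastic_sweep(seed: int) -> ScenarioConfig:
    cfg = _stage_mixture(seed)
    priors = []
    for level, mean in PRIOR_LEVELS.items():
        priors.append(
            (PriorSpec("uniform", lower=0.0, upper=2.0 * mean, level=level),)
        )
        priors.append((PriorSpec("exponential", mean_=mean, level=level),))
    design = MixtureDesign(
        pi_grid=PI_GRID,
        n_draws=50,
        seed=seed,
        share_draws=True,
        dispersion="variance",
    )
    return replace(
        cfg,
        priors=tuple(priors),
        design=design,
        eradication=EradicationOptions(horizon=60, window=8, epsilon=1e-5),
    )


def make_fixture(name: str, seed: int = 0) -> ScenarioConfig:
    """Build a named, fully validated scenario configuration.

    The same ``(name, seed)`` always yields an identical config; ``seed``
    feeds the Monte-Carlo design of stochastic fixtures.
    """
    builders = {
        "baseline_system1": _baseline_system1,
        "stage_mixture": _stage_mixture,
        "stochastic_sweep": _stochastic_sweep,
    }
    if name not in builders:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        )
    return builders[name](seed)
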