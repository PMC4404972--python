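"""Stochastic birth-rate priors and selection of the mixing weight pi.

Environmental and climatic variability makes the pest's birth-pulse
magnitude a random variable rather than a constant. This module draws the
magnitude from a prior (uniform, exponential, or a degenerate point mass),
propagates each draw through the impulsive model to the critical pesticide
efficacy E*, and scores each candidate mixture weight pi by the dispersion
of the resulting E* sample. The selected weight pi* minimizes that
dispersion: it identifies the mixture whose pesticide requirement is least
sensitive to birth-rate uncertainty, i.e. the most consistent eradication
strategy.

All candidates are evaluated under common random numbers — draw k uses the
identical sampled magnitude for every pi — so dispersion differences
reflect the weight alone, not sampling noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .eradication import EradicationScenario, critical_efficacy
from .model import ModelDomainError, PulseMixture

__all__ = [
    "PriorSpec",
    "MixtureDesign",
    "MonteCarloResult",
    "MixtureOptimizationResult",
    "mixture_pdf",
    "sample_prior",
    "monte_carlo_efficacy",
    "optimize_pi",
]

PRIOR_FAMILIES = ("uniform", "exponential", "point")
DISPERSIONS = ("variance", "sd", "cv")


@dataclass(frozen=True)
class PriorSpec:
    """Probability law of a stochastic pulse magnitude.

    families:
      * ``uniform(lower, upper)`` — non-informative over a range;
      * ``exponential(mean)`` — small pulses prevalent, large ones rare;
      * ``point(value)`` — degenerate (no stochasticity).

    ``level`` is a descriptive tag for the prior mean (low/medium/high).
    """

    family: str
    lower: float | None = None
    upper: float | None = None
    mean_: float | None = None
    value: float | None = None
    level: str | None = None

    def __post_init__(self) -> None:
        if self.family not in PRIOR_FAMILIES:
            raise ModelDomainError(
                f"unknown prior family {self.family!r}; expected {PRIOR_FAMILIES}"
            )
        if self.family == "uniform":
            if self.lower is None or self.upper is None or not self.lower < self.upper:
                raise ModelDomainError(
                    f"uniform prior needs lower < upper, got "
                    f"({self.lower!r}, {self.upper!r})"
                )
            if self.lower < 0:
                raise ModelDomainError("pulse magnitudes are non-negative")
        elif self.family == "exponential":
            if self.mean_ is None or not self.mean_ > 0:
                raise ModelDomainError(
                    f"exponential prior needs mean > 0, got {self.mean_!r}"
                )
        else:
            if self.value is None or self.value < 0:
                raise ModelDomainError(
                    f"point prior needs value >= 0, got {self.value!r}"
                )

    @property
    def mean(self) -> float:
        """Closed-form prior mean."""
        if self.family == "uniform":
            return 0.5 * (self.lower + self.upper)
        if self.family == "exponential":
            return self.mean_
        return self.value

    def pdf(self, x) -> np.ndarray | float:
        """Probability density (point priors have no density and raise)."""
        if self.family == "uniform":
            return stats.uniform.pdf(x, loc=self.lower, scale=self.upper - self.lower)
        if self.family == "exponential":
            return stats.expon.pdf(x, scale=self.mean_)
        raise ModelDomainError("a point prior has no probability density")

    def sample(self, rng: np.random.Generator, size=None):
        if self.family == "uniform":
            return rng.uniform(self.lower, self.upper, size=size)
        if self.family == "exponential":
            return rng.exponential(self.mean_, size=size)
        return self.value if size is None else np.full(size, float(self.value))


def mixture_pdf(
    pi: float,
    f_X: Callable[[float], float],
    f_Y: Callable[[float], float],
    x,
):
    """Two-component mixture density ``(1 - pi) f_X(x) + pi f_Y(x)``."""
    if not 0.0 <= pi <= 1.0:
        raise ModelDomainError(f"pi must lie in [0, 1], got {pi!r}")
    return (1.0 - pi) * f_X(x) + pi * f_Y(x)


def sample_prior(prior: PriorSpec, rng: np.random.Generator) -> float:
    """One draw from the prior, consuming the given generator's stream."""
    return float(prior.sample(rng))


@dataclass(frozen=True)
class MixtureDesign:
    """Experimental design for the pi sweep.

    ``pi_grid`` lists the candidate weights (endpoints 0 and 1 are allowed
    as diagnostic cases); ``n_draws`` Monte-Carlo draws are taken per
    candidate from ``seed``; ``share_draws`` controls whether both mixture
    components receive the same sampled magnitude (default) or each its
    own; ``dispersion`` picks the "variation of E" measure; non-converged
    draws (E*=1 with the horizon exhausted) are included unless
    ``include_nonconverged`` is False.
    """

    pi_grid: tuple[float, ...]
    n_draws: int
    seed: int
    share_draws: bool = True
    dispersion: str = "variance"
    include_nonconverged: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "pi_grid", tuple(float(p) for p in self.pi_grid))
        if len(self.pi_grid) == 0:
            raise ModelDomainError("pi_grid must not be empty")
        for pi in self.pi_grid:
            if not 0.0 <= pi <= 1.0:
                raise ModelDomainError(f"pi grid value {pi!r} outside [0, 1]")
        if self.n_draws < 2:
            raise ModelDomainError("variance estimation needs n_draws >= 2")
        if self.dispersion not in DISPERSIONS:
            raise ModelDomainError(
                f"dispersion must be one of {DISPERSIONS}, got {self.dispersion!r}"
            )


@dataclass(frozen=True)
class MonteCarloResult:
    """E* sample for one candidate weight."""

    pi: float
    e_star: np.ndarray
    converged: np.ndarray
    draws: np.ndarray
    seed: int

    @property
    def mean(self) -> float:
        return float(np.mean(self.e_star))

    @property
    def variance(self) -> float:
        return float(np.var(self.e_star, ddof=1))


def _draw_magnitudes(
    priors: Sequence[PriorSpec],
    n_draws: int,
    seed: int,
    share_draws: bool,
) -> np.ndarray:
    """Sampled magnitudes, shape (n_draws, n_components).

    With shared draws the first prior feeds every component, so one random
    magnitude drives the whole mixture; otherwise each component has its
    own prior and its own independent stream (spawned from the same seed,
    so adding a component never perturbs the others)."""
    ss = np.random.SeedSequence(seed)
    if share_draws:
        rng = np.random.default_rng(ss)
        col = np.asarray(priors[0].sample(rng, size=n_draws), dtype=float)
        return np.column_stack([col, col])
    children = ss.spawn(len(priors))
    cols = [
        np.asarray(pr.sample(np.random.default_rng(child), size=n_draws), dtype=float)
        for pr, child in zip(priors, children)
    ]
    return np.column_stack(cols)


def monte_carlo_efficacy(
    scenario: EradicationScenario,
    priors: PriorSpec | Sequence[PriorSpec],
    pi: float,
    n_draws: int,
    seed: int,
    *,
    share_draws: bool = True,
    e_tol: float = 1e-3,
) -> MonteCarloResult:
    """E* sample under random pulse magnitudes at a fixed weight ``pi``.

    The scenario's mixture must have two components; each draw overwrites
    the component magnitudes (shared or per-component), re-weights them as
    ``(pi, 1 - pi)``, and computes the critical efficacy. Draws whose
    bisection could not converge (E=1 fails within the horizon) enter the
    sample as E*=1 and are flagged in ``converged``.
    """
    if scenario.mixture is None or len(scenario.mixture.components) != 2:
        raise ModelDomainError(
            "monte_carlo_efficacy needs a 2-component template mixture"
        )
    if not 0.0 <= pi <= 1.0:
        raise ModelDomainError(f"pi must lie in [0, 1], got {pi!r}")
    if n_draws < 2:
        raise ModelDomainError("need n_draws >= 2")
    priors_seq = [priors] if isinstance(priors, PriorSpec) else list(priors)
    if not share_draws and len(priors_seq) != 2:
        raise ModelDomainError(
            "independent draws need one prior per mixture component"
        )
    base = [pulse for _, pulse in scenario.mixture.components]
    draws = _draw_magnitudes(priors_seq, n_draws, seed, share_draws)
    e_star = np.empty(n_draws)
    converged = np.empty(n_draws, dtype=bool)
    for k in range(n_draws):
        mix = PulseMixture.two_component(
            pi,
            base[0].replace_magnitude(draws[k, 0]),
            base[1].replace_magnitude(draws[k, 1]),
        )
        res = critical_efficacy(scenario.with_mixture(mix), tol=e_tol)
        e_star[k] = res.E_star
        converged[k] = res.converged
    return MonteCarloResult(pi, e_star, converged, draws, seed)


@dataclass(frozen=True)
class MixtureOptimizationResult:
    """Outcome of the pi sweep: per-candidate samples and the argmin."""

    pi_grid: tuple[float, ...]
    samples: tuple[MonteCarloResult, ...]
    means: np.ndarray
    dispersions: np.ndarray
    dispersion_measure: str
    pi_star: float
    seed: int
    n_draws: int

    def to_dict(self) -> dict:
        """JSON-serializable summary including full sample vectors."""
        return {
            "pi_grid": list(self.pi_grid),
            "dispersion_measure": self.dispersion_measure,
            "pi_star": self.pi_star,
            "seed": self.seed,
            "n_draws": self.n_draws,
            "candidates": [
                {
                    "pi": s.pi,
                    "mean_e_star": float(m),
                    "dispersion": float(d),
                    "e_star": [float(v) for v in s.e_star],
                    "converged": [bool(c) for c in s.converged],
                }
                for s, m, d in zip(self.samples, self.means, self.dispersions)
            ],
        }


def _dispersion(values: np.ndarray, measure: str) -> float:
    var = float(np.var(values, ddof=1))
    if measure == "variance":
        return var
    sd = var ** 0.5
    if measure == "sd":
        return sd
    mean = float(np.mean(values))
    return sd / mean if mean > 0 else np.inf


def optimize_pi(
    design: MixtureDesign,
    scenario: EradicationScenario,
    priors: PriorSpec | Sequence[PriorSpec],
    *,
    e_tol: float = 1e-3,
) -> MixtureOptimizationResult:
    """Sweep the pi grid under common random numbers and pick the weight
    with minimal dispersion of E*; ties break toward the smallest pi."""
    results = []
    for pi in design.pi_grid:
        results.append(
            monte_carlo_efficacy(
                scenario,
                priors,
                pi,
                design.n_draws,
                design.seed,
                share_draws=design.share_draws,
                e_tol=e_tol,
            )
        )
    means = np.empty(len(results))
    disps = np.empty(len(results))
    for j, res in enumerate(results):
        values = res.e_star
        if not design.include_nonconverged:
            values = values[res.converged]
        if values.size >= 2:
            means[j] = float(np.mean(values))
            disps[j] = _dispersion(values, design.dispersion)
        else:
            means[j] = np.nan
            disps[j] = np.inf

    # argmin with ties toward the smallest pi value
    best_j = 0
    for j in range(len(results)):
        better = disps[j] < disps[best_j]
        tie = disps[j] == disps[best_j]
        if better or (tie and design.pi_grid[j] < design.pi_grid[best_j]):
            best_j = j
    return MixtureOptimizationResult(
        pi_grid=design.pi_grid,
        samples=tuple(results),
        means=means,
        dispersions=disps,
        dispersion_measure=design.dispersion,
        pi_star=design.pi_grid[best_j],
        seed=design.seed,
        n_draws=design.n_draws,
    )
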