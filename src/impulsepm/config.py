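"""Scenario configuration: schema, validation, and (de)serialization.

Configs are YAML (JSON is a subset and is accepted unchanged). The loader
is strict: unknown keys are rejected with the offending key named, nested
invariants are enforced at load time, and every defaulted field is
materialized in the echoed config so a dumped file is self-contained.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .eradication import (
    DEFAULT_EPSILON,
    DEFAULT_HORIZON,
    DEFAULT_WINDOW,
    EradicationScenario,
)
from .integrate import ImpulseEvent, ImpulseSchedule
from .model import (
    BirthPulse,
    PulseMixture,
    StagePreyParams,
    SystemParams,
    SystemState,
)
from .stochastic import MixtureDesign, PriorSpec

__all__ = ["ScenarioConfig", "ConfigError", "load_config", "dump_config"]

MODEL_FAMILIES = ("lotka_volterra_ipm", "stage_structured")

_LOTKA_KEYS = {
    "b1", "b2", "alpha", "beta", "r1", "r2", "b3", "d", "p",
    "conversion_sign_mode", "x2_growth_mode",
}
_STAGE_KEYS = {
    "death_immature", "maturation", "death_mature", "r1", "r2", "b3", "d", "p",
}


class ConfigError(ValueError):
    """A configuration file violates the schema."""


@dataclass(frozen=True)
class IntegratorOptions:
    rtol: float = 1e-8
    atol: float = 1e-10
    method: str = "RK45"
    samples_per_period: int = 4

    def __post_init__(self) -> None:
        if self.rtol <= 0 or self.atol <= 0:
            raise ConfigError("integrator.rtol and integrator.atol must be > 0")
        if self.method not in ("RK45", "DOP853", "LSODA", "Radau", "BDF"):
            raise ConfigError(f"integrator.method {self.method!r} not supported")


@dataclass(frozen=True)
class EradicationOptions:
    horizon: int = DEFAULT_HORIZON
    window: int = DEFAULT_WINDOW
    epsilon: float = DEFAULT_EPSILON

    def __post_init__(self) -> None:
        if self.horizon < 1 or self.window < 1 or self.window > self.horizon:
            raise ConfigError(
                "eradication needs 1 <= window <= horizon, got "
                f"window={self.window}, horizon={self.horizon}"
            )
        if self.epsilon <= 0:
            raise ConfigError("eradication.epsilon must be > 0")


@dataclass(frozen=True)
class ScenarioConfig:
    """Fully validated scenario: model, impulses, mixture, priors, design."""

    model: str
    params: SystemParams | StagePreyParams
    schedule: ImpulseSchedule
    initial_state: SystemState
    efficacy: float = 0.0
    mixture: PulseMixture | None = None
    integrator: IntegratorOptions = field(default_factory=IntegratorOptions)
    eradication: EradicationOptions = field(default_factory=EradicationOptions)
    kill_mature: bool = False
    kill_predator: bool = False
    priors: tuple[tuple[PriorSpec, ...], ...] = ()
    design: MixtureDesign | None = None

    def scenario(self) -> EradicationScenario:
        """The eradication-analysis view of this configuration."""
        return EradicationScenario(
            params=self.params,
            schedule=self.schedule,
            state0=self.initial_state,
            mixture=self.mixture,
            horizon=self.eradication.horizon,
            window=self.eradication.window,
            epsilon=self.eradication.epsilon,
            rtol=self.integrator.rtol,
            atol=self.integrator.atol,
            method=self.integrator.method,
            samples_per_period=self.integrator.samples_per_period,
            kill_mature=self.kill_mature,
            kill_predator=self.kill_predator,
        )


def _check_keys(mapping: dict, allowed: set[str], context: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in {context}; allowed: {sorted(allowed)}"
        )


def _require(mapping: dict, key: str, context: str):
    if key not in mapping:
        raise ConfigError(f"missing required key {key!r} in {context}")
    return mapping[key]


def _parse_prior(entry: dict, context: str) -> PriorSpec:
    _check_keys(entry, {"family", "lower", "upper", "mean", "value", "level"}, context)
    family = _require(entry, "family", context)
    try:
        return PriorSpec(
            family=family,
            lower=entry.get("lower"),
            upper=entry.get("upper"),
            mean_=entry.get("mean"),
            value=entry.get("value"),
            level=entry.get("level"),
        )
    except ValueError as exc:
        raise ConfigError(f"{context}: {exc}") from exc


def _parse_mixture(entry: dict) -> PulseMixture:
    _check_keys(entry, {"components"}, "mixture")
    comps = []
    for i, c in enumerate(_require(entry, "components", "mixture")):
        ctx = f"mixture.components[{i}]"
        _check_keys(c, {"weight", "form", "b", "q"}, ctx)
        try:
            pulse = BirthPulse(
                form=_require(c, "form", ctx),
                b=float(_require(c, "b", ctx)),
                q=None if c.get("q") is None else float(c["q"]),
            )
        except ValueError as exc:
            raise ConfigError(f"{ctx}: {exc}") from exc
        comps.append((float(_require(c, "weight", ctx)), pulse))
    try:
        return PulseMixture(tuple(comps))
    except ValueError as exc:
        raise ConfigError(f"mixture: {exc}") from exc


def config_from_dict(raw: dict) -> ScenarioConfig:
    """Validate a raw mapping into a :class:`ScenarioConfig`."""
    if not isinstance(raw, dict):
        raise ConfigError("top-level config must be a mapping")
    _check_keys(
        raw,
        {
            "model", "period", "params", "events", "efficacy", "mixture",
            "initial_state", "integrator", "eradication",
            "pesticide_side_effects", "priors", "design",
        },
        "top level",
    )
    model = _require(raw, "model", "top level")
    if model not in MODEL_FAMILIES:
        raise ConfigError(
            f"model must be one of {MODEL_FAMILIES}, got {model!r}"
        )
    period = float(_require(raw, "period", "top level"))
    efficacy = float(raw.get("efficacy", 0.0))
    if not 0.0 <= efficacy <= 1.0:
        raise ConfigError(f"efficacy must lie in [0, 1], got {efficacy!r}")

    pdict = dict(_require(raw, "params", "top level"))
    try:
        if model == "lotka_volterra_ipm":
            _check_keys(pdict, _LOTKA_KEYS, "params")
            params = SystemParams(T=period, **pdict)
        else:
            _check_keys(pdict, _STAGE_KEYS, "params")
            params = StagePreyParams(T=period, E=efficacy, **pdict)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"params: {exc}") from exc

    events = []
    for i, e in enumerate(_require(raw, "events", "top level")):
        ctx = f"events[{i}]"
        _check_keys(e, {"kind", "offset"}, ctx)
        try:
            events.append(
                ImpulseEvent(_require(e, "kind", ctx), float(e.get("offset", 0.0)))
            )
        except ValueError as exc:
            raise ConfigError(f"{ctx}: {exc}") from exc
    try:
        schedule = ImpulseSchedule(period, tuple(events))
    except ValueError as exc:
        raise ConfigError(f"events: {exc}") from exc

    st = dict(_require(raw, "initial_state", "top level"))
    _check_keys(st, {"x1", "x2", "y"}, "initial_state")
    state0 = SystemState(
        float(_require(st, "x1", "initial_state")),
        float(_require(st, "x2", "initial_state")),
        float(_require(st, "y", "initial_state")),
    )
    if min(state0) < 0:
        raise ConfigError(f"initial_state components must be >= 0, got {state0}")

    mixture = None
    if raw.get("mixture") is not None:
        mixture = _parse_mixture(raw["mixture"])

    idict = dict(raw.get("integrator", {}))
    _check_keys(idict, {"rtol", "atol", "method", "samples_per_period"}, "integrator")
    integrator = IntegratorOptions(**idict)

    edict = dict(raw.get("eradication", {}))
    _check_keys(edict, {"horizon", "window", "epsilon"}, "eradication")
    eradication = EradicationOptions(**edict)

    side = dict(raw.get("pesticide_side_effects", {}))
    _check_keys(side, {"kill_mature", "kill_predator"}, "pesticide_side_effects")

    priors: list[tuple[PriorSpec, ...]] = []
    for i, entry in enumerate(raw.get("priors", []) or []):
        ctx = f"priors[{i}]"
        if isinstance(entry, dict):
            priors.append((_parse_prior(entry, ctx),))
        else:
            priors.append(
                tuple(
                    _parse_prior(e, f"{ctx}[{j}]") for j, e in enumerate(entry)
                )
            )

    design = None
    if raw.get("design") is not None:
        ddict = dict(raw["design"])
        _check_keys(
            ddict,
            {
                "pi_grid", "n_draws", "seed", "share_draws", "dispersion",
                "include_nonconverged",
            },
            "design",
        )
        try:
            design = MixtureDesign(
                pi_grid=tuple(_require(ddict, "pi_grid", "design")),
                n_draws=int(_require(ddict, "n_draws", "design")),
                seed=int(_require(ddict, "seed", "design")),
                share_draws=bool(ddict.get("share_draws", True)),
                dispersion=ddict.get("dispersion", "variance"),
                include_nonconverged=bool(ddict.get("include_nonconverged", True)),
            )
        except ValueError as exc:
            raise ConfigError(f"design: {exc}") from exc

    return ScenarioConfig(
        model=model,
        params=params,
        schedule=schedule,
        initial_state=state0,
        efficacy=efficacy,
        mixture=mixture,
        integrator=integrator,
        eradication=eradication,
        kill_mature=bool(side.get("kill_mature", False)),
        kill_predator=bool(side.get("kill_predator", False)),
        priors=tuple(priors),
        design=design,
    )


def config_to_dict(cfg: ScenarioConfig) -> dict:
    """Echo a config as a plain mapping with every default materialized."""
    if isinstance(cfg.params, SystemParams):
        pdict = {k: getattr(cfg.params, k) for k in sorted(_LOTKA_KEYS)}
    else:
        pdict = {k: getattr(cfg.params, k) for k in sorted(_STAGE_KEYS)}
    out: dict = {
        "model": cfg.model,
        "period": cfg.schedule.period,
        "params": pdict,
        "events": [
            {"kind": ev.kind, "offset": ev.offset} for ev in cfg.schedule.events
        ],
        "efficacy": cfg.efficacy,
        "initial_state": {
            "x1": cfg.initial_state.x1,
            "x2": cfg.initial_state.x2,
            "y": cfg.initial_state.y,
        },
        "mixture": None,
        "integrator": asdict(cfg.integrator),
        "eradication": asdict(cfg.eradication),
        "pesticide_side_effects": {
            "kill_mature": cfg.kill_mature,
            "kill_predator": cfg.kill_predator,
        },
        "priors": [],
        "design": None,
    }
    if cfg.mixture is not None:
        out["mixture"] = {
            "components": [
                {"weight": w, "form": p.form, "b": p.b, "q": p.q}
                for w, p in cfg.mixture.components
            ]
        }
    for group in cfg.priors:
        entries = [
            {
                "family": pr.family,
                "lower": pr.lower,
                "upper": pr.upper,
                "mean": pr.mean_,
                "value": pr.value,
                "level": pr.level,
            }
            for pr in group
        ]
        out["priors"].append(entries[0] if len(entries) == 1 else entries)
    if cfg.design is not None:
        out["design"] = {
            "pi_grid": list(cfg.design.pi_grid),
            "n_draws": cfg.design.n_draws,
            "seed": cfg.design.seed,
            "share_draws": cfg.design.share_draws,
            "dispersion": cfg.design.dispersion,
            "include_nonconverged": cfg.design.include_nonconverged,
        }
    return out


def load_config(path: str | Path) -> ScenarioConfig:
    """Load and validate a YAML or JSON scenario file."""
    text = Path(path).read_text()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: not valid YAML/JSON: {exc}") from exc
    return config_from_dict(raw)


def dump_config(cfg: ScenarioConfig, path: str | Path | None = None) -> str:
    """Serialize a config to YAML; optionally write it to ``path``."""
    text = yaml.safe_dump(config_to_dict(cfg), sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def config_hash(cfg: ScenarioConfig) -> str:
    """Stable hash of the effective configuration (for run logs)."""
    import hashlib

    blob = json.dumps(config_to_dict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
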