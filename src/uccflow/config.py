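"""Scenario configuration for the urgent-care-center flow model.

A scenario fixes everything one simulated opening period needs: staffing
counts for the four roles (triage nurse, doctor, examination/treatment
nurse, discharge administrator), exponential service means in minutes,
the per-patient time saving attributed to a digital symptom/history-taking
app at the triage and consultation stages, the two routing probabilities
of the patient trajectory, the Poisson arrival intensity, the opening
horizon and the Monte-Carlo replication plan.

The canonical what-if study is a grid of 33 scenarios: the baseline
staffing, two extra-staff variants, and the 6 x 5 combinations of app
time savings at triage (2.5-5 min) and consultation (1.5-3.5 min).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd
import yaml

__all__ = [
    "ConfigError",
    "ScenarioConfig",
    "TRIAGE_SAVINGS",
    "CONSULT_SAVINGS",
    "baseline_config",
    "build_scenarios",
    "validate_config",
    "load_config",
    "scenarios_to_csv",
]

#: App time savings (minutes) modeled at the triage stage.
TRIAGE_SAVINGS: tuple[float, ...] = (2.5, 3.0, 3.5, 4.0, 4.5, 5.0)
#: App time savings (minutes) modeled at the consultation stage.
CONSULT_SAVINGS: tuple[float, ...] = (1.5, 2.0, 2.5, 3.0, 3.5)


class ConfigError(ValueError):
    """A scenario configuration violates an invariant."""


@dataclass(frozen=True)
class ScenarioConfig:
    """Full parameterization of one what-if scenario.

    Defaults are the baseline urgent care center: 2 triage nurses,
    2 doctors, 1 examination/treatment nurse, 1 discharge administrator;
    mean interaction times 15/20/15/5 minutes; Poisson arrivals at 0.2
    patients per minute over a 240-minute (4-hour) opening window;
    5000 replications.

    ``p_exam`` is the probability that a doctor sends the patient to the
    examination/treatment room (rather than straight to discharge);
    ``p_return`` the probability that examination/treatment sends the
    patient back to a doctor (rather than to discharge).
    """

    name: str = "baseline"
    n_triage: int = 2
    n_doctor: int = 2
    n_exam: int = 1
    n_admin: int = 1
    mean_triage: float = 15.0
    mean_doctor: float = 20.0
    mean_exam: float = 15.0
    mean_admin: float = 5.0
    triage_saving: float = 0.0
    consult_saving: float = 0.0
    p_exam: float = 0.4
    p_return: float = 0.2
    arrival_rate: float = 0.2
    horizon: float = 240.0
    n_reps: int = 5000
    base_seed: int = 20210521

    @property
    def eff_mean_triage(self) -> float:
        """Triage service mean after the app's time saving, minutes."""
        return self.mean_triage - self.triage_saving

    @property
    def eff_mean_doctor(self) -> float:
        """Consultation service mean after the app's time saving, minutes."""
        return self.mean_doctor - self.consult_saving

    def with_(self, **changes) -> "ScenarioConfig":
        """Return a validated copy with the given fields replaced."""
        return validate_config(replace(self, **changes))


def baseline_config(**overrides) -> ScenarioConfig:
    """The baseline scenario; keyword overrides are applied and validated."""
    return validate_config(replace(ScenarioConfig(), **overrides))


def validate_config(cfg: ScenarioConfig) -> ScenarioConfig:
    """Check every invariant; return ``cfg`` unchanged if all hold.

    Raises
    ------
    ConfigError
        Naming the violated invariant.
    """
    for role in ("n_triage", "n_doctor", "n_exam", "n_admin"):
        if getattr(cfg, role) < 1:
            raise ConfigError(f"server count {role} must be >= 1, got {getattr(cfg, role)}")
    for label, value in (
        ("triage", cfg.eff_mean_triage),
        ("doctor", cfg.eff_mean_doctor),
        ("exam", cfg.mean_exam),
        ("admin", cfg.mean_admin),
    ):
        if not value > 0:
            raise ConfigError(
                f"effective service mean must be positive ({label} stage: {value} min)"
            )
    for label, p in (("p_exam", cfg.p_exam), ("p_return", cfg.p_return)):
        if not 0.0 <= p <= 1.0:
            raise ConfigError(f"probability out of range: {label}={p}")
    if not cfg.arrival_rate > 0:
        raise ConfigError(f"arrival_rate must be positive, got {cfg.arrival_rate}")
    if not cfg.horizon > 0:
        raise ConfigError(f"horizon must be positive, got {cfg.horizon}")
    if cfg.n_reps < 1:
        raise ConfigError(f"n_reps must be >= 1, got {cfg.n_reps}")
    if cfg.base_seed < 0:
        raise ConfigError(f"base_seed must be non-negative, got {cfg.base_seed}")
    return cfg


def build_scenarios() -> list[ScenarioConfig]:
    """Enumerate the 33-scenario what-if grid.

    Returns, in order: the baseline; baseline plus one triage nurse;
    baseline plus one triage nurse and one doctor; then the 30 app
    scenarios combining each triage saving with each consultation saving.
    All other fields equal the baseline.
    """
    base = baseline_config()
    out = [
        base,
        base.with_(name="baseline+nurse", n_triage=3),
        base.with_(name="baseline+nurse+doctor", n_triage=3, n_doctor=3),
    ]
    for ts in TRIAGE_SAVINGS:
        for cs in CONSULT_SAVINGS:
            out.append(
                base.with_(
                    name=f"app_t{ts:g}_c{cs:g}",
                    triage_saving=ts,
                    consult_saving=cs,
                )
            )
    return out


_FIELD_NAMES = tuple(f.name for f in dataclasses.fields(ScenarioConfig))


def load_config(path: str | Path) -> ScenarioConfig:
    """Read a scenario from a YAML or JSON file.

    Keys must match :class:`ScenarioConfig` field names exactly; unknown
    keys are an error. Missing keys take baseline defaults.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    unknown = sorted(set(raw) - set(_FIELD_NAMES))
    if unknown:
        raise ConfigError(f"unknown config keys: {', '.join(unknown)}")
    return baseline_config(**raw)


def scenarios_to_csv(scenarios: list[ScenarioConfig], path: str | Path) -> None:
    """Emit the scenario grid as CSV, one row per scenario, for audit."""
    df = pd.DataFrame([dataclasses.asdict(s) for s in scenarios])
    df.to_csv(path, index=False)
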