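"""Layered run configuration: one YAML file per run, strict validation,
and a full echo of effective values for provenance."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .engine import SimConfig
from .protocols import ModelConfig
from .synapses import DISTRIBUTION_MODELS


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one protocol run."""
    morphology: str | None = None        # SWC path; None = synthetic default
    protocol: str = "tuning"
    distribution: str = "biologically_plausible"
    n_total: int = 7200
    bg_fraction: float = 0.75
    inhibitory_bg_fraction: float = 0.2
    pref_sigma: float = 30.0
    rate_stim_peak: float = 0.3
    rate_background: float = 0.11
    tuning_sigma_rate: float = 30.0
    dt: float = 0.1
    duration: float = 2500.0
    stimulus_onset: float = 500.0
    orientations: tuple[float, ...] = tuple(float(o) for o in range(0, 180, 10))
    disparities: tuple[float, ...] = tuple(float(d) for d in range(0, 100, 10))
    n_trials: int = 10
    seed: int = 0
    out_dir: str = "results"
    protocol_params: dict = field(default_factory=dict)

    def sim_config(self) -> SimConfig:
        return SimConfig(dt=self.dt, duration=self.duration,
                         stimulus_onset=self.stimulus_onset)

    def model_config(self) -> ModelConfig:
        return ModelConfig(
            distribution=self.distribution, n_total=self.n_total,
            bg_fraction=self.bg_fraction,
            inhibitory_bg_fraction=self.inhibitory_bg_fraction,
            pref_sigma=self.pref_sigma,
            rate_stim_peak=self.rate_stim_peak,
            rate_background=self.rate_background,
            tuning_sigma_rate=self.tuning_sigma_rate)

    def echo(self) -> dict:
        d = asdict(self)
        d["orientations"] = list(self.orientations)
        d["disparities"] = list(self.disparities)
        return d


_VALID_PROTOCOLS = ("run", "i3p", "tuning", "disparity", "intervene",
                    "attenuate", "ablate", "sensitivity")


def parse_config(path: str | Path, overrides: dict | None = None) -> RunConfig:
    """Read and validate a YAML run configuration.

    Unknown keys are rejected with the offending key named; defaults fill
    every omitted field. `overrides` (e.g. CLI flags) take precedence.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    if overrides:
        raw.update({k: v for k, v in overrides.items() if v is not None})
    return config_from_dict(raw, source=str(path))


def config_from_dict(raw: dict, source: str = "<dict>") -> RunConfig:
    known = set(RunConfig.__dataclass_fields__)
    for key in raw:
        if key not in known:
            raise ConfigError(f"{source}: unknown key {key!r}")
    for tup_key in ("orientations", "disparities"):
        if tup_key in raw:
            raw[tup_key] = tuple(float(x) for x in raw[tup_key])
    cfg = RunConfig(**raw)
    _validate(cfg, source)
    return cfg


def _validate(cfg: RunConfig, source: str) -> None:
    if cfg.protocol not in _VALID_PROTOCOLS:
        raise ConfigError(f"{source}: protocol must be one of "
                          f"{_VALID_PROTOCOLS}, got {cfg.protocol!r}")
    if cfg.distribution not in DISTRIBUTION_MODELS:
        raise ConfigError(f"{source}: distribution: unknown model "
                          f"{cfg.distribution!r}")
    if cfg.dt <= 0:
        raise ConfigError(f"{source}: dt must be positive")
    if cfg.duration < cfg.stimulus_onset:
        raise ConfigError(f"{source}: duration must cover stimulus_onset")
    if cfg.n_total < 1:
        raise ConfigError(f"{source}: n_total must be >= 1")
    if not (0.0 <= cfg.bg_fraction <= 1.0):
        raise ConfigError(f"{source}: bg_fraction must be in [0, 1]")
    if cfg.n_trials < 1:
        raise ConfigError(f"{source}: n_trials must be >= 1")


def write_echo(cfg: RunConfig, out_dir: str | Path) -> Path:
    """Write the effective configuration next to the results."""
    from . import __version__
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = {"dendrosynergy_version": __version__, **cfg.echo()}
    p = out / "config_echo.yaml"
    p.write_text(yaml.safe_dump(payload, sort_keys=False))
    return p
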