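"""Run configuration: defaults, YAML loading, exhaustive validation."""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import yaml

from .errors import ConfigError
from .synth import AcquisitionSchedule, GeneratorConfig

__all__ = ["RunConfig", "validate_config"]


@dataclass(frozen=True)
class RunConfig:
    """Everything a full pipeline run needs; all stages draw their settings
    (and their seeds) from here so a run is reproducible from one object."""

    n_lambs: int = 40
    master_seed: int = 0
    output_dir: str = "greylung_run"
    # schedule
    inflation_pressures: tuple[float, ...] = (0, 5, 10, 15, 20, 25, 30, 35)
    deflation_pressures: tuple[float, ...] = (30, 25, 20, 15, 10)
    # ROI settings
    depth_mm: float = 1.0
    shadow_threshold_frac: float = 0.35
    search_band: tuple[int, int] | None = None
    # fit settings
    grid_step: float = 0.1
    n_starts: int = 5
    # stats settings
    ci_method: str = "bootstrap"
    n_boot: int = 2000
    alpha: float = 0.05
    bonferroni_m: int | None = None
    # observers
    observer_sigma: float = 2.0  # AU of extra measurement noise for observer B
    # generator settings (nested; overridable via flat gen_* keys in YAML)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)

    def schedule(self) -> AcquisitionSchedule:
        return AcquisitionSchedule(tuple(self.inflation_pressures),
                                   tuple(self.deflation_pressures))

    def violations(self) -> list[str]:
        """Every contract violation, not just the first."""
        problems: list[str] = []
        if self.n_lambs < 1:
            problems.append("n_lambs must be >= 1")
        if self.master_seed < 0:
            problems.append("master_seed must be >= 0")
        if self.depth_mm <= 0:
            problems.append("depth_mm must be > 0")
        if not 0 < self.shadow_threshold_frac < 1:
            problems.append("shadow_threshold_frac must lie in (0, 1)")
        if self.grid_step <= 0:
            problems.append("grid_step must be > 0")
        if self.n_starts < 1:
            problems.append("n_starts must be >= 1")
        if self.ci_method not in ("bootstrap", "fisher"):
            problems.append("ci_method must be 'bootstrap' or 'fisher'")
        if self.n_boot < 10:
            problems.append("n_boot must be >= 10")
        if not 0 < self.alpha < 1:
            problems.append("alpha must lie in (0, 1)")
        if self.bonferroni_m is not None and self.bonferroni_m < 1:
            problems.append("bonferroni_m must be >= 1 when given")
        if self.observer_sigma < 0:
            problems.append("observer_sigma must be >= 0")
        try:
            self.schedule()
        except Exception as exc:  # noqa: BLE001 - report, do not raise yet
            problems.append(f"schedule invalid: {exc}")
        try:
            self.generator.validate()
        except ConfigError as exc:
            problems.extend(f"generator: {v}" for v in exc.violations)
        return problems

    def validated(self) -> "RunConfig":
        problems = self.violations()
        if problems:
            raise ConfigError(problems)
        return self


_TUPLE_KEYS = {"inflation_pressures", "deflation_pressures", "search_band"}


def validate_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a fully-defaulted :class:`RunConfig` from a YAML mapping.

    An empty (or absent) file yields pure defaults. Unknown keys and every
    contract violation are reported together in one :class:`ConfigError`.
    Generator settings are addressed with a ``gen_`` prefix, e.g.
    ``gen_noise_sigma_range: [0, 0]``.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        try:
            loaded = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ConfigError([f"unparseable config: {exc}"]) from exc
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(["config must be a key-value mapping"])
        data = loaded
    data.update(overrides)

    run_fields = {f.name for f in fields(RunConfig)} - {"generator"}
    gen_fields = {f.name for f in fields(GeneratorConfig)}
    problems: list[str] = []
    run_kwargs: dict = {}
    gen_kwargs: dict = {}
    for key, value in data.items():
        if key in run_fields:
            if key in _TUPLE_KEYS and value is not None:
                value = tuple(value)
            run_kwargs[key] = value
        elif key.startswith("gen_") and key[4:] in gen_fields:
            if isinstance(value, list):
                value = tuple(value)
            gen_kwargs[key[4:]] = value
        else:
            problems.append(f"unknown config key {key!r}")

    try:
        cfg = RunConfig(**run_kwargs)
        if gen_kwargs:
            cfg = replace(cfg, generator=replace(cfg.generator, **gen_kwargs))
    except (TypeError, ValueError) as exc:
        raise ConfigError(problems + [f"bad config value: {exc}"]) from exc

    problems.extend(cfg.violations())
    if problems:
        raise ConfigError(problems)
    return cfg
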