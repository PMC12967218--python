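"""Pipeline configuration.

One YAML file drives every subcommand: input paths, the ledger path,
all module thresholds, the seed, and which steps ``run-all`` executes.
Unknown keys are rejected (they are almost always typos of a
threshold name); every threshold has a documented default, so an empty
file is a valid configuration.  Command-line flags override file
values, file values override defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, is_dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml

from .filter_clusters import SubclusterConfig
from .filter_metrics import MetricThresholds
from .pedigree import PedigreeConfig
from .ploidy import PloidyConfig
from .synthetic import SimulationConfig


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class InputConfig:
    genotypes: str | None = None
    reference_genotypes: str | None = None
    reference_pedigree: str | None = None


@dataclass(frozen=True)
class FiltermConfig:
    midpoint_limit: float = 1.5
    min_fld: float | None = 3.6
    min_hom_fld: float | None = 6.5
    min_het_so: float | None = -0.1
    min_hom_ro: dict | None = field(
        default_factory=lambda: {1: 0.6, 2: 0.3, 3: -0.9}
    )
    max_cluster_variance: float | None = None
    max_abs_variance_zscore: float | None = 2.0

    def thresholds(self) -> MetricThresholds:
        hom_ro = (
            {int(k): float(v) for k, v in self.min_hom_ro.items()}
            if self.min_hom_ro is not None
            else None
        )
        return MetricThresholds(
            min_fld=self.min_fld,
            min_hom_fld=self.min_hom_fld,
            min_het_so=self.min_het_so,
            min_hom_ro=hom_ro,
            max_cluster_variance=self.max_cluster_variance,
            max_abs_variance_zscore=self.max_abs_variance_zscore,
        )


@dataclass(frozen=True)
class ExportConfig:
    prefix: str = "curated"
    format: str = "tped"  # tped | tabular

    def __post_init__(self) -> None:
        if self.format not in ("tped", "tabular"):
            raise ConfigError(f"unknown export format {self.format!r}")


@dataclass(frozen=True)
class StepsConfig:
    """Which steps ``run-all`` executes (any step can be skipped)."""

    ploidy: bool = True
    filterm: bool = True
    filterc: bool = True
    duos: bool = True
    trios: bool = True
    filterp: bool = True


@dataclass(frozen=True)
class PipelineConfig:
    input: InputConfig = field(default_factory=InputConfig)
    ledger: str = "curation_ledger.json"
    output_dir: str = "axiomcurate_out"
    seed: int = 17
    log_level: str = "INFO"
    ploidy: PloidyConfig = field(default_factory=PloidyConfig)
    filterm: FiltermConfig = field(default_factory=FiltermConfig)
    filterc: SubclusterConfig = field(default_factory=SubclusterConfig)
    pedigree: PedigreeConfig = field(default_factory=PedigreeConfig)
    export: ExportConfig = field(default_factory=ExportConfig)
    steps: StepsConfig = field(default_factory=StepsConfig)
    simulate: SimulationConfig = field(default_factory=SimulationConfig)


def _build(cls: type, data: Mapping[str, Any], path: str) -> Any:
    if not isinstance(data, Mapping):
        raise ConfigError(f"{path or 'top level'}: expected a mapping")
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ConfigError(
            f"{path or 'top level'}: unknown key(s) {sorted(unknown)}; "
            f"valid keys: {sorted(known)}"
        )
    kwargs: dict[str, Any] = {}
    for name, value in data.items():
        f = known[name]
        # nested dataclass sections are declared via default_factory
        factory = f.default_factory
        nested = None
        if callable(factory):
            candidate = factory()
            if is_dataclass(candidate):
                nested = type(candidate)
        if nested is not None and isinstance(value, Mapping):
            kwargs[name] = _build(nested, value, f"{path}{name}.")
        else:
            kwargs[name] = tuple(value) if isinstance(value, list) else value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path or 'top level'}: {exc}") from exc


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML configuration file; a missing path gives defaults."""
    if path is None:
        return PipelineConfig()
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file {path} does not exist")
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return _build(PipelineConfig, data, "")


def default_config_yaml() -> str:
    """Render the full default configuration as commented YAML."""

    def as_dict(obj: Any) -> Any:
        if is_dataclass(obj):
            return {f.name: as_dict(getattr(obj, f.name)) for f in fields(obj)}
        if isinstance(obj, tuple):
            return list(obj)
        return obj

    return yaml.safe_dump(as_dict(PipelineConfig()), sort_keys=False)
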