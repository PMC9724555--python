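"""Pipeline configuration: a versioned YAML schema with the benchmark
protocol's defaults baked in, so a near-empty config reproduces the
standard protocol shape (5,000 bp tree sampling, 1 cM truth minimum,
50% coverage threshold, [2..7,inf) cM bins, 2 cM coverage cutoff,
window 5 downsampling)."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, Optional

import yaml

from .core import ConfigError, MetricConfig
from .panelops import DownsampleConfig, ErrorSpec
from .summaries import RelatednessConfig
from .truth import TruthConfig

__all__ = ["PipelineConfig", "SimulateConfig", "load_config"]

SCHEMA_VERSION = 1


@dataclass
class SimulateConfig:
    n_haplotypes: int = 200
    region_bp: int = 10_000_000
    mean_segment_bp: float = 1_000_000
    n_sites: int = 5000
    cm_per_mb: float = 1.0
    # pseudo-caller perturbation
    boundary_jitter_cm: float = 0.1
    fragmentation_prob: float = 0.2
    gap_cm: float = 0.5
    false_positive_rate: float = 0.05
    drop_rate: float = 0.05

    def __post_init__(self) -> None:
        if self.n_haplotypes < 4 or self.n_haplotypes % 2:
            raise ConfigError(
                f"simulate.n_haplotypes: must be even and >= 4, got {self.n_haplotypes}"
            )
        if self.region_bp < 1:
            raise ConfigError(f"simulate.region_bp: must be >= 1, got {self.region_bp}")


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs; see the YAML schema in the docs."""

    outdir: Path = Path("ibdbench_out")
    seed: int = 0
    panel: Optional[Path] = None
    genetic_map: Optional[Path] = None
    map_dialect: str = "plink"
    track: Optional[Path] = None
    calls: Optional[Path] = None
    calls_dialect: str = "truth"
    truth_file: Optional[Path] = None
    plots: bool = False

    truth: TruthConfig = field(default_factory=TruthConfig)
    downsample: DownsampleConfig = field(default_factory=DownsampleConfig)
    error_rate: float = 0.001
    metrics: MetricConfig = field(default_factory=MetricConfig)
    reference: str = "full"
    coverage_min_length_cm: float = 2.0
    genome_length_cm: Optional[float] = None
    max_degree: int = 4
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    _frozen_hash: Optional[str] = field(default=None, repr=False, compare=False)

    def freeze_hash(self) -> None:
        self._frozen_hash = None
        self._frozen_hash = self.config_hash()

    def config_hash(self) -> str:
        """Stable short hash identifying this configuration + seed.

        The output directory is excluded: it does not affect what is
        computed, and two runs of one config into different directories
        must produce identically stamped artifacts. Once frozen by
        :func:`load_config` the hash reflects the configuration as
        loaded, not paths a pipeline stage fills in while running.
        """
        if self._frozen_hash is not None:
            return self._frozen_hash
        payload = self.to_dict()
        payload.pop("outdir", None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    def to_dict(self) -> Dict[str, Any]:
        return {
            "schema_version": SCHEMA_VERSION,
            "outdir": str(self.outdir),
            "seed": self.seed,
            "panel": str(self.panel) if self.panel else None,
            "genetic_map": str(self.genetic_map) if self.genetic_map else None,
            "map_dialect": self.map_dialect,
            "track": str(self.track) if self.track else None,
            "calls": str(self.calls) if self.calls else None,
            "calls_dialect": self.calls_dialect,
            "truth_file": str(self.truth_file) if self.truth_file else None,
            "plots": self.plots,
            "truth": vars(self.truth),
            "downsample": vars(self.downsample),
            "error_rate": self.error_rate,
            "metrics": {
                "coverage_threshold": self.metrics.coverage_threshold,
                "bin_edges_cm": list(self.metrics.bin_edges_cm),
                "pair_mode": self.metrics.pair_mode,
            },
            "reference": self.reference,
            "coverage_min_length_cm": self.coverage_min_length_cm,
            "genome_length_cm": self.genome_length_cm,
            "max_degree": self.max_degree,
            "simulate": vars(self.simulate),
        }


def _take(section: Dict[str, Any], name: str, cls, path: str):
    """Build a dataclass from a config section, naming bad fields."""
    if not isinstance(section, dict):
        raise ConfigError(f"{path}: expected a mapping")
    allowed = set(cls.__dataclass_fields__)
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"{path}.{sorted(unknown)[0]}: unknown field")
    try:
        return cls(**section)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def load_config(path=None, overrides: Optional[Dict[str, Any]] = None) -> PipelineConfig:
    """Load YAML config (all keys optional) and apply CLI overrides."""
    raw: Dict[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ConfigError(f"{path}: top level must be a mapping")
            raw = loaded
    if overrides:
        raw.update({k: v for k, v in overrides.items() if v is not None})
    version = raw.pop("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ConfigError(f"schema_version: unsupported version {version}")

    cfg = PipelineConfig()
    simple_paths = ("panel", "genetic_map", "track", "calls", "truth_file", "outdir")
    for key in list(raw):
        val = raw[key]
        if key in simple_paths:
            setattr(cfg, key, Path(val) if val is not None else None)
        elif key in ("map_dialect", "calls_dialect", "reference"):
            setattr(cfg, key, str(val))
        elif key == "seed":
            cfg.seed = int(val)
        elif key == "plots":
            cfg.plots = bool(val)
        elif key == "error_rate":
            cfg.error_rate = float(val)
        elif key == "coverage_min_length_cm":
            cfg.coverage_min_length_cm = float(val)
        elif key == "genome_length_cm":
            cfg.genome_length_cm = float(val) if val is not None else None
        elif key == "max_degree":
            cfg.max_degree = int(val)
        elif key == "truth":
            cfg.truth = _take(val, key, TruthConfig, "truth")
        elif key == "downsample":
            cfg.downsample = _take(val, key, DownsampleConfig, "downsample")
        elif key == "metrics":
            try:
                cfg.metrics = MetricConfig(**{
                    k: (tuple(v) if k == "bin_edges_cm" else v) for k, v in val.items()
                })
            except TypeError as exc:
                raise ConfigError(f"metrics: {exc}") from exc
        elif key == "simulate":
            cfg.simulate = _take(val, key, SimulateConfig, "simulate")
        else:
            raise ConfigError(f"{key}: unknown configuration field")
    if cfg.reference not in ("full", "binned"):
        raise ConfigError(f"reference: must be 'full' or 'binned', got {cfg.reference!r}")
    if not (0.0 <= cfg.error_rate <= 1.0):
        raise ConfigError(f"error_rate: must be in [0, 1], got {cfg.error_rate}")
    cfg.freeze_hash()
    return cfg
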