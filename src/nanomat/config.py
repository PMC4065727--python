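"""Analysis and pipeline configuration.

Plain dataclasses with YAML/TOML loading; a stable hash of the fully
resolved configuration is stamped into every output file header so reruns
can be matched to their settings.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

__all__ = ["AnalysisConfig", "StatsConfig", "SimulationConfig", "PipelineConfig"]


def _from_mapping(cls, data: Mapping[str, Any]):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(data) - names)
    if unknown:
        raise ValueError(f"{cls.__name__}: unknown fields {unknown}")
    return cls(**data)


@dataclass(frozen=True)
class AnalysisConfig:
    """Settings for the single-field structural analysis."""

    n_layers: int = 7
    #: projection mask (overall porosity, pore sizing): inclusive
    #: background-vs-fiber cut; "li" | "otsu" | "fixed"
    binarization: str = "li"
    #: surface-fiber mask (fiber-width measurements): bright in-focus fibers
    fiber_binarization: str = "otsu"
    fixed_level: int | None = None
    invert: bool = False
    min_pore_area: int = 5
    border_policy: str = "exclude"  # censored pores at the frame edge
    nm_per_pixel: float | None = None
    fiber_samples: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_layers < 2:
            raise ValueError("n_layers must be >= 2")
        for name in (self.binarization, self.fiber_binarization):
            if name not in {"li", "otsu", "fixed"}:
                raise ValueError(f"unknown binarization {name!r}")
            if name == "fixed" and self.fixed_level is None:
                raise ValueError("fixed binarization requires fixed_level")


@dataclass(frozen=True)
class StatsConfig:
    alpha: float = 0.001
    t_test: str = "correlation"  # "correlation" | "pooled"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass(frozen=True)
class SimulationConfig:
    """Optional synthetic-study settings for the pipeline.

    ``mat`` holds MatSpec overrides shared by all samples; per-sample
    seeds/coverages are derived from the master seed.  ``coefficients``
    drives the viability generator; when empty, no viability table is
    produced.
    """

    n_samples: int = 11
    mat: dict = field(default_factory=dict)
    coefficients: dict = field(
        default_factory=lambda: {"fiber_mean": 4.0, "pore_mean": 4.0, "P": -4.0, "SPE": -4.0}
    )
    noise_sd: float = 0.01
    control_mean: float = 0.5
    intercept: float = 80.0
    #: samples sweep fine -> coarse mats along the electrospinning trend:
    #: fiber diameter rises with packing (coverage), so porosity falls
    coverage_range: tuple[float, float] = (0.55, 0.8)
    diameter_range: tuple[float, float] = (5.0, 12.0)


@dataclass(frozen=True)
class PipelineConfig:
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    simulation: SimulationConfig | None = None
    #: mapping sample_id -> list of image paths (multiple fields per sample)
    samples: dict = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_mapping(cls, data: Mapping[str, Any]) -> "PipelineConfig":
        data = dict(data)
        unknown = sorted(set(data) - {"analysis", "stats", "simulation", "samples", "seed"})
        if unknown:
            raise ValueError(f"PipelineConfig: unknown fields {unknown}")
        analysis = _from_mapping(AnalysisConfig, data.get("analysis", {}))
        stats = _from_mapping(StatsConfig, data.get("stats", {}))
        sim = data.get("simulation")
        simulation = _from_mapping(SimulationConfig, sim) if sim is not None else None
        samples = {str(k): [str(p) for p in v] for k, v in data.get("samples", {}).items()}
        return cls(
            analysis=analysis,
            stats=stats,
            simulation=simulation,
            samples=samples,
            seed=int(data.get("seed", 0)),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".toml":
            import tomllib

            data = tomllib.loads(text)
        else:
            import yaml

            data = yaml.safe_load(text) or {}
        try:
            return cls.from_mapping(data)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"invalid config {path}: {exc}") from exc

    def config_hash(self) -> str:
        """Stable 12-hex-digit digest of the resolved configuration."""
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
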