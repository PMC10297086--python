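"""Run configuration: TOML loading, validation and defaults.

All defaults reproduce the clinical configuration: 4.5° receiver step,
doublet transmitters at {0, 72, 144, 216, 288}° ± 4.5°, 1–9 GHz sweep,
sigma = 0.3 S/m conductivity weighting, 9° rotation subtraction, the
five-feature median-calibrated rule with min_positives = 5, ~50% lesion
prevalence and 15 calibration subjects per site.  Unknown keys are
rejected with their key path.
"""

from __future__ import annotations

import tomllib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

from .acquisition import AcquisitionGeometry, make_geometry
from .classifier import DEFAULT_SELECTED_FEATURES, SelectedFeatureSet
from .phantom import PhantomParameters
from .reconstruction import ImageGrid, MediumParameters
from .study_stats import DesignParameters

__all__ = ["RunConfig", "ConfigError", "load_config", "dump_toml"]


class ConfigError(ValueError):
    """Raised for unknown keys, type mismatches or constraint violations."""


@dataclass
class GeometryConfig:
    rx_step_deg: float = 4.5
    section_centres_deg: list[float] = field(default_factory=lambda: [0.0, 72.0, 144.0, 216.0, 288.0])
    doublet_offset_deg: float = 9.0
    antenna_radius_m: float = 0.10
    f_min_hz: float = 1e9
    f_max_hz: float = 9e9
    n_freq: int = 81


@dataclass
class MediumConfig:
    sigma: float = 0.3
    epsilon_r: float = 1.0


@dataclass
class ReconstructionConfig:
    grid_size: int = 64
    delta_deg: float = 9.0


@dataclass
class ClassifierConfig:
    selected_features: list[str] = field(default_factory=lambda: list(DEFAULT_SELECTED_FEATURES))
    min_positives: int = 5


@dataclass
class SimulationConfig:
    n_subjects: int = 90
    prevalence: float = 0.5
    density_weights: dict[str, float] = field(
        default_factory=lambda: {"A": 0.1, "B": 0.4, "C": 0.4, "D": 0.1}
    )
    n_calibration_per_site: int = 15
    sites: list[str] = field(default_factory=lambda: ["site1", "site2", "site3"])
    breast_radius_m: float = 0.06
    lesion_amplitude: list[float] = field(default_factory=lambda: [1.0, 2.0])
    noise_sigma: float = 0.0
    seed: int = 0


@dataclass
class StatsConfig:
    alpha: float = 0.05
    sided: str = "one"
    ci_method: str = "beta"


@dataclass
class RunConfig:
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    medium: MediumConfig = field(default_factory=MediumConfig)
    reconstruction: ReconstructionConfig = field(default_factory=ReconstructionConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)

    # -- conversions to domain objects -------------------------------------

    def make_geometry(self) -> AcquisitionGeometry:
        g = self.geometry
        return make_geometry(
            rx_step=g.rx_step_deg,
            section_centres=tuple(g.section_centres_deg),
            doublet_offset=g.doublet_offset_deg,
            antenna_radius=g.antenna_radius_m,
            n_freq=g.n_freq,
            f_min=g.f_min_hz,
            f_max=g.f_max_hz,
        )

    def make_medium(self) -> MediumParameters:
        return MediumParameters(
            relative_permittivity=self.medium.epsilon_r, conductivity=self.medium.sigma
        )

    def make_grid(self) -> ImageGrid:
        return ImageGrid(
            half_extent=self.simulation.breast_radius_m,
            n_pixels_per_side=self.reconstruction.grid_size,
        )

    def make_selected(self) -> SelectedFeatureSet:
        return SelectedFeatureSet(
            features=tuple(self.classifier.selected_features),
            min_positives=self.classifier.min_positives,
        )

    def make_phantom_params(self) -> PhantomParameters:
        return PhantomParameters(
            breast_radius=self.simulation.breast_radius_m,
            lesion_amplitude_range=tuple(self.simulation.lesion_amplitude),
        )

    def make_design(self) -> DesignParameters:
        return DesignParameters(
            alpha=self.stats.alpha, sided=self.stats.sided, prevalence=self.simulation.prevalence
        )


_CONSTRAINTS = {
    "geometry.rx_step_deg": lambda v: v > 0,
    "geometry.antenna_radius_m": lambda v: v > 0,
    "geometry.n_freq": lambda v: v >= 2,
    "medium.sigma": lambda v: v >= 0,
    "medium.epsilon_r": lambda v: v >= 1,
    "reconstruction.grid_size": lambda v: v >= 2,
    "reconstruction.delta_deg": lambda v: v > 0,
    "classifier.min_positives": lambda v: v >= 1,
    "simulation.prevalence": lambda v: 0 <= v <= 1,
    "simulation.n_calibration_per_site": lambda v: v >= 0,
    "simulation.noise_sigma": lambda v: v >= 0,
    "stats.alpha": lambda v: 0 < v < 1,
    "stats.sided": lambda v: v in ("one", "two"),
    "stats.ci_method": lambda v: v in ("beta", "wilson"),
}


def _apply_block(block_obj, data: dict, path: str):
    known = {f.name: f for f in fields(block_obj)}
    for key, value in data.items():
        if key not in known:
            raise ConfigError(f"unknown key {path}.{key}")
        default = getattr(block_obj, key)
        if isinstance(default, bool) is not isinstance(value, bool) or (
            not isinstance(value, type(default))
            and not (isinstance(default, float) and isinstance(value, int))
        ):
            raise ConfigError(
                f"type mismatch at {path}.{key}: expected {type(default).__name__}, "
                f"got {type(value).__name__}"
            )
        setattr(block_obj, key, type(default)(value) if isinstance(default, float) else value)


def _validate(config: RunConfig) -> None:
    for path, ok in _CONSTRAINTS.items():
        block, key = path.split(".")
        v = getattr(getattr(config, block), key)
        if not ok(v):
            raise ConfigError(f"constraint violation at {path}: value {v!r}")


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a TOML run configuration; missing keys get defaults.

    ``path=None`` (or an empty file) yields the full default configuration.
    """
    config = RunConfig()
    if path is not None:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        blocks = {f.name: f for f in fields(config)}
        for block_name, block_data in data.items():
            if block_name not in blocks:
                raise ConfigError(f"unknown config block {block_name!r}")
            if not isinstance(block_data, dict):
                raise ConfigError(f"block {block_name!r} must be a table")
            _apply_block(getattr(config, block_name), block_data, block_name)
    _validate(config)
    return config


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return f'"{v}"'
    if isinstance(v, list):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialise {type(v)}")


def dump_toml(config: RunConfig) -> str:
    """Serialise a config to TOML text (round-trips through load_config)."""
    lines: list[str] = []
    for block_name, block in asdict(config).items():
        lines.append(f"[{block_name}]")
        for key, value in block.items():
            if isinstance(value, dict):
                for sub, sv in value.items():
                    lines.append(f"{key}.{sub} = {_toml_value(sv)}")
            else:
                lines.append(f"{key} = {_toml_value(value)}")
        lines.append("")
    return "\n".join(lines)
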