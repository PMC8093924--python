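"""Run configuration: YAML-backed, strictly validated, fully seeded.

Every stage parameter defaults to the reference analysis settings
(window/step sizes, bands, thresholds, permutation count); synthetic
cohort sizes default to 35 HC + 60 CTD.  Unknown keys are
rejected so that typos cannot silently fall back to defaults, and all
randomness flows from the single ``seed`` (no wall-clock seeding).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

__all__ = ["RunConfig", "load_config"]


@dataclass
class StageToggles:
    simulate: bool = True
    ersp: bool = True
    cluster: bool = True
    connect: bool = True
    project: bool = True
    infer: bool = True
    stats: bool = True


@dataclass
class CohortConfig:
    n_hc: int = 35
    n_ctd: int = 60


@dataclass
class SimulateConfig:
    n_sources: int = 10
    mvar_order: int = 2
    fs: float = 100.0
    coupling_density: float = 0.15
    coupling_strength: float = 0.4
    #: CTD-only multiplier on one planted edge (sender, receiver)
    effect_edge: tuple = (0, 1)
    effect_multiplier: float = 2.0
    effect_window_ms: tuple = (100.0, 700.0)
    save_epochs: bool = False


@dataclass
class ErspStageConfig:
    window_ms: float = 1000.0
    step_ms: float = 25.0
    baseline_ms: tuple = (-550.0, -50.0)
    fs: float = 250.0


@dataclass
class ClusterConfig:
    k: int = 12
    coverage_threshold: float = 0.70
    n_restarts: int = 50


@dataclass
class ConnectConfig:
    window_ms: float = 1000.0
    step_ms: float = 20.0
    n_freqs: int = 30
    freq_lo: float = 2.0
    freq_hi: float = 49.0
    top_ics: int = 10
    order: int | None = None  # None -> max admissible under the ratio rule


@dataclass
class ProjectConfig:
    n_rois: int = 76
    voxel_mm: float = 5.0
    fwhm_mm: float = 20.0
    n_sigma: float = 3.0
    coverage_threshold: float = 0.70
    parcellation_path: str | None = None
    label_table_path: str | None = None


@dataclass
class InferConfig:
    n_perm: int = 10_000
    alpha_pixel: float = 0.01
    alpha_cluster: float = 0.05
    u: int = 1
    scope: str = "across_edge"
    connectivity: int = 4
    sign_mode: str = "pooled"


@dataclass
class RunConfig:
    seed: int = 0
    output_dir: str = "srcflow_out"
    stages: StageToggles = field(default_factory=StageToggles)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    ersp: ErspStageConfig = field(default_factory=ErspStageConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    connect: ConnectConfig = field(default_factory=ConnectConfig)
    project: ProjectConfig = field(default_factory=ProjectConfig)
    infer: InferConfig = field(default_factory=InferConfig)
    epochs_path: str | None = None

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def _build(cls, data: dict, path: str = ""):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValueError(f"unknown config key(s) {sorted(unknown)} at '{path or cls.__name__}'")
    kwargs = {}
    for name, value in data.items():
        f = fields[name]
        if dataclasses.is_dataclass(f.type) or (
            isinstance(f.default_factory, type) and dataclasses.is_dataclass(f.default_factory)
        ):
            kwargs[name] = _build(f.default_factory, value, f"{path}.{name}" if path else name)
        elif isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration (unknown keys rejected)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return _build(RunConfig, data)
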