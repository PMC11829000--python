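"""Run configuration: every protocol constant in one serializable place.

Defaults reproduce the production protocol: tail filter 0.02, hydropathy
threshold -1.4, confident-stretch rule 5 residues > 75, structured-segment
rule 2 residues > 75, PAE cutoffs 10/5 A, 6 replicas, 1e6 steps of 5 fs at
friction 0.01 ps^-1, error-sampling range [0.0001, 10] A with trial moves of
0.1 A, SEM window 200 steps.  ``test_profile`` scales the simulation down
(2 replicas x 2e5 steps) without touching any selection or error constant.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

__all__ = [
    "PathsConfig",
    "SelectionConfig",
    "EngineConfig",
    "MetainferenceConfig",
    "MetadConfig",
    "OutputConfig",
    "RunConfig",
    "load_config",
    "save_config",
    "test_profile",
]


@dataclass
class PathsConfig:
    distogram: str = ""
    pae: str = ""
    plddt: str = ""
    fasta: str = ""
    start_structure: str = ""  # optional multi/single-model PDB


@dataclass
class SelectionConfig:
    tail_threshold: float = 0.02
    kd_threshold: float = -1.4
    stretch_len: int = 5
    stretch_cutoff: float = 75.0
    segment_min_len: int = 2
    segment_cutoff: float = 75.0
    pae_cutoff_hydrophilic: float = 10.0
    pae_cutoff_default: float = 5.0
    min_separation: int = 3


@dataclass
class EngineConfig:
    n_replicas: int = 6
    n_steps: int = 1_000_000
    dt: float = 0.005  # ps (5 fs)
    friction: float = 0.01  # ps^-1
    temperature: float = 298.0  # K
    pH: float = 7.0
    ionic_strength: float = 0.15  # mol/L
    save_every: int = 1000
    seed: int = 0
    minimize_steps: int = 100
    charged_termini: bool = True


@dataclass
class MetainferenceConfig:
    sigma_bounds: tuple[float, float] = (1e-4, 10.0)  # Angstrom
    move_width: float = 0.1  # Angstrom
    sem_window: int = 200  # steps
    forward_model: str = "replica_average"  # or "per_replica"
    sigma_prior: str = "jeffreys"  # or "as_printed"
    wall_kappa: float = 1e4  # kJ/mol/nm^2
    wall_threshold: float = 0.1  # nm


@dataclass
class MetadConfig:
    height: float = 0.5  # kJ/mol
    bias_factor: float = 10.0
    pace: int = 500  # steps
    width_fraction: float = 0.1  # Gaussian width as fraction of initial CV


@dataclass
class OutputConfig:
    directory: str = "afmi_run"
    n_resampled: int = 1000
    equilibration_fraction: float = 0.1
    n_convergence_blocks: int = 5


@dataclass
class RunConfig:
    paths: PathsConfig = field(default_factory=PathsConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    engine: EngineConfig = field(default_factory=EngineConfig)
    metainference: MetainferenceConfig = field(default_factory=MetainferenceConfig)
    metad: MetadConfig = field(default_factory=MetadConfig)
    output: OutputConfig = field(default_factory=OutputConfig)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["metainference"]["sigma_bounds"] = list(
            d["metainference"]["sigma_bounds"]
        )
        return d

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        cfg = cls()
        for f in fields(cls):
            if f.name in doc:
                section = getattr(cfg, f.name)
                for key, value in doc[f.name].items():
                    if not hasattr(section, key):
                        raise KeyError(f"unknown config key {f.name}.{key}")
                    if key == "sigma_bounds":
                        value = tuple(value)
                    setattr(section, key, value)
        return cfg


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh))


def test_profile(seed: int = 0) -> RunConfig:
    """Scaled-down profile for tests and desk-scale experiments."""
    cfg = RunConfig()
    cfg.engine.n_replicas = 2
    cfg.engine.n_steps = 200_000
    cfg.engine.save_every = 200
    cfg.engine.seed = seed
    cfg.output.n_resampled = 500
    return cfg
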