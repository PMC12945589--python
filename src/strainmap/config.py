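"""Pipeline configuration: schema, defaults, validation, YAML loading."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config"]


def _in_range(name: str, value: float, lo: float, hi: float) -> None:
    if not (lo <= value <= hi):
        raise ValueError(f"{name}={value} outside the documented range [{lo}, {hi}]")


@dataclass
class PipelineConfig:
    """Validated configuration for the end-to-end pipeline.

    Unknown keys in a YAML file are rejected; thresholds are checked against
    their documented ranges on construction.
    """

    output_dir: str = "strainmap_out"
    seed: int = 0
    # synthetic-cohort sizes
    n_mre_subjects: int = 20
    n_control: int = 15
    n_mtbi: int = 15
    preset: str = "subacute_chronic"
    actuation: str = "occipital"
    grid_shape: tuple[int, int, int] = (48, 56, 48)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    # thresholds
    q_thr: float = 0.05
    t_thr: float = 4.0
    fa_threshold: float = 0.7
    lmax: int = 8
    amp_threshold_tau: float = 0.1
    reg_lambda: float = 1.0
    bin_width: float = 0.25
    min_voxels_per_bin: int = 10
    min_cluster_size: int = 1
    # stage toggles
    run_loo: bool = False
    zscore_before_average: bool = True
    logging_level: str = "INFO"

    def __post_init__(self) -> None:
        _in_range("q_thr", self.q_thr, 0.0, 1.0)
        _in_range("t_thr", self.t_thr, 0.0, 100.0)
        _in_range("fa_threshold", self.fa_threshold, 0.0, 1.0)
        _in_range("amp_threshold_tau", self.amp_threshold_tau, 0.0, 1.0)
        _in_range("reg_lambda", self.reg_lambda, 0.0, 1e6)
        _in_range("bin_width", self.bin_width, 1e-6, 10.0)
        if self.lmax % 2 or self.lmax < 2:
            raise ValueError("lmax must be a positive even integer")
        if self.preset not in ("subacute_chronic", "acute", "null", "hs_deficit"):
            raise ValueError(f"unknown preset {self.preset!r}")
        if self.actuation not in ("occipital", "lateral"):
            raise ValueError(f"unknown actuation {self.actuation!r}")
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML configuration file, rejecting unknown keys."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping")
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)
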