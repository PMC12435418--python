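"""Run configuration: YAML-backed, validated, hashable.

Defaults encode the pipeline's standard analysis settings: 100 ns
equilibration trim, CSP flags at 0.3 and 1.0 ppm, 10% contact-persistence
cutoff, loop-clustering cutoff presets of 5.0 A (apo) and 3.5 A (holo) with
an 85%-in-6-clusters coverage target, core-only presets of 1.3 and 1.2 A,
a 0-30 A protrusion threshold grid, and a 16 A highlighted threshold.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


@dataclass
class RunConfig:
    # inputs: trajectory paths (multi-model PDB) and/or NMR tables
    apo_trajectory: str | None = None
    holo_trajectory: str | None = None
    apo_shifts: str | None = None
    holo_shifts: str | None = None
    # synthetic generation when no trajectories are supplied
    simulate: dict = field(default_factory=dict)
    # selections (generator residue layout by default)
    core_residues: tuple[int, int] = (1, 40)
    orientation_residues: tuple[int, int] = (41, 44)
    loop_residues: tuple[int, int] = (66, 96)
    reporter_residue: int = 81
    reporter_atom: str = "CA"
    # thresholds
    theta_grid: tuple[float, float, float] = (0.0, 30.0, 0.5)  # start, stop, step
    theta_star: float = 16.0
    csp_flags: tuple[float, float] = (0.3, 1.0)
    hbond_d_da_max: float = 3.5
    hbond_angle_min: float = 150.0
    persistence_min_pct: float = 10.0
    # clustering
    cluster_cutoff_presets: dict = field(
        default_factory=lambda: {
            "loop_apo": 5.0,
            "loop_holo": 3.5,
            "core_text": 1.3,
            "core_figure": 1.2,
        }
    )
    coverage_target: float = 0.85
    max_clusters: int = 6
    # equilibration trim
    trim_t_cut_ns: float | None = None
    trim_fraction: float = 0.1
    # reproducibility
    seed: int = 0
    output_dir: str = "results"

    def validate(self) -> None:
        for attr in ("apo_trajectory", "holo_trajectory", "apo_shifts", "holo_shifts"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{attr}: file not found: {p}")
        if not (self.apo_trajectory or self.holo_trajectory or self.simulate):
            raise ConfigError(
                "no inputs: provide trajectory paths or a 'simulate' block"
            )
        start, stop, step = self.theta_grid
        if step <= 0 or stop <= start:
            raise ConfigError("theta_grid must be (start, stop, step) with step > 0")
        if not 0 < self.coverage_target <= 1:
            raise ConfigError("coverage_target must be in (0, 1]")

    def hash(self) -> str:
        payload = _plain(asdict(self))
        payload.pop("output_dir", None)  # analysis identity, not location
        canon = yaml.safe_dump(payload, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(_plain(asdict(self)), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(data)
        for key in ("core_residues", "orientation_residues", "loop_residues",
                    "theta_grid", "csp_flags"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


def load_config(path: str | Path) -> RunConfig:
    cfg = RunConfig.from_yaml(path)
    cfg.validate()
    return cfg
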