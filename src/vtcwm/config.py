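"""Run configuration: one YAML-serializable object holding every stage knob.

Every random stage derives its own seed from the single top-level seed, so a
config file fully determines a run.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .synthetic import CohortConfig, MeshConfig

__all__ = ["RunConfig", "stage_seed"]

_STAGE_OFFSETS = {
    "cohort": 1,
    "mesh": 2,
    "tractogram": 3,  # plus session index
    "classify": 4,
    "bootstrap": 5,
}


def stage_seed(base_seed: int, stage: str, index: int = 0) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (base_seed * 1_000_003 + _STAGE_OFFSETS[stage] * 10_007 + index) % (2**31 - 1)


@dataclass
class RunConfig:
    seed: int = 0
    n_streamlines_per_froi: int = 2000
    radius_mm: float = 3.0
    qc_threshold: float = 0.05
    renormalize_profiles: bool = False
    n_components: int | str = "auto"
    ridge: float = 1e-6
    balanced: bool = False
    n_resample_per_label: int = 200
    n_iter: int = 1000
    fraction: float = 0.75
    similarity_hemisphere: str = "L"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    mesh: MeshConfig = field(default_factory=MeshConfig)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mesh"]["hemispheres"] = list(d["mesh"]["hemispheres"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        cohort = d.pop("cohort", {})
        mesh = d.pop("mesh", {})
        if "hemispheres" in mesh:
            mesh["hemispheres"] = tuple(mesh["hemispheres"])
        known = {f.name for f in fields(cls)} - {"cohort", "mesh"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(cohort=CohortConfig(**cohort), mesh=MeshConfig(**mesh), **d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
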