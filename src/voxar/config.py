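"""Run configuration: every tunable with its default, validated up front.

Defaults: Gaussian similarity window sigma_G = 2 voxels, rank-decay
beta = 0.5, top-T pool size T = 7, refined mask-fusion threshold 0.8 and
rough (affine-stage) fusion threshold 0.5.  Registration defaults carry the
validated two-stage setup (see :class:`voxar.registration.RegistrationConfig`).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any, Mapping

import yaml

from .registration import RegistrationConfig

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    sigma_g: float = 2.0
    beta: float = 0.5
    T: int = 7
    refined_fusion_threshold: float = 0.8
    affine_fusion_threshold: float = 0.5
    min_component_voxels: int = 100
    closing_radius: int = 3
    seed: int = 0
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)

    def validate(self) -> None:
        errors: list[str] = []
        if self.sigma_g <= 0:
            errors.append(f"sigma_g must be > 0 (got {self.sigma_g})")
        if self.beta <= 0:
            errors.append(f"beta must be > 0 (got {self.beta})")
        if self.T < 1:
            errors.append(f"T must be >= 1 (got {self.T})")
        elif self.T % 2 == 0:
            # even T is legal but the absolute-majority guard is stricter
            pass
        for name in ("refined_fusion_threshold", "affine_fusion_threshold"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                errors.append(f"{name} must be in (0, 1] (got {v})")
        if self.min_component_voxels < 1:
            errors.append(f"min_component_voxels must be >= 1 (got {self.min_component_voxels})")
        if self.closing_radius < 0:
            errors.append(f"closing_radius must be >= 0 (got {self.closing_radius})")
        if errors:
            raise ValueError("invalid configuration:\n  - " + "\n  - ".join(errors))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        d = dict(d)
        errors: list[str] = []
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            errors.append(f"unknown configuration keys: {sorted(unknown)}")
        reg = d.pop("registration", None)
        reg_cfg = None
        if reg is not None:
            reg_known = {f.name for f in fields(RegistrationConfig)}
            reg_unknown = set(reg) - reg_known
            if reg_unknown:
                errors.append(f"unknown registration keys: {sorted(reg_unknown)}")
            else:
                try:
                    reg_cfg = RegistrationConfig(**reg)
                except (TypeError, ValueError) as exc:
                    errors.append(f"registration: {exc}")
        if errors:
            raise ValueError("invalid configuration:\n  - " + "\n  - ".join(errors))
        cfg = cls(**{k: v for k, v in d.items() if k in known})
        if reg_cfg is not None:
            cfg.registration = reg_cfg
        cfg.validate()
        return cfg


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML/JSON run configuration (defaults if None)."""
    if path is None:
        cfg = RunConfig()
        cfg.validate()
        return cfg
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError(f"configuration file {path} must contain a mapping")
    return RunConfig.from_dict(data)
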