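"""Run configuration: material, reference geometry, imaging and solver knobs."""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from .material import Material

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Defaults are the standard bead: E 1.8 kPa, nu 0.443, diameter 17 µm."""

    E: float = 1800.0
    nu: float = 0.443
    diameter: float = 17.0

    # imaging
    spacing_xy: float = 0.1
    spacing_z: float = 1.0
    blur_sigma: float = 0.2
    noise_level: float = 0.05

    # meshing
    voxel_size: float | None = None  # isosurface grid; None = spacing_z
    smoothing_iterations: int = 10
    max_tet_volume: float | None = None
    sphere_refinement: int = 2

    # solver
    n_load_steps: int = 5
    tol: float = 1.0e-8

    # post-processing
    n_angles: int = 360
    amplification: float = 5.0

    seed: int = 0
    outdir: str = "compax_out"

    def __post_init__(self) -> None:
        for name in ("E", "diameter", "spacing_xy", "spacing_z", "tol"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not (0 <= self.nu < 0.5):
            raise ValueError("nu must lie in [0, 0.5)")
        if self.noise_level < 0 or self.blur_sigma < 0:
            raise ValueError("noise_level and blur_sigma must be >= 0")

    @property
    def material(self) -> Material:
        return Material(E=self.E, nu=self.nu)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def replace(self, **kwargs) -> "RunConfig":
        data = asdict(self)
        data.update({k: v for k, v in kwargs.items() if v is not None})
        return RunConfig(**data)

    def digest(self) -> str:
        import hashlib
        import json

        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]
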