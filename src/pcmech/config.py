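"""Run configuration: a single serializable object that pins every input.

A resolved ``RunConfig`` (plus the seed it contains) fully determines each
output byte of a simulation, and every run writes the resolved config back
next to its results so they are reproducible from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, asdict

import yaml

from .materials import MaterialParams

MODELS = ("isolated", "epidermis", "dermis", "dermis_vertical")


@dataclass
class RunConfig:
    model: str = "isolated"
    resolution: float = 4
    seed: int = 0
    fiber_count_range: tuple = (500, 700)
    corpuscle_policy: str = "surface_aligned_corpuscle"
    skin_policy: str = "skin_plane"
    stretch_ratio: float = 3.0
    A: float = 114.0          # μN
    B: float = 10.0
    G: float = 4.2            # kPa
    nu: float = 0.47
    increments: tuple = (10.0,)   # μm
    indenter_kind: str = "cylinder"   # isolated default; embedded runs use 'node'
    indenter_diameter: float = 250.0  # μm
    indenter_center: tuple = (0.0, 0.0)
    tol_rel: float = 1e-4
    tol_abs: float = 1e-6
    max_iter: int = 30
    eq4_correction: bool = False
    rf_extent: float = 760.0  # μm, receptive-field site radius on the surface
    output_dir: str = "runs"

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}")
        self.fiber_count_range = tuple(int(v) for v in self.fiber_count_range)
        self.increments = tuple(float(v) for v in self.increments)
        self.indenter_center = tuple(float(v) for v in self.indenter_center)

    @property
    def params(self) -> MaterialParams:
        return MaterialParams(self.A, self.B, self.G, self.nu)

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, s: str) -> "RunConfig":
        return cls.from_dict(json.loads(s))
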