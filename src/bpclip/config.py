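"""Run configuration: serializable bundle of every stage's parameters.

A :class:`RunConfig` collects the spring/contact constants, synthetic optics,
protocol staircase, filter settings and estimator options, plus the master
seed. It round-trips through YAML or JSON, and its content hash is stamped
into every output file so results can be traced back to the exact settings
that produced them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .mechanics import ContactGeometry, SpringModel
from .protocol import ProtocolConfig, UserModel
from .synth import OpticsModel, PopulationModel


@dataclass(frozen=True)
class FilterConfig:
    """Signal-conditioning settings shared by imaging and oscillogram stages."""

    force_lowpass_hz: float = 0.4
    bandpass_lo_hz: float = 0.5
    bandpass_hi_hz: float = 10.0
    min_prominence: float = 0.5
    no_pulse_floor: float = 1.0


@dataclass(frozen=True)
class EstimatorConfig:
    inner_cv: int = 5
    multi_target: bool = False
    fold_seed: int = 0


@dataclass
class RunConfig:
    spring: SpringModel = field(default_factory=SpringModel)
    geometry: ContactGeometry = field(default_factory=ContactGeometry)
    optics: OpticsModel = field(default_factory=OpticsModel)
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    user: UserModel = field(default_factory=UserModel)
    population: PopulationModel = field(default_factory=PopulationModel)
    filters: FilterConfig = field(default_factory=FilterConfig)
    estimator: EstimatorConfig = field(default_factory=EstimatorConfig)
    seed: int = 0
    frame_rate: float = 30.0

    _BLOCKS = {
        "spring": SpringModel,
        "geometry": ContactGeometry,
        "optics": OpticsModel,
        "protocol": ProtocolConfig,
        "user": UserModel,
        "population": PopulationModel,
        "filters": FilterConfig,
        "estimator": EstimatorConfig,
    }

    def to_dict(self) -> dict:
        out = {
            name: dataclasses.asdict(getattr(self, name)) for name in self._BLOCKS
        }
        out["seed"] = self.seed
        out["frame_rate"] = self.frame_rate
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = {}
        for name, klass in cls._BLOCKS.items():
            if name in d:
                block = dict(d[name])
                if name == "optics" and "frame_shape" in block:
                    block["frame_shape"] = tuple(block["frame_shape"])
                kwargs[name] = klass(**block)
        for scalar in ("seed", "frame_rate"):
            if scalar in d:
                kwargs[scalar] = d[scalar]
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load YAML (.yml/.yaml) or JSON (.json) by file extension."""
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yml", ".yaml"):
            return cls.from_dict(yaml.safe_load(text) or {})
        if path.suffix == ".json":
            return cls.from_dict(json.loads(text))
        raise ValueError(f"unknown config format: {path.suffix}")

    def to_file(self, path) -> None:
        path = Path(path)
        d = self.to_dict()
        if path.suffix in (".yml", ".yaml"):
            path.write_text(yaml.safe_dump(d, sort_keys=True))
        elif path.suffix == ".json":
            path.write_text(json.dumps(d, indent=2, sort_keys=True))
        else:
            raise ValueError(f"unknown config format: {path.suffix}")

    def content_hash(self) -> str:
        """Short SHA-256 of the canonical JSON form."""
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]
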