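"""Run configuration shared by the CLI and the pipeline helpers.

A :class:`RunConfig` groups the tunables of every stage under the section
names used in YAML config files (``filter``, ``sampling``, ``model``,
``roc``, ``post``, ``hough``, ``synth``).  Loading validates section and key
names strictly: unknown keys are rejected rather than silently ignored.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .filterbank import DEFAULT_ISOTROPIC_SIGMA, DEFAULT_SCALES, DEFAULT_SUPPORT


@dataclass
class FilterConfig:
    support: int = DEFAULT_SUPPORT
    scales: list = DEFAULT_SCALES
    isotropic_sigma: float = DEFAULT_ISOTROPIC_SIGMA
    weber_normalize: bool = False

    def __post_init__(self) -> None:
        # canonical list-of-lists form so YAML round-trips compare equal
        self.scales = [[float(a), float(b)] for a, b in self.scales]

    def bank_kwargs(self) -> dict:
        return {
            "support": self.support,
            "scales": tuple(tuple(s) for s in self.scales),
            "isotropic_sigma": self.isotropic_sigma,
        }


@dataclass
class SamplingConfig:
    fraction: float = 0.3
    seed: int = 0


@dataclass
class ModelConfig:
    ridge: float | None = None  # None -> relative default ridge


@dataclass
class RocConfig:
    n_thresholds: int = 512


@dataclass
class PostConfig:
    open_radius: int = 1
    close_radius: int = 2


@dataclass
class HoughConfig:
    peak_fraction: float = 0.5
    min_length: int = 25
    max_gap: int = 3
    stroke_width: int = 2


@dataclass
class SynthConfig:
    n_scenes: int = 12
    size: int = 512
    noise_sd: float = 0.15
    n_granules: int = 40
    seed: int = 0


_SECTIONS = {
    "filter": FilterConfig,
    "sampling": SamplingConfig,
    "model": ModelConfig,
    "roc": RocConfig,
    "post": PostConfig,
    "hough": HoughConfig,
    "synth": SynthConfig,
}


@dataclass
class RunConfig:
    filter: FilterConfig = field(default_factory=FilterConfig)
    sampling: SamplingConfig = field(default_factory=SamplingConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    roc: RocConfig = field(default_factory=RocConfig)
    post: PostConfig = field(default_factory=PostConfig)
    hough: HoughConfig = field(default_factory=HoughConfig)
    synth: SynthConfig = field(default_factory=SynthConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        doc = doc or {}
        unknown = set(doc) - set(_SECTIONS)
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        kwargs = {}
        for name, section_cls in _SECTIONS.items():
            block = doc.get(name, {}) or {}
            valid = {f.name for f in fields(section_cls)}
            bad = set(block) - valid
            if bad:
                raise ValueError(f"unknown keys in [{name}]: {sorted(bad)}")
            kwargs[name] = section_cls(**block)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
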