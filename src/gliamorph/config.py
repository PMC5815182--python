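"""Run configuration: nested parameter blocks with strict key validation.

Every parameter has a default except the pixel calibration and the
input/output paths, which the user must always supply.  Unknown keys are
rejected up front so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .arborization import ArborParams
from .errors import InputError, ValidationError
from .segmentation import SegmentationParams
from .stains import DAB_VECTOR, HEMATOXYLIN_VECTOR, StainMatrix

__all__ = ["StainConfig", "MorphometryConfig", "MtrConfig", "SynthConfig", "RunConfig"]


@dataclass
class StainConfig:
    hematoxylin_vector: tuple[float, float, float] = HEMATOXYLIN_VECTOR
    dab_vector: tuple[float, float, float] = DAB_VECTOR

    def matrix(self) -> StainMatrix:
        import numpy as np

        return StainMatrix(
            np.array([self.hematoxylin_vector, self.dab_vector]), ("hematoxylin", "dab")
        )


@dataclass
class MorphometryConfig:
    stain_threshold: float = 200.0  # chromogen-gray cutoff for bulk stained area


@dataclass
class MtrConfig:
    noise_floor: float | None = None  # absolute override; None = estimate or 0
    noise_floor_scale: float = 5.0
    background_roi: str | None = None  # ROI name used for the robust estimate


@dataclass
class SynthConfig:
    n_cells: int = 30
    field_size_um: float = 500.0
    morphotype_mix: float = 1.0
    noise_sd: float = 4.0
    margin_um: float = 10.0
    min_separation_um: float = 15.0


def _from_mapping(cls, mapping: Mapping[str, Any], where: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - names
    if unknown:
        raise ValidationError(f"unknown config key(s) under {where!r}: {sorted(unknown)}")
    kwargs = dict(mapping)
    for key, value in kwargs.items():
        if isinstance(value, list):
            kwargs[key] = tuple(value)
    return cls(**kwargs)


@dataclass
class RunConfig:
    """Everything a pipeline run needs, grouped per stage."""

    stain: StainConfig = field(default_factory=StainConfig)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    arbor: ArborParams = field(default_factory=ArborParams)
    morphometry: MorphometryConfig = field(default_factory=MorphometryConfig)
    mtr: MtrConfig = field(default_factory=MtrConfig)
    synth: SynthConfig = field(default_factory=SynthConfig)
    calibration: float | None = None  # µm/pixel; mandatory for image runs
    image: str | None = None
    roi: str | None = None
    out_dir: str | None = None
    seed: int = 0

    _SECTIONS = {
        "stain": StainConfig,
        "segmentation": SegmentationParams,
        "arbor": ArborParams,
        "morphometry": MorphometryConfig,
        "mtr": MtrConfig,
        "synth": SynthConfig,
    }
    _SCALARS = ("calibration", "image", "roi", "out_dir", "seed")

    @classmethod
    def from_dict(cls, payload: Mapping[str, Any]) -> "RunConfig":
        payload = dict(payload or {})
        unknown = set(payload) - set(cls._SECTIONS) - set(cls._SCALARS)
        if unknown:
            raise ValidationError(f"unknown top-level config key(s): {sorted(unknown)}")
        kwargs: dict[str, Any] = {}
        for name, section_cls in cls._SECTIONS.items():
            if name in payload:
                block = payload[name]
                if not isinstance(block, Mapping):
                    raise ValidationError(f"config section {name!r} must be a mapping")
                kwargs[name] = _from_mapping(section_cls, block, name)
        for name in cls._SCALARS:
            if name in payload:
                kwargs[name] = payload[name]
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        try:
            payload = yaml.safe_load(path.read_text(encoding="utf-8"))
        except OSError as exc:
            raise InputError(f"cannot read config {path}: {exc}") from exc
        except yaml.YAMLError as exc:
            raise ValidationError(f"config {path} is not valid YAML: {exc}") from exc
        if payload is None:
            payload = {}
        if not isinstance(payload, Mapping):
            raise ValidationError(f"config {path} must contain a mapping at top level")
        return cls.from_dict(payload)

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {}
        for name in self._SECTIONS:
            out[name] = dataclasses.asdict(getattr(self, name))
        for name in self._SCALARS:
            out[name] = getattr(self, name)
        return out
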