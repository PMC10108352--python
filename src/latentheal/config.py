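"""YAML-backed run configuration for the command-line pipeline."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "provenance_record"]


@dataclass
class DataSection:
    source: str = "synthetic"  # synthetic | directory
    directory: str | None = None
    image_size: tuple[int, ...] = (64, 64)
    n_train: int = 500
    n_val: int = 100
    n_test: int = 50
    sprite_intensities: tuple[float, ...] = (0.0, 1.0)
    noise_sd: float = 0.0
    normalization: str = "auto"  # auto | minmax | percentile | none
    seed: int = 0


@dataclass
class VqvaeSection:
    f: int = 8
    K: int = 32
    n_z: int = 64
    channels: tuple[int, ...] = (16, 32, 64)
    beta: float = 0.25
    epochs: int = 30
    warmup_epochs: int = 8
    batch_size: int = 32
    lr: float = 3e-3
    seed: int = 0


@dataclass
class DensitySection:
    ordering_class: str = "raster"
    ensemble_size: int = 4
    d_model: int = 64
    n_heads: int = 4
    n_layers: int = 2
    d_ff: int = 256
    epochs: int = 35
    batch_size: int = 64
    lr: float = 3e-3
    seed: int = 0


@dataclass
class HealingSection:
    threshold: float = 0.005
    sigma: float | None = None  # None -> f/2 pixels
    positive_residuals: bool = False
    seed: int = 0


@dataclass
class EvalSection:
    lesion_quantile: float = 0.99


@dataclass
class RunConfig:
    data: DataSection = field(default_factory=DataSection)
    vqvae: VqvaeSection = field(default_factory=VqvaeSection)
    density: DensitySection = field(default_factory=DensitySection)
    healing: HealingSection = field(default_factory=HealingSection)
    eval: EvalSection = field(default_factory=EvalSection)

    def __post_init__(self):
        if not 0.0 < self.healing.threshold < 1.0:
            raise ValueError("healing.threshold must be in (0,1)")
        nd = len(tuple(self.data.image_size))
        max_members = 8 if nd == 2 else 7
        if self.density.ensemble_size > max_members:
            raise ValueError(
                f"ensemble_size {self.density.ensemble_size} exceeds the "
                f"{max_members} available {nd}D orderings"
            )

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


_SECTIONS = {
    "data": DataSection,
    "vqvae": VqvaeSection,
    "density": DensitySection,
    "healing": HealingSection,
    "eval": EvalSection,
}


def load_config(path_or_dict) -> RunConfig:
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(path_or_dict or {})
    kwargs = {}
    for name, cls in _SECTIONS.items():
        section = raw.get(name, {})
        unknown = set(section) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown keys in config section {name!r}: {sorted(unknown)}")
        for key in ("image_size", "channels", "sprite_intensities"):
            if key in section and section[key] is not None:
                section[key] = tuple(section[key])
        kwargs[name] = cls(**section)
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    return RunConfig(**kwargs)


def provenance_record(config: RunConfig, stage: str, seeds: dict, artifacts: dict) -> dict:
    """Provenance JSON for one pipeline stage: config digest, seeds, and
    sha256 of the artifact files the stage consumed or produced."""
    from . import __version__

    hashes = {}
    for name, path in artifacts.items():
        p = Path(path)
        hashes[name] = (
            hashlib.sha256(p.read_bytes()).hexdigest()[:16] if p.exists() else None
        )
    return {
        "stage": stage,
        "version": __version__,
        "config_digest": config.digest(),
        "config": config.to_dict(),
        "seeds": seeds,
        "artifacts": hashes,
    }
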