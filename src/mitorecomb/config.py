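"""Pipeline configuration and run manifests.

Defaults are the analysis' published operating points: 50-bp minimum repeat
length, exact repeats, 3,000-bp junction flanks, 1,800-bp dual-flank
overlap, 95% full-length threshold, 70% organelle query coverage.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Infeasible or out-of-range configuration."""


@dataclass
class PipelineConfig:
    min_repeat_len: int = 50
    min_identity: float = 1.0
    flank_len: int = 3000
    min_flank_overlap: int = 1800
    full_length_threshold: float = 0.95
    organelle_query_coverage: float = 0.70
    seed: int = 1

    def validate(self) -> "PipelineConfig":
        if self.min_repeat_len < 20:
            raise ConfigError("min_repeat_len must be >= 20")
        if not 0.0 < self.min_identity <= 1.0:
            raise ConfigError("min_identity must be in (0, 1]")
        if self.flank_len < 1:
            raise ConfigError("flank_len must be >= 1")
        if not 0 < self.min_flank_overlap <= self.flank_len:
            raise ConfigError("min_flank_overlap must be in (0, flank_len]")
        if not 0.0 < self.full_length_threshold <= 1.0:
            raise ConfigError("full_length_threshold must be in (0, 1]")
        if not 0.0 < self.organelle_query_coverage <= 1.0:
            raise ConfigError("organelle_query_coverage must be in (0, 1]")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data).validate()

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    def non_default_items(self) -> dict:
        default = PipelineConfig()
        return {
            k: v for k, v in asdict(self).items() if getattr(default, k) != v
        }


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def write_manifest(
    path: str | Path,
    config: PipelineConfig,
    inputs: dict[str, str | Path] | None = None,
    extra: dict[str, object] | None = None,
) -> None:
    """Flat key=value run manifest: version, full config, non-default
    overrides, and input digests."""
    from . import __version__

    lines = [f"mitorecomb_version={__version__}"]
    for k, v in asdict(config).items():
        lines.append(f"config.{k}={v}")
    for k, v in config.non_default_items().items():
        lines.append(f"override.{k}={v}")
    for name, p in (inputs or {}).items():
        lines.append(f"input.{name}={p}")
        if Path(p).exists():
            lines.append(f"input.{name}.sha256={file_digest(p)}")
    for k, v in (extra or {}).items():
        lines.append(f"{k}={v}")
    Path(path).write_text("\n".join(lines) + "\n")
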