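"""Pipeline configuration with YAML loading."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .vcf_io import DEFAULT_FREQUENCY_KEYS, DEFAULT_GENE_KEY


@dataclass
class PipelineConfig:
    """Tunable stage parameters.

    rarity_threshold — population frequency above which a recorded variant is
    discarded (default 0.01, i.e. 1%); strict_pass — drop FILTER='.' records
    instead of keeping them; frequency_sources — mapping of source name to
    VCF INFO key; pair_identical — require the same compound-het pair in every
    sibling when intersecting recessive candidates.
    """

    rarity_threshold: float = 0.01
    strict_pass: bool = False
    frequency_sources: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_FREQUENCY_KEYS))
    gene_info_key: str = DEFAULT_GENE_KEY
    pair_identical: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.rarity_threshold <= 1.0:
            raise ConfigurationError(
                f"rarity_threshold must be in [0, 1], got {self.rarity_threshold}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"{path}: config must be a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)
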