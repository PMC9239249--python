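"""Pipeline configuration: every numeric threshold of the workflow lives
here with its field-validated default, so stages never hard-code cutoffs."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Union

import yaml


class ConfigError(ValueError):
    """Raised with the offending field named in the message."""


@dataclass
class PipelineConfig:
    # AAI tiers and hit gating
    family_identity: float = 30.0      # % AAI, family tier
    genus_identity: float = 50.0       # % AAI, genus tier
    min_coverage: float = 0.80         # fraction of the shorter protein
    hit_e_max: float = 0.001           # all-vs-all significance cutoff
    hallmark_e_max: float = 0.05       # profile-search inclusion cutoff
    # taxonomy
    min_family_size: int = 6           # provisional VP1-less family needs > 5 genomes
    nt_identity_min: float = 50.0      # % genus-level nucleotide identity floor
    map_seed: int = 42
    # curation / annotation
    min_contig_length: int = 4000      # nt, metagenome screening floor
    min_orf_aa: int = 33
    translation_table: str = "auto"    # "11" | "4" | "auto"
    require_vp2: bool = False
    # recombination scan
    window: int = 99                   # nt of alignment columns
    step: int = 33
    z_min: float = 4.0
    # read recruitment
    read_min_identity: float = 50.0    # %
    read_kmer: int = 13

    def validate(self) -> "PipelineConfig":
        for name in ("family_identity", "genus_identity", "nt_identity_min", "read_min_identity"):
            v = getattr(self, name)
            if not 0 < v <= 100:
                raise ConfigError(f"{name} must be in (0, 100], got {v}")
        if not 0 < self.min_coverage <= 1:
            raise ConfigError(f"min_coverage must be in (0, 1], got {self.min_coverage}")
        for name in ("hit_e_max", "hallmark_e_max"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.min_family_size < 1:
            raise ConfigError(f"min_family_size must be >= 1, got {self.min_family_size}")
        for name in ("min_contig_length", "window", "step", "read_kmer"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be positive")
        if self.min_orf_aa < 10:
            raise ConfigError(f"min_orf_aa must be >= 10, got {self.min_orf_aa}")
        if self.translation_table not in ("11", "4", "auto"):
            raise ConfigError(f"translation_table must be '11', '4' or 'auto', got {self.translation_table!r}")
        if self.z_min <= 0:
            raise ConfigError(f"z_min must be positive, got {self.z_min}")
        return self

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**raw).validate()
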