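"""Pipeline configuration: paths to lexicon/catalog/ICD-10 table plus
matcher settings, cut-off and seed. Loaded from YAML; unset paths fall back
to the packaged defaults."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from typing import Optional

import yaml

from .extract import MatcherConfig
from .lexicon import Lexicon, default_lexicon, load_lexicon
from .phenotype import (
    FeatureCatalog,
    default_catalog,
    default_icd10_table,
    load_catalog,
    load_icd10_table,
)

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    lexicon_path: Optional[str] = None
    catalog_path: Optional[str] = None
    icd10_path: Optional[str] = None
    similarity_threshold: float = 0.85
    negation_window: int = 5
    typo_correction: bool = True
    cutoff: int = 4
    seed: int = 0
    population_rate: float = 40_000
    log_level: str = "INFO"

    def __post_init__(self):
        if self.cutoff < 0:
            raise ValueError("cutoff must be >= 0")

    def matcher(self) -> MatcherConfig:
        return MatcherConfig(
            similarity_threshold=self.similarity_threshold,
            negation_window=self.negation_window,
            typo_correction=self.typo_correction,
        )

    def lexicon(self) -> Lexicon:
        if self.lexicon_path:
            return load_lexicon(self.lexicon_path)
        return default_lexicon()

    def catalog(self) -> FeatureCatalog:
        if self.catalog_path:
            return load_catalog(self.catalog_path)
        return default_catalog()

    def icd10_table(self) -> dict[str, str]:
        if self.icd10_path:
            return load_icd10_table(self.icd10_path)
        return default_icd10_table()

    def digest(self) -> str:
        """Short hash of the configuration, for run logs."""
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path: Optional[str] = None, **overrides) -> PipelineConfig:
    """Build a config from an optional YAML file plus keyword overrides."""
    data: dict = {}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    return PipelineConfig(**data)
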