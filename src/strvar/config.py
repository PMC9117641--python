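"""Run configuration for the chained `strvar report` pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml

from .errors import InputError


@dataclass
class RunConfig:
    """Paths and thresholds for a full pipeline run.

    Thresholds default to the analysis' canonical constants: 8x minimum
    coverage, top-25% genotype rank, 5%/95% trim bounds, 80% cohort
    fraction, and adjusted-p significance at 0.01.
    """

    catalog: str
    reads: str
    outdir: str
    subsets: list[str] = field(default_factory=list)
    expression: Optional[str] = None
    terms: Optional[str] = None
    genes: Optional[str] = None  # gene set for tissue/enrichment stages
    universe: Optional[str] = None
    min_coverage: int = 8
    erc_quantile: float = 0.25
    trim_low: float = 0.05
    trim_high: float = 0.95
    min_fraction: float = 0.8
    alpha: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.erc_quantile < 1:
            raise InputError("erc_quantile must be in (0,1)")
        if not (0 < self.trim_low < self.trim_high < 1):
            raise InputError("trim bounds must satisfy 0 < low < high < 1")
        if not 0 < self.alpha < 1:
            raise InputError("alpha must be in (0,1)")
        if not 0 <= self.min_fraction <= 1:
            raise InputError("min_fraction must be in [0,1]")
        if self.min_coverage < 1:
            raise InputError("min_coverage must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise InputError(f"{path}: config must be a mapping")
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise InputError(f"{path}: unknown config keys {sorted(unknown)}")
        missing = {"catalog", "reads", "outdir"} - set(data)
        if missing:
            raise InputError(f"{path}: config missing required keys {sorted(missing)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)
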