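"""Pipeline configuration: paths, thresholds and the MHC exclusion region."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .twas import MHC_REGION


@dataclass
class PipelineConfig:
    sumstats: Optional[str] = None
    weights: Optional[str] = None
    panel_prefix: Optional[str] = None
    gene_sets: Optional[str] = None
    gwas_loci: Optional[str] = None

    alpha: float = 0.05
    locus_window_bp: int = 500_000
    gsea_min_genes: int = 10
    k_max_dist_bp: int = 5_000_000
    k_min_r2: float = 1e-4
    genome_wide_p: float = 5e-8
    mhc_chrom: str = MHC_REGION[0]
    mhc_start: int = MHC_REGION[1]
    mhc_end: int = MHC_REGION[2]
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha", "locus_window_bp", "gsea_min_genes",
                     "k_max_dist_bp", "k_min_r2", "genome_wide_p"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mhc_start >= self.mhc_end:
            raise ValueError("mhc_start must be < mhc_end")

    @property
    def mhc_region(self) -> tuple[str, int, int]:
        return (str(self.mhc_chrom), self.mhc_start, self.mhc_end)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        """Stable hash of the configuration, for provenance logs."""
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]
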