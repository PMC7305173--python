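"""Run configuration: every threshold of the pipeline in one serializable place."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import yaml


@dataclasses.dataclass
class RunConfig:
    """All pipeline thresholds, defaulting to the published cutoffs."""

    # paths
    reference: str = "reference.fasta"
    genes: str = "genes.gff3"
    metadata: str = "metadata.tsv"
    alignments: str = "alignments"  # directory of per-sample SAM/BAM
    outdir: str = "results"
    # read-pair filters
    max_span: int = 1500
    min_identity: float = 0.96
    min_mapq: int = 1  # strictly greater than
    # inclusion
    min_breadth: float = 0.5
    breadth_depth: int = 5
    # diversity
    min_depth: int = 5
    min_baseq: int = 30
    # SNP null model
    error_rate: float = 1e-4
    fpr: float = 1e-6
    maf: float = 0.05
    snp_mode: str = "analytic"
    split_error_rate: bool = True
    # linkage
    min_pairs: int = 30
    ld_bin_width: int = 50
    # FST / sweep scan
    fst_min_cov: int = 20
    coverage_sd_k: float = 2.0
    window: int = 5
    k_sd: float = 2.5
    alpha: float = 0.05
    # global
    seed: int = 0

    _RANGES = {
        "max_span": (1, None),
        "min_identity": (0.0, 1.0),
        "min_breadth": (0.0, 1.0),
        "breadth_depth": (1, None),
        "min_depth": (1, None),
        "min_baseq": (0, 60),
        "error_rate": (0.0, 1.0),
        "fpr": (0.0, 1.0),
        "maf": (0.0, 0.5),
        "min_pairs": (1, None),
        "fst_min_cov": (2, None),
        "coverage_sd_k": (0.0, None),
        "window": (1, None),
        "k_sd": (0.0, None),
        "alpha": (0.0, 1.0),
    }

    def __post_init__(self) -> None:
        for name, (lo, hi) in self._RANGES.items():
            v = getattr(self, name)
            if lo is not None and v < lo or (hi is not None and v > hi):
                raise ValueError(f"config field {name}={v} outside legal range [{lo}, {hi}]")

    def to_dict(self) -> dict:
        return {
            f.name: getattr(self, f.name)
            for f in dataclasses.fields(self)
            if not f.name.startswith("_")
        }

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]
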