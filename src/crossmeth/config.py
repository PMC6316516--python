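"""Pipeline configuration: thresholds, design, simulation parameters.

A configuration is a plain YAML or JSON mapping; every field has a
default, so an empty file (or no file) runs the full default study
design on the built-in synthetic references.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .simulate import ConfigError, CrossDesign, Population, SimParams, default_design

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Thresholds:
    """Analysis thresholds.

    min_quality / min_length
        Trailing-trim quality floor (Phred) and minimum post-trim read
        length.
    max_mismatch
        Bisulfite-space mismatch budget per read (~3% of a 150-mer).
    mapping_error
        Minor-allele read fraction below which reads are treated as
        mapping error (strictly-less-than rule).
    genotype
        Minimum allele fraction for a heterozygous call.
    reciprocal_alpha
        Significance level below which reciprocal crosses are NOT
        merged.
    min_mapped_reads
        Per-individual mapped-read count under which a QC warning is
        logged (the experiment mapped over 40,000 per individual).
    """

    min_quality: int = 20
    min_length: int = 100
    max_mismatch: int = 5
    mapping_error: float = 0.05
    genotype: float = 0.05
    reciprocal_alpha: float = 0.001
    min_mapped_reads: int = 40_000

    def __post_init__(self) -> None:
        if not 0 <= self.mapping_error <= 1 or not 0 <= self.genotype <= 1:
            raise ConfigError("fraction thresholds must lie in [0, 1]")
        if not 0 < self.reciprocal_alpha < 1:
            raise ConfigError("reciprocal_alpha must lie in (0, 1)")
        if self.min_quality < 0 or self.min_length < 1 or self.max_mismatch < 0:
            raise ConfigError("invalid read-filter thresholds")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a pipeline run needs, with full defaulting."""

    seed: int = 0
    reference_fasta: str | None = None  # default: built-in synthetic regions
    flanks: dict = field(default_factory=dict)  # region_id -> [flank5, flank3]
    design: CrossDesign = field(default_factory=default_design)
    params: SimParams = field(default_factory=SimParams)
    thresholds: Thresholds = field(default_factory=Thresholds)
    make_plots: bool = False

    @classmethod
    def from_mapping(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        design = default_design()
        if "design" in data:
            pops = tuple(
                Population(**p) for p in data.pop("design").get("populations", [])
            )
            design = CrossDesign(populations=pops)
        params = SimParams(**data.pop("params", {}))
        if "seed" in data:
            params = replace(params, seed=int(data["seed"]))
        thresholds = Thresholds(**data.pop("thresholds", {}))
        known = {"seed", "reference_fasta", "flanks", "make_plots"}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(
            seed=int(data.get("seed", 0)),
            reference_fasta=data.get("reference_fasta"),
            flanks={k: list(v) for k, v in (data.get("flanks") or {}).items()},
            design=design,
            params=params,
            thresholds=thresholds,
            make_plots=bool(data.get("make_plots", False)),
        )

    @classmethod
    def from_file(cls, path: str | Path | None) -> "PipelineConfig":
        if path is None:
            return cls()
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        with open(path) as fh:
            data = yaml.safe_load(fh)  # YAML is a superset of JSON
        return cls.from_mapping(data or {})

    def with_seed(self, seed: int) -> "PipelineConfig":
        return replace(self, seed=seed, params=replace(self.params, seed=seed))

    def to_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "reference_fasta": self.reference_fasta,
            "flanks": self.flanks,
            "design": {"populations": [asdict(p) for p in self.design.populations]},
            "params": asdict(self.params),
            "thresholds": asdict(self.thresholds),
            "make_plots": self.make_plots,
        }
        return d

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def setup_logging(verbose: bool = False) -> None:
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
    )
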