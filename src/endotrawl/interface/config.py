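"""Pipeline configuration: one place for every stage threshold.

Serializes losslessly to and from YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from ..errors import ConfigurationError


@dataclass
class PipelineConfig:
    # inputs
    reads: str | None = None
    contigs: str | None = None
    references: str | None = None
    markers: str | None = None  # protein FASTA with tlcA and nosZ
    marker_set: str | None = None  # completeness markers; defaults to `markers`
    rrna_refs: str | None = None
    trna_count: int = 0
    # prescreen
    screen_mode: str = "protein"  # or "nucleotide"
    bsr_min: float = 0.4
    coverage_min: float = 5.0
    # recruitment
    min_contig_len: int = 3000
    min_hit_columns: int = 1000
    min_identity: float = 0.80
    circular_overlap_min: int = 50
    # quality
    qc_bsr_min: float = 0.4
    orf_min_aa: int = 30
    species_identity_min: float = 0.987
    # detection
    detect_k: float = 0.883
    detect_tolerance: float = 0.15
    detect_sidedness: str = "one_sided_lower"
    map_seed_k: int = 15
    # timeseries
    bloom_k_mad: float = 5.0
    bloom_min_peak: float = 0.0001
    # run
    seed: int = 0
    outdir: str = "endotrawl_out"

    def __post_init__(self):
        checks = [
            (0.0 <= self.bsr_min <= 1.0, "bsr_min in [0,1]"),
            (self.coverage_min >= 0, "coverage_min >= 0"),
            (self.min_contig_len > 0, "min_contig_len > 0"),
            (self.min_hit_columns > 0, "min_hit_columns > 0"),
            (0.0 < self.min_identity <= 1.0, "min_identity in (0,1]"),
            (self.circular_overlap_min > 0, "circular_overlap_min > 0"),
            (0.0 < self.species_identity_min < 1.0, "species_identity_min in (0,1)"),
            (self.detect_k > 0, "detect_k > 0"),
            (0.0 < self.detect_tolerance < 1.0, "detect_tolerance in (0,1)"),
            (self.detect_sidedness in ("one_sided_lower", "two_sided"), "sidedness"),
            (self.map_seed_k >= 8, "map_seed_k >= 8"),
            (self.screen_mode in ("protein", "nucleotide"), "screen_mode"),
            (self.trna_count >= 0, "trna_count >= 0"),
            (self.bloom_k_mad > 0, "bloom_k_mad > 0"),
            (self.bloom_min_peak >= 0, "bloom_min_peak >= 0"),
            (self.orf_min_aa >= 1, "orf_min_aa >= 1"),
        ]
        for ok, label in checks:
            if not ok:
                raise ConfigurationError(f"config violates: {label}")

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "PipelineConfig":
        if hasattr(source, "read"):
            data = yaml.safe_load(source.read())
        else:
            try:
                with open(source) as fh:
                    data = yaml.safe_load(fh)
            except (OSError, ValueError):
                data = yaml.safe_load(source)
        if not isinstance(data, dict):
            raise ConfigurationError("config YAML must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
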