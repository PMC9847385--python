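"""Pipeline configuration: every stage threshold in one place.

Defaults are the published protocol values where the protocol states them
(sliding-window mean Q30, minimum read length 50 nt, SAM flag masks 4/264,
>=1,000 reads per virus, assembly k=33, >5% genome completeness, alpha=0.05);
the remaining knobs are this package's own documented choices.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml


@dataclass
class TrimConfig:
    window: int = 4
    mean_q: float = 30.0
    min_len: int = 50
    phred_offset: int = 33

    def validate(self) -> None:
        if self.window < 1:
            raise ValueError("trim.window must be >= 1")
        if self.mean_q < 0:
            raise ValueError("trim.mean_q must be >= 0")
        if self.min_len < 1:
            raise ValueError("trim.min_len must be >= 1")


@dataclass
class FlagConfig:
    include: int = 4  # read unmapped
    exclude: int = 264  # mate unmapped | secondary | QC-pass mask of -F 264

    def validate(self) -> None:
        if not (0 <= self.include < 4096 and 0 <= self.exclude < 4096):
            raise ValueError("flag masks must be 12-bit SAM flags")


@dataclass
class ClipConfig:
    min_clip_len: int = 20
    min_mapq: int = 20

    def validate(self) -> None:
        if self.min_clip_len < 1:
            raise ValueError("clip.min_clip_len must be >= 1")


@dataclass
class ScreenConfig:
    min_virus_reads: int = 1000
    min_identity: float = 0.90
    min_aln_len: int = 30
    seed_k: int = 15
    band: int = 15

    def validate(self) -> None:
        if not (0 < self.min_identity <= 1):
            raise ValueError("screen.min_identity must be in (0, 1]")
        if self.min_virus_reads < 0:
            raise ValueError("screen.min_virus_reads must be >= 0")


@dataclass
class AssemblyConfig:
    k: int = 33
    min_kmer_count: int = 2
    # at a branch, sibling edges below this fraction of the dominant
    # sibling's multiplicity are error artifacts and are removed
    minority_edge_ratio: float = 0.2
    min_completeness_pct: float = 5.0
    use_summed_breadth: bool = False

    def validate(self) -> None:
        if self.k < 3 or self.k % 2 == 0:
            raise ValueError("assembly.k must be odd and >= 3")


@dataclass
class CallingConfig:
    cluster_window: int = 10
    max_insert: int = 1000
    min_support: int = 1

    def validate(self) -> None:
        if self.cluster_window < 0:
            raise ValueError("calling.cluster_window must be >= 0")


@dataclass
class AnnotationConfig:
    promoter_up: int = 2000
    promoter_down: int = 200

    def validate(self) -> None:
        if self.promoter_up < 0 or self.promoter_down < 0:
            raise ValueError("annotation promoter window must be non-negative")


@dataclass
class StatsConfig:
    alpha: float = 0.05
    two_sided: bool = True

    def validate(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("stats.alpha must be in (0, 1)")


@dataclass
class PipelineConfig:
    trim: TrimConfig = field(default_factory=TrimConfig)
    flags: FlagConfig = field(default_factory=FlagConfig)
    clip: ClipConfig = field(default_factory=ClipConfig)
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    assembly: AssemblyConfig = field(default_factory=AssemblyConfig)
    calling: CallingConfig = field(default_factory=CallingConfig)
    annotation: AnnotationConfig = field(default_factory=AnnotationConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    use_assembly_gate: bool = True
    seed: int = 0

    def validate(self) -> None:
        for sub in (
            self.trim, self.flags, self.clip, self.screen,
            self.assembly, self.calling, self.annotation, self.stats,
        ):
            sub.validate()

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = {}
        sections = {
            "trim": TrimConfig, "flags": FlagConfig, "clip": ClipConfig,
            "screen": ScreenConfig, "assembly": AssemblyConfig,
            "calling": CallingConfig, "annotation": AnnotationConfig,
            "stats": StatsConfig,
        }
        for key, klass in sections.items():
            if key in d:
                kwargs[key] = klass(**d[key])
        for key in ("use_assembly_gate", "seed"):
            if key in d:
                kwargs[key] = d[key]
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
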