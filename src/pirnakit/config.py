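"""Pipeline configuration: one YAML file with per-stage sections.

The ``simulate`` section mirrors :class:`pirnakit.sim.SimConfig`; the other
sections carry the thresholds of the downstream stages. Configs round-trip
losslessly through YAML and are validated against documented ranges.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .sim import Fragment, SimConfig


@dataclass
class MapParams:
    max_mismatches: int = 1

    def validate(self) -> None:
        if not 0 <= self.max_mismatches <= 3:
            raise ValueError("max_mismatches must be in 0..3")


@dataclass
class TileParams:
    kmer_size: int = 25
    tile_size: int = 500
    min_unique_frac: float = 0.85

    def validate(self) -> None:
        if self.kmer_size < 2:
            raise ValueError("kmer_size must be >= 2")
        if self.tile_size < self.kmer_size:
            raise ValueError("tile_size must be >= kmer_size")
        if not 0 <= self.min_unique_frac <= 1:
            raise ValueError("min_unique_frac must be in [0, 1]")


@dataclass
class ClusterParams:
    fold_min: float = 10.0
    min_ov_cpm: float = 5.0
    max_gap_tiles: int = 2
    min_tiles: int = 2

    def validate(self) -> None:
        if self.fold_min <= 0 or self.min_ov_cpm < 0:
            raise ValueError("fold_min must be > 0 and min_ov_cpm >= 0")
        if self.max_gap_tiles < 0 or self.min_tiles < 1:
            raise ValueError("max_gap_tiles >= 0 and min_tiles >= 1 required")


@dataclass
class SignatureParams:
    min_plus_cpm: float = 1000.0
    min_minus_cpm: float = 10.0
    pingpong_mode: str = "product"

    def validate(self) -> None:
        if self.pingpong_mode not in ("product", "min"):
            raise ValueError("pingpong_mode must be 'product' or 'min'")
        if self.min_plus_cpm < 0 or self.min_minus_cpm < 0:
            raise ValueError("coverage thresholds must be >= 0")


@dataclass
class PipelineConfig:
    simulate: SimConfig = field(default_factory=SimConfig)
    mapping: MapParams = field(default_factory=MapParams)
    tiles: TileParams = field(default_factory=TileParams)
    clusters: ClusterParams = field(default_factory=ClusterParams)
    signatures: SignatureParams = field(default_factory=SignatureParams)

    def validate(self) -> None:
        self.simulate.validate()
        for section in (self.mapping, self.tiles, self.clusters, self.signatures):
            section.validate()

    def to_dict(self) -> dict:
        d = asdict(self)
        d["simulate"]["cluster_interval"] = list(self.simulate.cluster_interval)
        d["simulate"]["transposon_fragments"] = [
            asdict(f) for f in self.simulate.transposon_fragments
        ]
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        sim_data = dict(data.get("simulate", {}))
        if "cluster_interval" in sim_data:
            ci = sim_data["cluster_interval"]
            sim_data["cluster_interval"] = (str(ci[0]), int(ci[1]), int(ci[2]))
        if "transposon_fragments" in sim_data:
            sim_data["transposon_fragments"] = [
                f if isinstance(f, Fragment) else Fragment(**f)
                for f in sim_data["transposon_fragments"]
            ]
        known = {f.name for f in fields(SimConfig)}
        unknown = set(sim_data) - known
        if unknown:
            raise ValueError(f"unknown simulate keys: {sorted(unknown)}")
        cfg = cls(
            simulate=SimConfig(**sim_data),
            mapping=MapParams(**data.get("mapping", {})),
            tiles=TileParams(**data.get("tiles", {})),
            clusters=ClusterParams(**data.get("clusters", {})),
            signatures=SignatureParams(**data.get("signatures", {})),
        )
        cfg.validate()
        return cfg

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
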