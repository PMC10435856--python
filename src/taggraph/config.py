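"""Pipeline configuration: one YAML file, one seed, validated up front."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .cooccurrence import month_range
from .corpus import DIALECTS

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Everything the pipeline needs, with a single seed fanned out to all
    stochastic components.

    YAML layout mirrors the stages::

        input: corpus.jsonl
        output_dir: out/
        dialect: jsonl
        window: {start: "2020-03", end: "2022-03"}
        embedding: {dim: 1024, hash_seed: 0}
        dbscan: {eps: 0.35, min_samples: 2}
        refex: {depth: 2, prune_threshold: 0.95}
        rolx: {r: null, r_min: 2, r_max: 8, restarts: 3}
        analysis: {start_tags: [], k: 20, min_freq: 2}
        seed: 0
    """

    input: str = ""
    output_dir: str = "out"
    dialect: str = "jsonl"
    keywords_column: str | None = None
    window_start: str | None = None
    window_end: str | None = None
    embedding_dim: int = 1024
    embedding_hash_seed: int = 0
    dbscan_eps: float = 0.35
    dbscan_min_samples: int = 2
    refex_depth: int = 2
    refex_prune_threshold: float = 0.95
    rolx_r: int | None = None  # fixed role count; None selects by MDL
    rolx_r_min: int = 2
    rolx_r_max: int = 8
    rolx_restarts: int = 3
    analysis_start_tags: list[str] = field(default_factory=list)
    analysis_k: int = 20
    analysis_min_freq: int = 2
    analysis_from_role: int | None = None
    analysis_to_roles: list[int] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        if self.dialect not in DIALECTS:
            raise ValueError(f"unknown dialect {self.dialect!r}")
        if (self.window_start is None) != (self.window_end is None):
            raise ValueError("window start and end must be given together")
        if self.window_start is not None:
            month_range(self.window_start, self.window_end)  # raises if start > end
        if self.dbscan_eps <= 0 or self.dbscan_min_samples < 1:
            raise ValueError("dbscan parameters out of range")
        if self.refex_depth < 0 or not 0 < self.refex_prune_threshold <= 1:
            raise ValueError("refex parameters out of range")
        if self.rolx_r is not None and self.rolx_r < 1:
            raise ValueError("rolx.r must be >= 1")
        if not 1 <= self.rolx_r_min <= self.rolx_r_max:
            raise ValueError("need 1 <= rolx.r_min <= rolx.r_max")
        if self.analysis_k < 1 or self.analysis_min_freq < 1:
            raise ValueError("analysis parameters out of range")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs: dict = {}
        nested = {
            "window": ("start", "end"),
            "embedding": ("dim", "hash_seed"),
            "dbscan": ("eps", "min_samples"),
            "refex": ("depth", "prune_threshold"),
            "rolx": ("r", "r_min", "r_max", "restarts"),
            "analysis": ("start_tags", "k", "min_freq", "from_role", "to_roles"),
        }
        for key, value in raw.items():
            if key in nested:
                for sub, subval in (value or {}).items():
                    if sub not in nested[key]:
                        raise ValueError(f"unknown config key {key}.{sub}")
                    kwargs[f"{key}_{sub}"] = subval
            else:
                kwargs[key] = value
        config = cls(**kwargs)
        config.validate()
        return config

    def to_yaml(self, path: str | Path) -> None:
        flat = asdict(self)
        doc = {
            "input": flat["input"],
            "output_dir": flat["output_dir"],
            "dialect": flat["dialect"],
            "keywords_column": flat["keywords_column"],
            "window": {"start": flat["window_start"], "end": flat["window_end"]},
            "embedding": {"dim": flat["embedding_dim"], "hash_seed": flat["embedding_hash_seed"]},
            "dbscan": {"eps": flat["dbscan_eps"], "min_samples": flat["dbscan_min_samples"]},
            "refex": {"depth": flat["refex_depth"], "prune_threshold": flat["refex_prune_threshold"]},
            "rolx": {
                "r": flat["rolx_r"],
                "r_min": flat["rolx_r_min"],
                "r_max": flat["rolx_r_max"],
                "restarts": flat["rolx_restarts"],
            },
            "analysis": {
                "start_tags": flat["analysis_start_tags"],
                "k": flat["analysis_k"],
                "min_freq": flat["analysis_min_freq"],
                "from_role": flat["analysis_from_role"],
                "to_roles": flat["analysis_to_roles"],
            },
            "seed": flat["seed"],
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))
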