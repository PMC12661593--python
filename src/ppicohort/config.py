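"""Run configuration: defaults, file parsing, validation, echo.

A run is fully described by a ``RunConfig``. Config files are either
``key = value`` lines (parameter names in snake_case) or YAML; unknown
keys are errors so that typos cannot silently fall back to defaults.
Every effective value is echoed verbatim into the run manifest, which
alone suffices to re-execute an identical run.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .errors import InputFormatError


@dataclass
class RunConfig:
    """All knobs of a pipeline run.

    ``bootstrapping_rounds`` is accepted for config compatibility but
    must be 0 (bootstrapping is not implemented); ``repulsion_constant``
    is a layout-only parameter, recorded in the manifest with no
    analysis effect. ``consensus_min_count`` of 0 means automatic:
    max(2, ceil(members / 2)) per group.
    """

    interactome: str = ""
    expression: str = ""
    phenotype: str = ""
    output_directory: str = "ppicohort_run"
    seed_count: int = 125
    direction: str = "up"
    min_interactome_score: int = 900
    default_edge_confidence: float = 1.0
    max_path_length: int = 2
    connector_mode: str = "best"
    jaccard_mode: str = "nodes"
    meta_cluster_threshold: float = 0.8
    alpha: float = 0.001
    min_cluster_size: int = 2
    consensus_mode: str = "union_count"
    consensus_min_count: int = 0
    hub_k: int = 5
    modularity_resolution: float = 1.0
    modularity_weighted: bool = False
    max_vertices_to_render: int = 50
    bootstrapping_rounds: int = 0
    repulsion_constant: float = 1.2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.bootstrapping_rounds != 0:
            raise ValueError(
                "bootstrapping_rounds must be 0: bootstrapping is not supported"
            )
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be 'up' or 'down', got {self.direction!r}")
        if self.max_path_length not in (1, 2):
            raise ValueError("max_path_length must be 1 or 2")
        if self.connector_mode not in ("best", "all"):
            raise ValueError("connector_mode must be 'best' or 'all'")
        if self.jaccard_mode not in ("nodes", "edges"):
            raise ValueError("jaccard_mode must be 'nodes' or 'edges'")
        if self.consensus_mode not in ("union_count", "pooled_seeds"):
            raise ValueError("consensus_mode must be 'union_count' or 'pooled_seeds'")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.seed_count < 1:
            raise ValueError("seed_count must be >= 1")
        if self.min_cluster_size < 2:
            raise ValueError("min_cluster_size must be >= 2")
        if not 0 <= self.min_interactome_score <= 1000:
            raise ValueError("min_interactome_score must be in 0-1000")

    def echo(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def field_names(cls) -> set[str]:
        return {f.name for f in dataclasses.fields(cls)}

    @classmethod
    def from_dict(cls, values: dict[str, Any]) -> "RunConfig":
        unknown = set(values) - cls.field_names()
        if unknown:
            raise InputFormatError(f"unknown configuration key(s): {sorted(unknown)}")
        coerced: dict[str, Any] = {}
        for f in dataclasses.fields(cls):
            if f.name not in values:
                continue
            raw = values[f.name]
            if f.type in ("int", int):
                coerced[f.name] = int(raw)
            elif f.type in ("float", float):
                coerced[f.name] = float(raw)
            elif f.type in ("bool", bool):
                coerced[f.name] = (
                    raw if isinstance(raw, bool) else str(raw).lower() in ("1", "true", "yes")
                )
            else:
                coerced[f.name] = str(raw)
        return cls(**coerced)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Parse a config file: YAML if the suffix is .yaml/.yml/.json,
        otherwise ``key = value`` lines (# comments allowed)."""
        path = Path(path)
        if path.suffix.lower() in (".yaml", ".yml", ".json"):
            with open(path) as fh:
                values = yaml.safe_load(fh) or {}
            if not isinstance(values, dict):
                raise InputFormatError(f"{path}: expected a mapping of keys to values")
        else:
            values = {}
            with open(path) as fh:
                for lineno, line in enumerate(fh, start=1):
                    line = line.split("#", 1)[0].strip()
                    if not line:
                        continue
                    if "=" not in line:
                        raise InputFormatError(
                            f"{path}: line {lineno}: expected 'key = value'"
                        )
                    key, value = (part.strip() for part in line.split("=", 1))
                    if key in values:
                        raise InputFormatError(
                            f"{path}: line {lineno}: duplicate key {key!r}"
                        )
                    values[key] = value
        return cls.from_dict(values)

    @classmethod
    def from_manifest(cls, path: str | Path) -> "RunConfig":
        """Rebuild the configuration from a run manifest's config echo."""
        with open(path) as fh:
            manifest = json.load(fh)
        return cls.from_dict(manifest["config"])

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for key, value in self.echo().items():
                fh.write(f"{key} = {value}\n")


# kept as a module-level constant so docs/tests can reference the
# automatic consensus recurrence rule in one place
def auto_min_count(n_members: int) -> int:
    """Default consensus recurrence threshold: max(2, ceil(members/2))."""
    return max(2, -(-n_members // 2))
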