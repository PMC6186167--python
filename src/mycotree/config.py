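"""Run configuration and deterministic seed fan-out.

A single global seed is split into per-stage child seeds through
``numpy.random.SeedSequence(seed).spawn``, in the fixed stage order below,
so each pipeline stage can be replayed independently.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

#: fixed fan-out order for per-stage child seeds
STAGES = ("pools", "design", "layout", "niche", "inventory", "analysis")


@dataclass
class DesignParams:
    pool_size: int = 5
    blocks: int = 2
    grid_rows: int = 5
    grid_cols: int = 8
    richness_levels: tuple[int, ...] = (1, 2, 4)

    def __post_init__(self):
        self.richness_levels = tuple(self.richness_levels)


@dataclass
class SimulationParams:
    scenario: str = "complementarity"
    years: int = 2
    noise_sd: float = 0.05
    mortality_rate: float = 0.0
    resolution: int = 200
    initial_diameter: float = 1.0
    initial_sd: float = 0.0
    base_rate: float = 1500.0
    amf_rate_factor: float = 1.0
    dominance_factor: float = 4.0


@dataclass
class AnalysisParams:
    n_boot: int = 2000
    richness_scale: str = "log2"
    year_from: int = 1
    year_to: int = 2


@dataclass
class RunConfig:
    seed: int = 1
    design: DesignParams = field(default_factory=DesignParams)
    simulation: SimulationParams = field(default_factory=SimulationParams)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)

    # -- seed fan-out ------------------------------------------------------
    def stage_seed(self, stage: str) -> int:
        if stage not in STAGES:
            raise KeyError(f"unknown stage {stage!r}; expected one of {STAGES}")
        children = np.random.SeedSequence(self.seed).spawn(len(STAGES))
        return int(children[STAGES.index(stage)].generate_state(1)[0])

    # -- (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["design"]["richness_levels"] = list(self.design.richness_levels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(
            seed=int(d.get("seed", 1)),
            design=_sub(DesignParams, d.get("design", {})),
            simulation=_sub(SimulationParams, d.get("simulation", {})),
            analysis=_sub(AnalysisParams, d.get("analysis", {})),
        )

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} does not contain a mapping")
        return cls.from_dict(data)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def _sub(cls, d: dict):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**d)
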