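"""Pipeline configuration: validated blocks, YAML/JSON loading, defaults.

The default configuration reproduces the acquisition and survey
conditions of the reference expedition: seven 60x60-tile montages of
6144x4090-pixel images with a 120-um field of view, 12.5% overlap and
8 s dwell; a specimen density of ~207 specimens/cm**2; quorum-3
consensus over up to four views; and the default calibrated volunteer
pool.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from .cohort import DEFAULT_TAXON_MIX, TaxonMix
from .consensus import ANSWER_FIELDS
from .geometry import TileGrid

__all__ = [
    "MontageConfig",
    "ConsensusConfig",
    "ReviewConfig",
    "CensusConfig",
    "SimulationConfig",
    "PipelineConfig",
    "default_config",
    "load_config",
]


@dataclass(frozen=True)
class MontageConfig:
    n_cols: int = 60
    n_rows: int = 60
    tile_px_x: int = 6144
    tile_px_y: int = 4090
    fov_width_um: float = 120.0
    overlap_frac: float = 0.125
    dwell_s_per_image: float = 8.0
    count: int = 7  # identical montages in the dataset

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("montage count must be >= 1")
        self.grids()  # TileGrid enforces the geometric invariants

    def grids(self) -> list[TileGrid]:
        g = TileGrid(
            self.n_cols,
            self.n_rows,
            self.tile_px_x,
            self.tile_px_y,
            self.fov_width_um,
            self.overlap_frac,
            self.dwell_s_per_image,
        )
        return [g] * self.count


@dataclass(frozen=True)
class ConsensusConfig:
    quorum: int = 3
    max_views: int = 4
    match_fields: tuple[str, ...] = ANSWER_FIELDS
    count_cap: int = 10
    order_aware_dispute: bool = True

    def __post_init__(self) -> None:
        if self.quorum > self.max_views:
            raise ValueError("quorum cannot exceed max_views")
        bad = set(self.match_fields) - set(ANSWER_FIELDS)
        if bad:
            raise ValueError(f"unknown match fields: {sorted(bad)}")


@dataclass(frozen=True)
class ReviewConfig:
    seconds_per_image: float = 5.0
    miss_rate: float = 0.0
    escalation_rate: float = 0.1


@dataclass(frozen=True)
class CensusConfig:
    epsilon_um: float = 10.0


@dataclass(frozen=True)
class SimulationConfig:
    density_per_cm2: float = 207.0
    taxon_mix: TaxonMix = DEFAULT_TAXON_MIX
    n_volunteers: int = 100
    sensitivity: float = 0.85
    false_positive_rate: float = 0.04
    count_error_rate: float = 0.10
    focus_error_rate: float = 0.08
    skip_rate: float = 0.0
    radius_mean_um: float = 15.0


@dataclass(frozen=True)
class PipelineConfig:
    montage: MontageConfig = field(default_factory=MontageConfig)
    consensus: ConsensusConfig = field(default_factory=ConsensusConfig)
    review: ReviewConfig = field(default_factory=ReviewConfig)
    census: CensusConfig = field(default_factory=CensusConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    master_seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["simulation"]["taxon_mix"] = {
            "frequencies": dict(self.simulation.taxon_mix.frequencies),
            "indeterminable_fraction": self.simulation.taxon_mix.indeterminable_fraction,
        }
        return d


def default_config(**overrides: Any) -> PipelineConfig:
    return PipelineConfig(**overrides)


def _build(cls, block: Mapping[str, Any] | None):
    return cls(**(block or {}))


def load_config(source: str | Path | Mapping[str, Any]) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML/JSON file or mapping."""
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
        data = yaml.safe_load(text)  # YAML is a JSON superset
    else:
        data = dict(source)
    data = data or {}
    sim = dict(data.get("simulation") or {})
    if "taxon_mix" in sim:
        tm = sim["taxon_mix"]
        sim["taxon_mix"] = TaxonMix(
            frequencies=tm["frequencies"],
            indeterminable_fraction=tm.get("indeterminable_fraction", 0.0),
        )
    cons = dict(data.get("consensus") or {})
    if "match_fields" in cons:
        cons["match_fields"] = tuple(cons["match_fields"])
    return PipelineConfig(
        montage=_build(MontageConfig, data.get("montage")),
        consensus=_build(ConsensusConfig, cons),
        review=_build(ReviewConfig, data.get("review")),
        census=_build(CensusConfig, data.get("census")),
        simulation=SimulationConfig(**sim),
        master_seed=int(data.get("master_seed", 0)),
    )
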