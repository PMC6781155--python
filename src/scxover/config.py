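"""Run configuration: schema-validated YAML covering the whole pipeline."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .curate import Chr1Filter, CurationParams
from .foci import FociParams
from .midline import DEFAULT_PX_PER_UM, MidlineParams
from .segment import SegmentationParams


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CellConfig(_Strict):
    n_bivalents: int = 24
    include_xy: bool = True
    overlap_fraction: float = 0.0
    noise_sd: float = 0.01
    salt_fraction: float = 0.0
    illumination_gradient: float = 0.10
    canvas_size: tuple[int, int] = (900, 900)
    arc_length_range: tuple[float, float] = (80.0, 160.0)
    ribbon_width: float = 5.0
    sc_intensity: float = 0.75
    foci_sigma: float = 2.0
    foci_intensity: float = 0.9
    n_stray_foci: int = 0


class SimulateConfig(_Strict):
    n_cells: int = 1
    seed: int = 0
    cell_seeds: list[int] | None = None
    cell: CellConfig = Field(default_factory=CellConfig)


class SegmentationConfig(_Strict):
    threshold_method: str = "otsu"
    threshold_offset: float = 0.0
    robust_k: float = 6.0
    smooth_sigma: float = 1.0
    min_detect_area: int = 20
    min_area: int = 150
    max_area: int = 6000
    min_skeleton_len: float = 30.0
    max_skeleton_len: float = 400.0
    min_eccentricity: float = 0.85
    min_solidity: float = 0.25
    max_branch_points: int = 0
    border_margin: int = 3
    spur_px: float = 5.0

    def to_params(self) -> SegmentationParams:
        return SegmentationParams(**self.model_dump())


class MidlineConfig(_Strict):
    spur_px: float = 5.0
    step_px: float = 0.5
    max_spline_dev: float = 1.0
    max_extension_px: float = 12.0

    def to_params(self) -> MidlineParams:
        return MidlineParams(**self.model_dump())


class FociConfig(_Strict):
    k_sigma: float = 4.0
    ribbon_half_width: float = 6.0
    min_separation_px: float = 5.0
    min_peak_distance: int = 3
    smooth_sigma: float = 1.0

    def to_params(self) -> FociParams:
        return FociParams(**self.model_dump())


class Chr1Config(_Strict):
    sc_length_um_window: tuple[float, float] = (10.0, 17.0)
    centromere_norm_window: tuple[float, float] = (0.15, 0.40)
    require_longest_in_cell: bool = True

    def to_filter(self) -> Chr1Filter:
        return Chr1Filter(**self.model_dump())


class CurationConfig(_Strict):
    max_foci: int = 4
    center_tol_px: float = 2.5
    robust_z: float = 3.5
    min_length_px: float = 30.0
    chr1: Chr1Config = Field(default_factory=Chr1Config)

    def to_params(self) -> CurationParams:
        d = self.model_dump()
        d.pop("chr1")
        return CurationParams(**d)


class StatsConfig(_Strict):
    bin_width: float = 0.05
    n_perm: int = 10_000
    seed: int = 0
    outlier_min_distance_um: float = 1.0
    min_interference_n: int = 10


class RunConfig(_Strict):
    """Full pipeline configuration; unknown keys are rejected."""

    px_per_um: float = DEFAULT_PX_PER_UM
    channels: dict[str, int] = Field(
        default_factory=lambda: {"sc": 0, "foci": 1, "centromere": 2}
    )
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    segmentation: SegmentationConfig = Field(default_factory=SegmentationConfig)
    midline: MidlineConfig = Field(default_factory=MidlineConfig)
    foci: FociConfig = Field(default_factory=FociConfig)
    curation: CurationConfig = Field(default_factory=CurationConfig)
    stats: StatsConfig = Field(default_factory=StatsConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
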