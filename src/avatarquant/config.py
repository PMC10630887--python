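"""Run configuration: a flat, YAML-round-trippable parameter record.

Every stage parameter that affects results lives here — segmentation sigma,
the 0.6/0.35 circularity thresholds, the 30 um proximity radius, the IoU
matching threshold, and an explicit seed for every random operation — so a
run is reproducible from its config file alone.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .errors import ConfigError
from .gam import RAMIFIED_THRESHOLD, ROUND_THRESHOLD
from .spatial import PROXIMITY_RADIUS_UM


@dataclass
class RunConfig:
    # paths
    movie_path: str | None = None
    output_dir: str = "avatarquant_out"
    classifier_path: str | None = None

    # calibration / channel roles (override file metadata when set)
    channels: dict = field(default_factory=dict)
    spacing: tuple[float, float, float] | None = None
    frame_interval_min: float | None = None
    injection_offset_hpi: float | None = None

    # avatar stage parameters
    tumor_sigma_px: float = 1.0
    tumor_keep: str = "all"
    gam_backend: str = "classical"
    gam_sigma_px: float = 0.7
    gam_min_area_px: int = 20
    round_threshold: float = ROUND_THRESHOLD
    ramified_threshold: float = RAMIFIED_THRESHOLD
    proximity_radius_um: float = PROXIMITY_RADIUS_UM
    iou_threshold: float = 0.5
    z_inference: str = "weighted_centroid"
    perimeter_estimator: str = "crofton"
    bleedthrough_coefficient: float = 0.0
    remove_autofluorescence_channels: tuple[str, ...] = ("tumor", "gam")

    # stage toggles
    do_bleedthrough: bool = False
    do_autofluorescence: bool = False
    do_rolling_ball: bool = True
    do_prestain_subtraction: bool = True
    do_quantile_normalization: bool = False
    write_masks: bool = False

    # IHC stage parameters
    rolling_ball_radius_px: float = 50.0
    nucleus_block_size: int = 51
    nucleus_offset: float = 0.0
    nucleus_min_size_px: int = 40
    expansion_px: int = 5
    summary_quantile: float = 0.95
    sox2_rule: str = "otsu"
    sox2_value: float | None = None

    # randomness
    seed: int = 0

    def __post_init__(self):
        if self.tumor_keep not in ("all", "largest"):
            raise ConfigError(f"tumor_keep must be all|largest, got {self.tumor_keep}")
        if not 0 < self.iou_threshold <= 1:
            raise ConfigError("iou_threshold must be in (0, 1]")
        if self.proximity_radius_um < 0:
            raise ConfigError("proximity_radius_um must be >= 0")
        if self.ramified_threshold > self.round_threshold:
            raise ConfigError("ramified_threshold must not exceed round_threshold")
        if self.seed is None:
            raise ConfigError("an explicit seed is required")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        d.update(overrides)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("spacing", "remove_autofluorescence_channels"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)
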