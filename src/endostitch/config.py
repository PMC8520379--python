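"""Run configuration: every tunable of the pipeline in one place."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

from .errors import ConfigurationError


@dataclass
class RunConfig:
    """All pipeline tunables with their defaults.

    Pyramid: ``sigma0`` (base smoothing, px), ``s`` (intervals/octave),
    ``n_octaves``, ``upsample`` (2x input upsampling).  Detector:
    ``contrast_thresh`` (min |DoG| response), ``edge_ratio`` (principal
    curvature ratio r), ``max_keypoints`` (keep strongest).  Matching:
    ``ratio`` (Lowe nearest/second-nearest test).  Filters: ``slope_t``
    (slope neighbourhood half-width), ``dg_max`` (disparity-gradient
    cut-off), ``knn`` (spatial neighbours for the disparity test).
    Estimation: ``ransac_thresh`` (px), ``n_iter``, ``seed``.
    """

    sigma0: float = 1.6
    s: int = 3
    n_octaves: int = 4
    upsample: bool = False
    contrast_thresh: float = 0.03
    edge_ratio: float = 10.0
    max_keypoints: int = 600
    ratio: float = 0.8
    slope_t: float = 0.02
    dg_max: float = 2.0
    knn: int = 4
    ransac_thresh: float = 3.0
    n_iter: int = 1000
    seed: int = 17

    def __post_init__(self) -> None:
        if self.sigma0 <= 0 or self.s < 1 or self.n_octaves < 1:
            raise ConfigurationError("invalid pyramid parameters")
        if not (0 < self.ratio < 1):
            raise ConfigurationError(f"ratio must be in (0, 1), got {self.ratio}")
        if self.slope_t <= 0 or self.dg_max <= 0 or self.knn < 1:
            raise ConfigurationError("invalid filter parameters")
        if self.ransac_thresh <= 0 or self.n_iter < 1:
            raise ConfigurationError("invalid RANSAC parameters")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
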