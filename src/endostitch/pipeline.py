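"""End-to-end registration and stitching of one frame pair.

Pipeline: scale-space keypoint detection and description on both frames,
ratio-test coarse matching, slope-consistency pre-check, disparity-
gradient filtering, seeded RANSAC homography estimation, and feathered
mosaicking.  :func:`stitch_pair` returns the mosaic together with a
machine-readable report of every stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import match_filtering as mf
from .config import RunConfig
from .keypoint_features import Keypoint, detect_and_describe
from .scale_space import build_scale_space
from .stitcher import HomographyModel, Mosaic, estimate_homography, stitch


@dataclass
class RegistrationResult:
    """Matches (with filter statuses) and the fitted homography."""

    keypoints_a: list[Keypoint]
    keypoints_b: list[Keypoint]
    matches: list[mf.MatchPair]
    model: HomographyModel
    report: dict


@dataclass
class StitchResult:
    registration: RegistrationResult
    mosaic: Mosaic


def register_pair(
    img_a: np.ndarray, img_b: np.ndarray, config: RunConfig | None = None
) -> RegistrationResult:
    """Detect, describe, match, filter and fit the inter-frame homography."""
    cfg = config or RunConfig()
    ss_a = build_scale_space(
        img_a, cfg.n_octaves, cfg.s, cfg.sigma0, upsample=cfg.upsample
    )
    ss_b = build_scale_space(
        img_b, cfg.n_octaves, cfg.s, cfg.sigma0, upsample=cfg.upsample
    )
    kps_a, desc_a = detect_and_describe(
        ss_a, cfg.contrast_thresh, cfg.edge_ratio, cfg.max_keypoints
    )
    kps_b, desc_b = detect_and_describe(
        ss_b, cfg.contrast_thresh, cfg.edge_ratio, cfg.max_keypoints
    )
    matches = mf.coarse_match(desc_a, desc_b, cfg.ratio, kps_a, kps_b)
    params = mf.PrescreenParams(t=cfg.slope_t, composite_offset=float(img_a.shape[1]))
    mf.composite_slopes(matches, params, src_width=float(img_a.shape[1]))
    mf.prescreen(matches, params)
    mf.disparity_filter(matches, K=cfg.knn, max_gradient=cfg.dg_max)
    kept = mf.retained(matches)
    model = estimate_homography(kept, cfg.ransac_thresh, cfg.n_iter, cfg.seed)
    report = {
        "n_keypoints_a": len(kps_a),
        "n_keypoints_b": len(kps_b),
        "filters": mf.filter_report(matches, params, K=cfg.knn),
        "n_retained": len(kept),
        "n_inliers": int(model.inlier_indices.size),
        "rms_error_px": model.rms_error,
        "homography": model.H.tolist(),
        "config": cfg.to_dict(),
    }
    return RegistrationResult(
        keypoints_a=kps_a,
        keypoints_b=kps_b,
        matches=matches,
        model=model,
        report=report,
    )


def stitch_pair(
    img_a: np.ndarray, img_b: np.ndarray, config: RunConfig | None = None
) -> StitchResult:
    """Register two frames and blend them into a mosaic."""
    reg = register_pair(img_a, img_b, config)
    mosaic = stitch(img_a, img_b, reg.model)
    reg.report["canvas_shape"] = list(mosaic.canvas.shape)
    reg.report["origin_shift"] = list(mosaic.origin_shift)
    return StitchResult(registration=reg, mosaic=mosaic)
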