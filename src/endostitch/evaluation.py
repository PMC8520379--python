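"""Seeded synthetic benchmarks for the match filters and the full pipeline.

Two benchmarks, both driven entirely by the synthetic fixture generator:

* :func:`evaluate_filters` scores the two-stage mismatch filter
  (slope pre-check + disparity gradient) on fixture pairs whose true
  correspondences are known and into which a controlled fraction of
  deliberately wrong matches has been injected.  Motion follows the
  consecutive-endoscopic-frame regime (rotation <= 3 deg, scale
  0.97-1.03, translation <= 25 px).

* :func:`evaluate_end_to_end` runs the whole pipeline (detect, describe,
  match, filter, RANSAC) on fixture pairs with rotations up to 10 deg and
  scales 0.9-1.1, and scores the recovered homography by the corner
  transfer error against the generating transform.
"""

from __future__ import annotations

import numpy as np

from . import match_filtering as mf
from .config import RunConfig
from .pipeline import register_pair
from .stitcher import apply_homography
from .synthetic_fixtures import FixturePair, FixtureSpec, generate_pair, inject_false_matches


def filter_injected_matches(
    matches: list[mf.MatchPair], src_width: float, t: float = 0.02, K: int = 4
) -> list[mf.MatchPair]:
    """Run both filters over a labelled match list; returns the same list."""
    params = mf.PrescreenParams(t=t, composite_offset=src_width)
    mf.composite_slopes(matches, params, src_width=src_width)
    mf.prescreen(matches, params)
    mf.disparity_filter(matches, K=K)
    return matches


def _filter_motion_spec(seed: int, size=(256, 256)) -> FixtureSpec:
    rng = np.random.default_rng(seed)
    return FixtureSpec(
        size=size,
        rotation=float(rng.uniform(-3.0, 3.0)),
        scale=float(rng.uniform(0.97, 1.03)),
        translation=(float(rng.uniform(-25.0, 25.0)), float(rng.uniform(-10.0, 10.0))),
        perspective=(0.0, 0.0),
        noise_sigma=0.01,
        seed=seed,
    )


def evaluate_filters(
    n_pairs: int = 20,
    false_fraction: float = 0.3,
    seed: int = 0,
    t: float = 0.02,
    K: int = 4,
) -> dict:
    """False-match removal and true-match retention of the two-stage filter.

    Returns overall rates pooled over ``n_pairs`` seeded fixture pairs:
    ``false_removal`` = fraction of injected wrong matches rejected,
    ``true_retention`` = fraction of true correspondences retained.
    """
    removed_false = total_false = kept_true = total_true = 0
    for i in range(n_pairs):
        spec = _filter_motion_spec(seed + 1000 * i + 1)
        pair = generate_pair(spec)
        matches = inject_false_matches(pair, false_fraction, seed + 1000 * i + 2)
        filter_injected_matches(matches, src_width=float(pair.frame_a.shape[1]), t=t, K=K)
        for m in matches:
            if m.truth == "false":
                total_false += 1
                if m.status != mf.STATUS_RETAINED:
                    removed_false += 1
            else:
                total_true += 1
                if m.status == mf.STATUS_RETAINED:
                    kept_true += 1
    return {
        "n_pairs": n_pairs,
        "false_fraction": false_fraction,
        "n_true": total_true,
        "n_false": total_false,
        "false_removal": removed_false / max(total_false, 1),
        "true_retention": kept_true / max(total_true, 1),
    }


def corner_transfer_error(
    H_est: np.ndarray, H_true: np.ndarray, size: tuple[int, int]
) -> float:
    """Mean displacement (px) of the frame corners under H_est vs H_true."""
    h, w = size
    corners = np.array(
        [[0.0, 0.0], [w - 1.0, 0.0], [w - 1.0, h - 1.0], [0.0, h - 1.0]]
    )
    d = apply_homography(H_est, corners) - apply_homography(H_true, corners)
    return float(np.linalg.norm(d, axis=1).mean())


def _end_to_end_spec(seed: int, size=(256, 256)) -> FixtureSpec:
    rng = np.random.default_rng(seed)
    return FixtureSpec(
        size=size,
        rotation=float(rng.uniform(-10.0, 10.0)),
        scale=float(rng.uniform(0.9, 1.1)),
        translation=(float(rng.uniform(-15.0, 15.0)), float(rng.uniform(-10.0, 10.0))),
        perspective=(0.0, 0.0),
        noise_sigma=0.01,
        seed=seed,
    )


def evaluate_end_to_end(
    n_pairs: int = 10,
    seed: int = 0,
    size: tuple[int, int] = (256, 256),
    config: RunConfig | None = None,
) -> dict:
    """Full-pipeline homography recovery on seeded fixture pairs.

    Per pair, the corner transfer error of the estimated vs the true
    homography; reports the per-pair errors and their median.  Pairs where
    estimation fails count as infinite error.
    """
    errors = []
    for i in range(n_pairs):
        spec = _end_to_end_spec(seed + 1000 * i + 1, size=size)
        pair = generate_pair(spec)
        try:
            reg = register_pair(pair.frame_a, pair.frame_b, config)
            err = corner_transfer_error(reg.model.H, pair.true_H, size)
        except Exception:
            err = float("inf")
        errors.append(err)
    return {
        "n_pairs": n_pairs,
        "corner_errors_px": errors,
        "median_corner_error_px": float(np.median(errors)),
    }


def evaluate_fixture_pair(pair: FixturePair, config: RunConfig | None = None) -> dict:
    """Run the pipeline on one fixture pair and score it against ground truth."""
    reg = register_pair(pair.frame_a, pair.frame_b, config)
    err = corner_transfer_error(reg.model.H, pair.true_H, pair.frame_a.shape)
    report = dict(reg.report)
    report["corner_transfer_error_px"] = err
    return report
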