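"""Homography estimation and feathered mosaicking of two frames.

The inter-frame model is a 3x3 projective transform (homography) estimated
from retained matches by normalised DLT inside a seeded RANSAC loop with
symmetric transfer error, followed by a least-squares refit on the
consensus set.  The target frame is warped into the source frame by the
inverse homography with bilinear sampling, and the overlap is blended by
linear feathering: each frame contributes proportionally to the distance
from its own border, with weights normalised to sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DivergentModelError, EstimationError
from .match_filtering import MatchPair


@dataclass
class HomographyModel:
    """A fitted projective transform mapping source to target coordinates.

    ``H`` is normalised so that ``H[2, 2] == 1``; ``inlier_indices`` index
    into the match list the model was estimated from; ``rms_error`` is the
    root-mean-square symmetric transfer error over the inliers, in pixels.
    """

    H: np.ndarray
    inlier_indices: np.ndarray
    rms_error: float


@dataclass
class Mosaic:
    """A stitched canvas with blending provenance.

    ``origin_shift`` is the integer translation that places the source
    frame on the canvas: source pixel (x, y) lands at canvas
    (x - origin_shift[0], y - origin_shift[1]).  ``seam_mask`` labels each
    canvas pixel 0 = empty, 1 = source only, 2 = target only, 3 = blended;
    ``weights_src`` / ``weights_dst`` are the normalised blending weights
    (summing to 1 wherever either frame contributes).
    """

    canvas: np.ndarray
    origin_shift: tuple[int, int]
    seam_mask: np.ndarray
    weights_src: np.ndarray
    weights_dst: np.ndarray


def apply_homography(H: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Map ``(n, 2)`` points through a homography (inhomogeneous result)."""
    pts = np.atleast_2d(np.asarray(pts, dtype=np.float64))
    ones = np.ones((pts.shape[0], 1))
    proj = np.hstack([pts, ones]) @ H.T
    return proj[:, :2] / proj[:, 2:3]


def _normalise_points(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hartley normalisation: centroid at origin, mean distance sqrt(2)."""
    centroid = pts.mean(axis=0)
    d = np.linalg.norm(pts - centroid, axis=1).mean()
    s = np.sqrt(2.0) / d if d > 0 else 1.0
    T = np.array(
        [[s, 0.0, -s * centroid[0]], [0.0, s, -s * centroid[1]], [0.0, 0.0, 1.0]]
    )
    return (pts * s - s * centroid), T


def _dlt(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Direct linear transform with Hartley normalisation."""
    src_n, T_src = _normalise_points(src)
    dst_n, T_dst = _normalise_points(dst)
    n = src_n.shape[0]
    A = np.zeros((2 * n, 9))
    for i in range(n):
        x, y = src_n[i]
        u, v = dst_n[i]
        A[2 * i] = [-x, -y, -1.0, 0.0, 0.0, 0.0, u * x, u * y, u]
        A[2 * i + 1] = [0.0, 0.0, 0.0, -x, -y, -1.0, v * x, v * y, v]
    _, _, vt = np.linalg.svd(A)
    Hn = vt[-1].reshape(3, 3)
    H = np.linalg.inv(T_dst) @ Hn @ T_src
    if abs(H[2, 2]) < 1e-12:
        raise EstimationError("degenerate homography (H[2,2] ~ 0)")
    return H / H[2, 2]


def _symmetric_transfer_error(
    H: np.ndarray, src: np.ndarray, dst: np.ndarray
) -> np.ndarray:
    Hinv = np.linalg.inv(H)
    fwd = np.linalg.norm(apply_homography(H, src) - dst, axis=1)
    bwd = np.linalg.norm(apply_homography(Hinv, dst) - src, axis=1)
    return 0.5 * (fwd + bwd)


def _sample_degenerate(pts: np.ndarray) -> bool:
    """True if any 3 of the 4 sampled points are (nearly) collinear."""
    from itertools import combinations

    for a, b, c in combinations(range(4), 3):
        v1 = pts[b] - pts[a]
        v2 = pts[c] - pts[a]
        area = abs(v1[0] * v2[1] - v1[1] * v2[0])
        if area < 1e-8:
            return True
    return False


def estimate_homography(
    matches: list[MatchPair],
    ransac_thresh: float = 3.0,
    n_iter: int = 1000,
    seed: int = 17,
) -> HomographyModel:
    """Robust homography fit from retained matches.

    Seeded RANSAC over minimal 4-point normalised-DLT solves; inliers are
    classified by symmetric transfer error below ``ransac_thresh`` pixels;
    the final model is a least-squares DLT refit on the largest consensus
    set.  Raises :class:`EstimationError` for fewer than 4 matches or a
    degenerate (collinear) consensus.
    """
    if len(matches) < 4:
        raise EstimationError(f"need >= 4 matches, got {len(matches)}")
    src = np.array([[m.src.x, m.src.y] for m in matches])
    dst = np.array([[m.dst.x, m.dst.y] for m in matches])
    n = len(matches)

    if n == 4:
        if _sample_degenerate(src) or _sample_degenerate(dst):
            raise EstimationError("4-point sample is degenerate (collinear)")
        H = _dlt(src, dst)
        err = _symmetric_transfer_error(H, src, dst)
        return HomographyModel(H, np.arange(4), float(np.sqrt(np.mean(err ** 2))))

    rng = np.random.default_rng(seed)
    best_inliers: np.ndarray | None = None
    best_err = np.inf
    for _ in range(n_iter):
        idx = rng.choice(n, 4, replace=False)
        if _sample_degenerate(src[idx]) or _sample_degenerate(dst[idx]):
            continue
        try:
            H = _dlt(src[idx], dst[idx])
        except (EstimationError, np.linalg.LinAlgError):
            continue
        err = _symmetric_transfer_error(H, src, dst)
        inliers = err < ransac_thresh
        count = int(inliers.sum())
        mean_err = float(err[inliers].mean()) if count else np.inf
        if best_inliers is None or count > int(best_inliers.sum()) or (
            count == int(best_inliers.sum()) and mean_err < best_err
        ):
            best_inliers = inliers
            best_err = mean_err
    if best_inliers is None or int(best_inliers.sum()) < 4:
        raise EstimationError("RANSAC found no 4-point consensus")
    consensus = np.nonzero(best_inliers)[0]
    if _all_collinear(src[consensus]):
        raise EstimationError("consensus set is collinear")
    H = _dlt(src[consensus], dst[consensus])
    err = _symmetric_transfer_error(H, src, dst)
    inliers = err < ransac_thresh
    consensus = np.nonzero(inliers)[0]
    if consensus.size < 4:
        raise EstimationError("refit lost the consensus set")
    rms = float(np.sqrt(np.mean(err[consensus] ** 2)))
    return HomographyModel(H, consensus, rms)


def _all_collinear(pts: np.ndarray) -> bool:
    if pts.shape[0] < 3:
        return True
    centred = pts - pts.mean(axis=0)
    svals = np.linalg.svd(centred, compute_uv=False)
    return svals[1] < 1e-8


def _border_distance_weights(h: int, w: int) -> np.ndarray:
    """Distance-to-frame-border weight field (>= 1 everywhere inside)."""
    rows = np.minimum(np.arange(h), np.arange(h)[::-1])
    cols = np.minimum(np.arange(w), np.arange(w)[::-1])
    return np.minimum.outer(rows, cols).astype(np.float64) + 1.0


def stitch(src: np.ndarray, dst: np.ndarray, model: HomographyModel) -> Mosaic:
    """Warp the target frame into the source frame and blend.

    The canvas is the union bounding box of the source frame and the
    inverse-warped target frame corners.  The target is sampled bilinearly
    at ``H @ p`` for each canvas pixel ``p`` (out-of-frame samples are
    transparent, not black), and overlap is feather-blended with weights
    proportional to the distance to each frame's border.
    """
    src = np.asarray(src, dtype=np.float64)
    dst = np.asarray(dst, dtype=np.float64)
    hs, ws = src.shape
    hd, wd = dst.shape
    H = model.H
    Hinv = np.linalg.inv(H)

    corners_dst = np.array(
        [[0.0, 0.0], [wd - 1.0, 0.0], [wd - 1.0, hd - 1.0], [0.0, hd - 1.0]]
    )
    warped = apply_homography(Hinv, corners_dst)
    xs = np.r_[0.0, ws - 1.0, warped[:, 0]]
    ys = np.r_[0.0, hs - 1.0, warped[:, 1]]
    x0 = int(np.floor(xs.min()))
    y0 = int(np.floor(ys.min()))
    x1 = int(np.ceil(xs.max()))
    y1 = int(np.ceil(ys.max()))
    cw, ch = x1 - x0 + 1, y1 - y0 + 1
    if cw * ch > 20 * max(hs * ws, hd * wd):
        raise DivergentModelError(
            f"canvas {ch}x{cw} exceeds 20x the input area; model diverged"
        )

    yy, xx = np.mgrid[0:ch, 0:cw]
    fx = xx + x0  # canvas pixel position in the source frame
    fy = yy + y0

    # source layer: direct placement
    src_valid = (fx >= 0) & (fx <= ws - 1) & (fy >= 0) & (fy <= hs - 1)
    src_layer = np.zeros((ch, cw))
    src_layer[src_valid] = src[fy[src_valid], fx[src_valid]]
    w_src_frame = _border_distance_weights(hs, ws)
    w_src = np.zeros((ch, cw))
    w_src[src_valid] = w_src_frame[fy[src_valid], fx[src_valid]]

    # target layer: sample dst at H * p
    pts = np.stack([fx.ravel(), fy.ravel()], axis=1).astype(np.float64)
    mapped = apply_homography(H, pts)
    mx = mapped[:, 0].reshape(ch, cw)
    my = mapped[:, 1].reshape(ch, cw)
    dst_valid = (mx >= 0) & (mx <= wd - 1) & (my >= 0) & (my <= hd - 1)
    dst_layer = np.zeros((ch, cw))
    samp = ndimage.map_coordinates(
        dst, [my[dst_valid], mx[dst_valid]], order=1, mode="constant", cval=0.0
    )
    dst_layer[dst_valid] = samp
    # feather weight evaluated analytically in the target frame
    w_dst = np.zeros((ch, cw))
    bx = np.minimum(mx[dst_valid], wd - 1 - mx[dst_valid])
    by = np.minimum(my[dst_valid], hd - 1 - my[dst_valid])
    w_dst[dst_valid] = np.minimum(bx, by) + 1.0

    total = w_src + w_dst
    nz = total > 0
    wn_src = np.zeros((ch, cw))
    wn_dst = np.zeros((ch, cw))
    wn_src[nz] = w_src[nz] / total[nz]
    wn_dst[nz] = 1.0 - wn_src[nz]  # complement, so weights sum to 1 exactly
    canvas = wn_src * src_layer + wn_dst * dst_layer
    canvas[~nz] = 0.0

    seam = np.zeros((ch, cw), dtype=np.uint8)
    seam[src_valid & ~dst_valid] = 1
    seam[dst_valid & ~src_valid] = 2
    seam[src_valid & dst_valid] = 3
    return Mosaic(
        canvas=canvas,
        origin_shift=(x0, y0),
        seam_mask=seam,
        weights_src=wn_src,
        weights_dst=wn_dst,
    )
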