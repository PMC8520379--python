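"""Coarse descriptor matching and two-stage geometric mismatch filtering.

Coarse matches from the nearest-neighbour ratio test still contain many
mismatches.  Two geometric filters remove them:

1. **Slope-consistency pre-check.**  Both frames are placed side by side in
   one composite coordinate system (the target frame shifted right by a
   fixed offset at least the source width).  Every match then defines a
   line whose slope is ``(y' - y) / (x' + offset - x)``.  Correct matches
   produced by a smooth inter-frame motion concentrate in a narrow band of
   slopes, while mismatches scatter; the filter keeps the densest
   ``t``-neighbourhood of slopes (default t = 0.02) and deletes everything
   outside it.

2. **Disparity-gradient constraint.**  For two matches m, n with disparity
   vectors d(m), d(n) and cyclopean midpoints c(m), c(n), the disparity
   gradient ``|d(m) - d(n)| / |c(m) - c(n)|`` of mutually consistent
   matches stays below 2.  Each preselected match is compared against its
   K nearest spatial neighbours and retained only if the median gradient
   is strictly below the threshold.

Both filters are deterministic and order-invariant: permuting the input
match list never changes the retained set.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ConfigurationError, ParameterError
from .keypoint_features import Keypoint

STATUS_COARSE = "coarse"
STATUS_PRESELECTED = "preselected"
STATUS_RETAINED = "retained"
STATUS_REJECTED_SLOPE = "rejected_slope"
STATUS_REJECTED_DISPARITY = "rejected_disparity"

DISPARITY_GRADIENT_MAX = 2.0


@dataclass
class MatchPair:
    """A putative correspondence between a source and a target keypoint.

    ``slope`` is the composite-frame match-line slope (NaN until
    :func:`composite_slopes` runs); ``status`` advances monotonically
    through coarse -> preselected -> retained, or ends in one of the
    rejected states.  ``truth`` is an optional ground-truth label used by
    the synthetic benchmarks ("true" / "false").
    """

    src: Keypoint
    dst: Keypoint
    distance: float
    slope: float = math.nan
    status: str = STATUS_COARSE
    src_index: int = -1
    dst_index: int = -1
    truth: str | None = None


@dataclass
class PrescreenParams:
    """Parameters of the slope-consistency pre-check.

    ``t`` is the slope neighbourhood half-width (default 0.02, the
    empirical value); ``composite_offset`` is the horizontal shift applied
    to target-frame x coordinates and must be at least the source frame
    width so that all match-line slopes are finite.
    """

    t: float = 0.02
    composite_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.t <= 0:
            raise ParameterError(f"slope threshold t must be positive, got {self.t}")


def coarse_match(
    src_desc: np.ndarray,
    dst_desc: np.ndarray,
    ratio: float = 0.8,
    src_keypoints: list[Keypoint] | None = None,
    dst_keypoints: list[Keypoint] | None = None,
) -> list[MatchPair]:
    """Nearest-neighbour descriptor matching with Lowe's ratio test.

    For every source descriptor the nearest and second-nearest target
    descriptors (Euclidean) are found; the match is kept iff
    ``d1 / d2 < ratio``.  One-to-one assignment is enforced by keeping only
    the smallest-distance claim on each target keypoint.

    Keypoint lists are optional; when omitted, placeholder keypoints
    indexed by descriptor row are used (sufficient for the filters' own
    unit tests, not for geometry).
    """
    src_desc = np.atleast_2d(np.asarray(src_desc, dtype=np.float64))
    dst_desc = np.atleast_2d(np.asarray(dst_desc, dtype=np.float64))
    if src_desc.size == 0 or dst_desc.size == 0:
        raise ParameterError("descriptor sets must be non-empty")
    if not src_desc.any() or not dst_desc.any():
        warnings.warn("all descriptors are degenerate (zero); no matches")
        return []
    if src_keypoints is None:
        src_keypoints = [Keypoint(x=float(i), y=0.0) for i in range(len(src_desc))]
    if dst_keypoints is None:
        dst_keypoints = [Keypoint(x=float(j), y=0.0) for j in range(len(dst_desc))]

    d = cdist(src_desc, dst_desc)
    candidates: list[MatchPair] = []
    for i in range(d.shape[0]):
        row = d[i]
        if row.shape[0] == 1:
            j1, d1, d2 = 0, float(row[0]), math.inf
        else:
            j1 = int(np.argmin(row))
            d1 = float(row[j1])
            d2 = float(np.partition(row, 1)[1])
        if d1 < ratio * d2:
            candidates.append(
                MatchPair(
                    src=src_keypoints[i],
                    dst=dst_keypoints[j1],
                    distance=d1,
                    src_index=i,
                    dst_index=j1,
                )
            )
    # one-to-one: smallest distance wins each contested target keypoint
    candidates.sort(key=lambda m: (m.distance, m.src_index))
    claimed: set[int] = set()
    matches = []
    for m in candidates:
        if m.dst_index in claimed:
            continue
        claimed.add(m.dst_index)
        matches.append(m)
    matches.sort(key=lambda m: m.src_index)
    return matches


def composite_slopes(
    matches: list[MatchPair],
    params: PrescreenParams,
    src_width: float | None = None,
) -> list[MatchPair]:
    """Compute each match's line slope in the side-by-side composite frame.

    slope = (y' - y) / ((x' + offset) - x).  The offset must be at least
    the source frame width, which makes every denominator strictly positive
    and every slope finite.
    """
    if src_width is not None and params.composite_offset < src_width:
        raise ConfigurationError(
            f"composite_offset {params.composite_offset} is smaller than the "
            f"source width {src_width}"
        )
    for m in matches:
        denom = (m.dst.x + params.composite_offset) - m.src.x
        if denom <= 0:
            raise ConfigurationError(
                "composite_offset too small: non-positive match-line run"
            )
        m.slope = (m.dst.y - m.src.y) / denom
    return matches


def prescreen(matches: list[MatchPair], params: PrescreenParams) -> list[MatchPair]:
    """Slope-consistency pre-check over the coarse match set.

    Every candidate slope ``k_i`` is scored by the number of matches whose
    slope lies within ``t`` of it; the candidate with the maximal census
    wins (ties broken by smaller ``|k|``, then positive before negative
    slope, which makes the result independent of input order).  Matches in
    the winning neighbourhood become ``preselected``; all others are
    ``rejected_slope``.  With fewer than 3 matches the filter is undefined
    and passes everything through.
    """
    if len(matches) < 3:
        warnings.warn("fewer than 3 coarse matches; slope pre-check skipped")
        for m in matches:
            m.status = STATUS_PRESELECTED
        return matches
    slopes = np.array([m.slope for m in matches])
    if not np.all(np.isfinite(slopes)):
        raise ParameterError("slopes must be computed (composite_slopes) first")
    # visit candidates in tie-break priority order so the first maximal
    # census wins: smaller |k| first, then positive before negative
    order = sorted(range(len(slopes)), key=lambda i: (abs(slopes[i]), -slopes[i]))
    best_centre = None
    best_count = -1
    for i in order:
        count = int(np.sum(np.abs(slopes - slopes[i]) <= params.t))
        if count > best_count:
            best_count = count
            best_centre = slopes[i]
    keep = np.abs(slopes - best_centre) <= params.t
    for m, ok in zip(matches, keep):
        m.status = STATUS_PRESELECTED if ok else STATUS_REJECTED_SLOPE
    return matches


def _same_coords(m: MatchPair, n: MatchPair) -> bool:
    return (
        m.src.x == n.src.x
        and m.src.y == n.src.y
        and m.dst.x == n.dst.x
        and m.dst.y == n.dst.y
    )


def disparity_gradient(m: MatchPair, n: MatchPair) -> float:
    """Disparity gradient between two matches.

    ``|d(m) - d(n)| / |c(m) - c(n)|`` with disparity vectors
    ``d = dst - src`` in raw image frames and cyclopean midpoints
    ``c = (src + dst) / 2``.  Returns ``inf`` when the midpoints coincide.
    """
    if m is n or _same_coords(m, n):
        raise ParameterError("disparity gradient of a match with itself")
    ddx = (m.dst.x - m.src.x) - (n.dst.x - n.src.x)
    ddy = (m.dst.y - m.src.y) - (n.dst.y - n.src.y)
    cdx = 0.5 * ((m.src.x + m.dst.x) - (n.src.x + n.dst.x))
    cdy = 0.5 * ((m.src.y + m.dst.y) - (n.src.y + n.dst.y))
    sep = math.hypot(cdx, cdy)
    if sep == 0.0:
        return math.inf
    return math.hypot(ddx, ddy) / sep


def disparity_filter(
    matches: list[MatchPair],
    K: int = 4,
    max_gradient: float = DISPARITY_GRADIENT_MAX,
) -> list[MatchPair]:
    """Disparity-gradient consistency filter over preselected matches.

    Each preselected match is compared with its K nearest preselected
    neighbours (Euclidean distance between source keypoints) and retained
    iff the median of those disparity gradients is strictly below
    ``max_gradient`` (default 2).  With fewer than 2 preselected matches
    the filter is undefined and passes them through as retained.
    """
    pres = [m for m in matches if m.status == STATUS_PRESELECTED]
    if len(pres) < 2:
        warnings.warn("fewer than 2 preselected matches; disparity filter skipped")
        for m in pres:
            m.status = STATUS_RETAINED
        return matches
    k_eff = min(K, len(pres) - 1)
    pts = np.array([[m.src.x, m.src.y] for m in pres])
    dists = cdist(pts, pts)
    for i, m in enumerate(pres):
        # deterministic neighbour order: distance, then coordinates
        order = sorted(
            (
                j
                for j in range(len(pres))
                if j != i and not _same_coords(m, pres[j])
            ),
            key=lambda j: (dists[i, j], pts[j, 0], pts[j, 1]),
        )
        if not order:
            m.status = STATUS_RETAINED
            continue
        grads = [disparity_gradient(m, pres[j]) for j in order[:k_eff]]
        med = float(np.median(grads))
        m.status = STATUS_RETAINED if med < max_gradient else STATUS_REJECTED_DISPARITY
    return matches


def retained(matches: list[MatchPair]) -> list[MatchPair]:
    """Matches that survived both filters."""
    return [m for m in matches if m.status == STATUS_RETAINED]


def status_counts(matches: list[MatchPair]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for m in matches:
        counts[m.status] = counts.get(m.status, 0) + 1
    return counts


def dump_matches(path: str, matches: list[MatchPair]) -> None:
    """Write matches to CSV: src_x,src_y,dst_x,dst_y,distance,slope,status."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["src_x", "src_y", "dst_x", "dst_y", "distance", "slope", "status"])
        for m in matches:
            writer.writerow(
                [m.src.x, m.src.y, m.dst.x, m.dst.y, m.distance, m.slope, m.status]
            )


def filter_report(
    matches: list[MatchPair], params: PrescreenParams, K: int = 4
) -> dict:
    """JSON-serialisable report of the filter outcome."""
    slopes = [m.slope for m in matches if m.status in (STATUS_PRESELECTED, STATUS_RETAINED)]
    centre = float(np.median(slopes)) if slopes else None
    return {
        "counts": status_counts(matches),
        "winning_slope_centre": centre,
        "params": {"t": params.t, "composite_offset": params.composite_offset, "K": K},
    }
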