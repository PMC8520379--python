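"""Scale-space keypoint detection, orientation assignment and descriptors.

Keypoints are strict local extrema of the DoG stack over their 26
space-and-scale neighbours, refined to sub-pixel / sub-scale position with a
quadratic (3-D Taylor) fit, and filtered by a contrast threshold on the
interpolated DoG response and by a principal-curvature ratio test that
rejects points lying on edges.  Each surviving point receives one or more
dominant gradient orientations from a 36-bin histogram, and a 128-D
descriptor formed from a 4x4 spatial grid of 8-bin gradient-orientation
histograms, normalised, clamped at 0.2 and renormalised for robustness to
affine illumination changes.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .scale_space import ScaleSpace

# descriptor layout constants (canonical 4x4 grid x 8 orientation bins)
DESC_GRID = 4
DESC_BINS = 8
DESC_SIZE = DESC_GRID * DESC_GRID * DESC_BINS
DESC_CLAMP = 0.2

ORI_BINS = 36
ORI_PEAK_RATIO = 0.8
ORI_SIGMA_FACTOR = 1.5

BORDER = 5  # px at octave resolution; descriptor window validity
MAX_REFINE_ITER = 5


@dataclass
class Keypoint:
    """A scale-space extremum in full-resolution image coordinates.

    ``x`` is the column and ``y`` the row (0-based, sub-pixel); ``sigma`` is
    the characteristic scale in full-resolution pixels; ``orientation`` is
    the dominant gradient direction in radians in [0, 2*pi); ``response`` is
    the interpolated DoG value at the extremum; ``octave``/``level`` record
    where in the pyramid the point was found.
    """

    x: float
    y: float
    sigma: float = 1.6
    orientation: float = 0.0
    response: float = 0.0
    octave: int = 0
    level: int = 1


def _refine_extremum(
    dog: np.ndarray, l: int, r: int, c: int
) -> tuple[int, int, int, np.ndarray, float] | None:
    """Iterative 3-D quadratic localisation of a DoG extremum.

    Returns (l, r, c, offset, interpolated value) or None if the point
    drifts out of the valid interior or fails to converge in
    ``MAX_REFINE_ITER`` steps.
    """
    n_lvl, n_row, n_col = dog.shape
    for _ in range(MAX_REFINE_ITER):
        cube = dog[l - 1 : l + 2, r - 1 : r + 2, c - 1 : c + 2]
        g = 0.5 * np.array(
            [
                cube[2, 1, 1] - cube[0, 1, 1],
                cube[1, 2, 1] - cube[1, 0, 1],
                cube[1, 1, 2] - cube[1, 1, 0],
            ]
        )
        centre2 = 2.0 * cube[1, 1, 1]
        h_ll = cube[2, 1, 1] + cube[0, 1, 1] - centre2
        h_rr = cube[1, 2, 1] + cube[1, 0, 1] - centre2
        h_cc = cube[1, 1, 2] + cube[1, 1, 0] - centre2
        h_lr = 0.25 * (cube[2, 2, 1] - cube[2, 0, 1] - cube[0, 2, 1] + cube[0, 0, 1])
        h_lc = 0.25 * (cube[2, 1, 2] - cube[2, 1, 0] - cube[0, 1, 2] + cube[0, 1, 0])
        h_rc = 0.25 * (cube[1, 2, 2] - cube[1, 2, 0] - cube[1, 0, 2] + cube[1, 0, 0])
        hess = np.array([[h_ll, h_lr, h_lc], [h_lr, h_rr, h_rc], [h_lc, h_rc, h_cc]])
        try:
            offset = -np.linalg.solve(hess, g)
        except np.linalg.LinAlgError:
            return None
        if np.all(np.abs(offset) <= 0.5):
            value = cube[1, 1, 1] + 0.5 * float(g @ offset)
            return l, r, c, offset, value
        l += int(round(float(offset[0])))
        r += int(round(float(offset[1])))
        c += int(round(float(offset[2])))
        if not (
            1 <= l < n_lvl - 1
            and BORDER <= r < n_row - BORDER
            and BORDER <= c < n_col - BORDER
        ):
            return None
    return None


def _is_extremum(dog: np.ndarray, l: int, r: int, c: int) -> bool:
    """Strict maximum or minimum over the 26 space-and-scale neighbours."""
    cube = dog[l - 1 : l + 2, r - 1 : r + 2, c - 1 : c + 2]
    centre = cube[1, 1, 1]
    rest = np.delete(cube.ravel(), 13)
    return bool(centre > rest.max() or centre < rest.min())


def _passes_edge_test(dog_level: np.ndarray, r: int, c: int, edge_ratio: float) -> bool:
    """Principal-curvature ratio test on the 2x2 spatial Hessian."""
    d = dog_level
    dxx = d[r, c + 1] + d[r, c - 1] - 2.0 * d[r, c]
    dyy = d[r + 1, c] + d[r - 1, c] - 2.0 * d[r, c]
    dxy = 0.25 * (d[r + 1, c + 1] - d[r + 1, c - 1] - d[r - 1, c + 1] + d[r - 1, c - 1])
    tr = dxx + dyy
    det = dxx * dyy - dxy * dxy
    if det <= 0:
        return False
    return tr * tr * edge_ratio < det * (edge_ratio + 1.0) ** 2


def detect_extrema(
    ss: ScaleSpace,
    contrast_thresh: float = 0.03,
    edge_ratio: float = 10.0,
    max_keypoints: int | None = None,
) -> list[Keypoint]:
    """Detect refined DoG extrema across all octaves.

    A candidate must be a strict maximum or minimum over its 26 neighbours,
    survive sub-pixel refinement, have interpolated |DoG| >= contrast_thresh
    and pass the edge-ratio test tr^2/det < (r+1)^2/r with r = edge_ratio.
    Coordinates and scales are mapped back to the full-resolution frame.
    If ``max_keypoints`` is given, the strongest responses are kept.
    """
    footprint = np.ones((3, 3, 3), dtype=bool)
    footprint[1, 1, 1] = False
    keypoints: list[Keypoint] = []
    k = ss.k
    for o, dog in enumerate(ss.dogs):
        neigh_max = ndimage.maximum_filter(
            dog, footprint=footprint, mode="constant", cval=-np.inf
        )
        neigh_min = ndimage.minimum_filter(
            dog, footprint=footprint, mode="constant", cval=np.inf
        )
        cand = (dog > neigh_max) | (dog < neigh_min)
        # weak responses cannot pass the contrast test after refinement
        cand &= np.abs(dog) >= 0.5 * contrast_thresh
        cand[0] = cand[-1] = False
        cand[:, : BORDER + 1, :] = False
        cand[:, -(BORDER + 1) :, :] = False
        cand[:, :, : BORDER + 1] = False
        cand[:, :, -(BORDER + 1) :] = False
        scale = ss.octave_scale(o)
        for l, r, c in zip(*np.nonzero(cand)):
            res = _refine_extremum(dog, int(l), int(r), int(c))
            if res is None:
                continue
            li, ri, ci, offset, value = res
            # re-localised points must still be strict 26-neighbour extrema
            if (li, ri, ci) != (int(l), int(r), int(c)) and not _is_extremum(
                dog, li, ri, ci
            ):
                continue
            if abs(value) < contrast_thresh:
                continue
            if not _passes_edge_test(dog[li], ri, ci, edge_ratio):
                continue
            sigma = ss.sigma0 * ss.base_scale * (2.0 ** o) * k ** (li + offset[0])
            keypoints.append(
                Keypoint(
                    x=(ci + float(offset[2])) * scale,
                    y=(ri + float(offset[1])) * scale,
                    sigma=float(sigma),
                    response=float(value),
                    octave=o,
                    level=li,
                )
            )
    if max_keypoints is not None and len(keypoints) > max_keypoints:
        keypoints.sort(key=lambda p: -abs(p.response))
        keypoints = keypoints[:max_keypoints]
    return keypoints


def _window(
    ss: ScaleSpace, kp: Keypoint, radius: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray] | None:
    """Gradient magnitude/angle and centred offsets in a square window.

    Returns (mag, ang, drow, dcol) flattened over the clipped window around
    the keypoint at its octave resolution, or None if the window misses the
    image entirely.
    """
    scale = ss.octave_scale(kp.octave)
    g = ss.gaussians[kp.octave][kp.level]
    n_row, n_col = g.shape
    yc = kp.y / scale
    xc = kp.x / scale
    r0 = int(round(yc))
    c0 = int(round(xc))
    rlo, rhi = max(r0 - radius, 1), min(r0 + radius, n_row - 2)
    clo, chi = max(c0 - radius, 1), min(c0 + radius, n_col - 2)
    if rlo > rhi or clo > chi:
        return None
    dy, dx = ss.gradients(kp.octave, kp.level)
    sub_dy = dy[rlo : rhi + 1, clo : chi + 1]
    sub_dx = dx[rlo : rhi + 1, clo : chi + 1]
    mag = np.hypot(sub_dx, sub_dy)
    ang = np.arctan2(sub_dy, sub_dx) % (2.0 * math.pi)
    rows = np.arange(rlo, rhi + 1, dtype=np.float64) - yc
    cols = np.arange(clo, chi + 1, dtype=np.float64) - xc
    drow, dcol = np.meshgrid(rows, cols, indexing="ij")
    return mag.ravel(), ang.ravel(), drow.ravel(), dcol.ravel()


def assign_orientations(kp: Keypoint, ss: ScaleSpace) -> list[Keypoint]:
    """Dominant gradient orientation(s) of a keypoint.

    Builds a 36-bin orientation histogram of gradient angles in a Gaussian
    window of width 1.5 * sigma (at octave resolution), smooths it, and
    emits one keypoint per histogram peak at >= 0.8x the maximum, with
    parabolic interpolation of the peak position.
    """
    scale = ss.octave_scale(kp.octave)
    sigma_oct = kp.sigma / scale
    sigma_w = ORI_SIGMA_FACTOR * sigma_oct
    radius = max(int(round(3.0 * sigma_w)), 1)
    win = _window(ss, kp, radius)
    if win is None:
        return []
    mag, ang, drow, dcol = win
    weight = np.exp(-(drow ** 2 + dcol ** 2) / (2.0 * sigma_w ** 2))
    bin_width = 2.0 * math.pi / ORI_BINS
    bins = np.round(ang / bin_width).astype(int) % ORI_BINS
    hist = np.zeros(ORI_BINS)
    np.add.at(hist, bins, mag * weight)
    # circular smoothing with a binomial [1, 4, 6, 4, 1] / 16 kernel, twice
    kernel = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0
    for _ in range(2):
        hist = np.convolve(np.r_[hist[-2:], hist, hist[:2]], kernel, mode="valid")[
            : ORI_BINS
        ]
    peak = hist.max()
    if peak <= 0:
        return [replace(kp, orientation=0.0)]
    out = []
    for i in range(ORI_BINS):
        left = hist[(i - 1) % ORI_BINS]
        right = hist[(i + 1) % ORI_BINS]
        if hist[i] >= left and hist[i] >= right and hist[i] >= ORI_PEAK_RATIO * peak:
            denom = left - 2.0 * hist[i] + right
            delta = 0.0 if denom == 0 else 0.5 * (left - right) / denom
            theta = ((i + delta) * bin_width) % (2.0 * math.pi)
            out.append(replace(kp, orientation=float(theta)))
    if not out:
        out.append(replace(kp, orientation=0.0))
    return out


def compute_descriptor(kp: Keypoint, ss: ScaleSpace) -> np.ndarray:
    """128-D gradient-histogram descriptor of an oriented keypoint.

    4x4 spatial cells x 8 orientation bins relative to the keypoint
    orientation, trilinear vote interpolation, Gaussian spatial weighting;
    normalised to unit length, clamped at 0.2 and renormalised.  A window
    with no gradient energy (flat patch, or falling outside the image)
    yields the degenerate all-zero descriptor.
    """
    scale = ss.octave_scale(kp.octave)
    sigma_oct = kp.sigma / scale
    hist_width = 3.0 * sigma_oct
    radius = int(round(hist_width * math.sqrt(2.0) * (DESC_GRID + 1) * 0.5))
    radius = max(radius, 1)
    win = _window(ss, kp, radius)
    if win is None:
        return np.zeros(DESC_SIZE)
    mag, ang, drow, dcol = win
    cos_t = math.cos(kp.orientation)
    sin_t = math.sin(kp.orientation)
    c_rot = (cos_t * dcol + sin_t * drow) / hist_width
    r_rot = (-sin_t * dcol + cos_t * drow) / hist_width
    rbin = r_rot + DESC_GRID / 2.0 - 0.5
    cbin = c_rot + DESC_GRID / 2.0 - 0.5
    valid = (rbin > -1.0) & (rbin < DESC_GRID) & (cbin > -1.0) & (cbin < DESC_GRID)
    if not np.any(valid):
        return np.zeros(DESC_SIZE)
    rbin, cbin = rbin[valid], cbin[valid]
    obin = ((ang[valid] - kp.orientation) % (2.0 * math.pi)) * DESC_BINS / (
        2.0 * math.pi
    )
    w = mag[valid] * np.exp(
        -(r_rot[valid] ** 2 + c_rot[valid] ** 2) / (2.0 * (0.5 * DESC_GRID) ** 2)
    )

    hist = np.zeros((DESC_GRID + 2, DESC_GRID + 2, DESC_BINS))
    r0 = np.floor(rbin).astype(int)
    c0 = np.floor(cbin).astype(int)
    o0 = np.floor(obin).astype(int)
    fr = rbin - r0
    fc = cbin - c0
    fo = obin - o0
    for dr in (0, 1):
        wr = w * (fr if dr else 1.0 - fr)
        for dc in (0, 1):
            wc = wr * (fc if dc else 1.0 - fc)
            for do in (0, 1):
                wo = wc * (fo if do else 1.0 - fo)
                np.add.at(
                    hist,
                    (r0 + dr + 1, c0 + dc + 1, (o0 + do) % DESC_BINS),
                    wo,
                )
    vec = hist[1 : DESC_GRID + 1, 1 : DESC_GRID + 1, :].ravel()
    norm = np.linalg.norm(vec)
    if norm < 1e-12:
        return np.zeros(DESC_SIZE)
    vec = np.minimum(vec / norm, DESC_CLAMP)
    norm = np.linalg.norm(vec)
    if norm < 1e-12:
        return np.zeros(DESC_SIZE)
    return vec / norm


def detect_and_describe(
    ss: ScaleSpace,
    contrast_thresh: float = 0.03,
    edge_ratio: float = 10.0,
    max_keypoints: int | None = 600,
) -> tuple[list[Keypoint], np.ndarray]:
    """Full detector + descriptor pass over a scale space.

    Returns oriented keypoints and the matching ``(n, 128)`` descriptor
    array; degenerate all-zero descriptors are dropped.
    """
    kps = detect_extrema(ss, contrast_thresh, edge_ratio, max_keypoints)
    out_kps: list[Keypoint] = []
    out_desc: list[np.ndarray] = []
    for kp in kps:
        for okp in assign_orientations(kp, ss):
            d = compute_descriptor(okp, ss)
            if d.any():
                out_kps.append(okp)
                out_desc.append(d)
    if not out_desc:
        return [], np.zeros((0, DESC_SIZE))
    return out_kps, np.asarray(out_desc)


def dump_keypoints(
    path: str, keypoints: list[Keypoint], descriptors: np.ndarray | None = None
) -> None:
    """Write keypoints (and optionally descriptors) to a CSV file."""
    header = ["x", "y", "sigma", "orientation", "response", "octave", "level"]
    if descriptors is not None:
        header += [f"d{i}" for i in range(descriptors.shape[1])]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for i, kp in enumerate(keypoints):
            row = [kp.x, kp.y, kp.sigma, kp.orientation, kp.response, kp.octave, kp.level]
            if descriptors is not None:
                row += list(descriptors[i])
            writer.writerow(row)
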