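"""Synthetic endoscopic-like image pairs with known ground truth.

No public endoscopic stitching dataset is available, so every filter and
the end-to-end pipeline are exercised on generated frames: a band-limited
noise texture (Gaussian-filtered white noise, sigma = 3 px) carrying
smooth polyp-like blobs and a radial vignette, warped by a known
homography with an added multiplicative illumination field and sensor
noise.  The generator is fully determined by its seed, emits exact
ground-truth correspondences, and can inject a controlled fraction of
deliberately wrong matches for benchmarking the mismatch filters.

The texture reproduces the properties the detector relies on (gradient
structure at the blob scale, vignetting, illumination drift between
frames); it does not attempt photorealism.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import FixtureSpecError, ParameterError
from .keypoint_features import Keypoint
from .match_filtering import MatchPair

TEXTURE_SIGMA = 3.0  # px, band limit of the base noise texture


@dataclass
class FixtureSpec:
    """Generation parameters of one synthetic frame pair.

    ``rotation`` (degrees), ``scale``, ``translation`` (px) and
    ``perspective`` (dimensionless skew of the homography's bottom row)
    define the true inter-frame transform about the image centre;
    ``noise_sigma`` is additive Gaussian sensor noise in intensity units;
    ``illumination`` scales a smooth multiplicative illumination field
    applied to the second frame.  The seed fully determines the output.
    """

    size: tuple[int, int] = (256, 256)
    n_blobs: int = 8
    vignette_strength: float = 0.4
    rotation: float = 2.0
    scale: float = 1.0
    translation: tuple[float, float] = (20.0, 5.0)
    perspective: tuple[float, float] = (0.0, 0.0)
    noise_sigma: float = 0.005
    illumination: float = 0.05
    false_match_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.vignette_strength <= 1.0):
            raise ParameterError("vignette_strength must be in [0, 1]")
        if not (0.0 <= self.false_match_fraction <= 0.5):
            raise ParameterError("false_match_fraction must be in [0, 0.5]")
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma must be >= 0")


@dataclass
class FixturePair:
    """Two frames related by a known homography, with ground truth."""

    frame_a: np.ndarray
    frame_b: np.ndarray
    true_H: np.ndarray
    true_correspondences: np.ndarray  # (n, 4): x_a, y_a, x_b, y_b
    spec: FixtureSpec = field(default=None, repr=False)


def make_homography(
    rotation: float,
    scale: float,
    translation: tuple[float, float],
    perspective: tuple[float, float] = (0.0, 0.0),
    centre: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Similarity-plus-perspective homography about a given centre."""
    th = math.radians(rotation)
    cx, cy = centre
    R = np.array(
        [
            [scale * math.cos(th), -scale * math.sin(th), 0.0],
            [scale * math.sin(th), scale * math.cos(th), 0.0],
            [perspective[0], perspective[1], 1.0],
        ]
    )
    T_in = np.array([[1.0, 0.0, -cx], [0.0, 1.0, -cy], [0.0, 0.0, 1.0]])
    T_out = np.array(
        [
            [1.0, 0.0, cx + translation[0]],
            [0.0, 1.0, cy + translation[1]],
            [0.0, 0.0, 1.0],
        ]
    )
    H = T_out @ R @ T_in
    return H / H[2, 2]


def _base_texture(spec: FixtureSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.size
    tex = ndimage.gaussian_filter(rng.standard_normal((h, w)), TEXTURE_SIGMA)
    tex = 0.5 + 0.15 * tex / max(tex.std(), 1e-12)
    # polyp-like smooth blobs
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    for _ in range(spec.n_blobs):
        bx = rng.uniform(0.15 * w, 0.85 * w)
        by = rng.uniform(0.15 * h, 0.85 * h)
        bs = rng.uniform(5.0, 15.0)
        amp = rng.uniform(0.1, 0.25) * rng.choice([-1.0, 1.0])
        tex += amp * np.exp(-((xx - bx) ** 2 + (yy - by) ** 2) / (2.0 * bs * bs))
    # radial vignette typical of endoscopic optics
    if spec.vignette_strength > 0:
        r2 = ((xx - w / 2) / (w / 2)) ** 2 + ((yy - h / 2) / (h / 2)) ** 2
        tex *= 1.0 - spec.vignette_strength * 0.5 * r2
    return np.clip(tex, 0.0, 1.0)


def _apply_homography_pts(H: np.ndarray, pts: np.ndarray) -> np.ndarray:
    ones = np.ones((pts.shape[0], 1))
    proj = np.hstack([pts, ones]) @ H.T
    return proj[:, :2] / proj[:, 2:3]


def generate_pair(spec: FixtureSpec) -> FixturePair:
    """Generate one frame pair and its ground-truth correspondences.

    ``frame_b(q) = frame_a(H^-1 q)`` (bilinear, reflective boundary),
    optionally times a smooth illumination field, plus sensor noise.
    Correspondences are sampled on a 12 px grid of frame_a restricted to
    the region both frames observe, and satisfy ``H p = p'`` exactly
    (pre-noise).  Raises :class:`FixtureSpecError` if the homography
    leaves no overlap between the frames.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.size
    frame_a = _base_texture(spec, rng)
    H = make_homography(
        spec.rotation,
        spec.scale,
        spec.translation,
        spec.perspective,
        centre=((w - 1) / 2.0, (h - 1) / 2.0),
    )

    corners = np.array([[0.0, 0.0], [w - 1.0, 0.0], [w - 1.0, h - 1.0], [0.0, h - 1.0]])
    mapped = _apply_homography_pts(H, corners)
    if (
        mapped[:, 0].max() < 0
        or mapped[:, 0].min() > w - 1
        or mapped[:, 1].max() < 0
        or mapped[:, 1].min() > h - 1
    ):
        raise FixtureSpecError("homography maps the frame entirely outside the canvas")

    identity = np.allclose(H, np.eye(3))
    if identity:
        frame_b = frame_a.copy()
    else:
        Hinv = np.linalg.inv(H)
        yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
        pts = np.stack([xx.ravel(), yy.ravel()], axis=1)
        back = _apply_homography_pts(Hinv, pts)
        frame_b = ndimage.map_coordinates(
            frame_a, [back[:, 1], back[:, 0]], order=1, mode="reflect"
        ).reshape(h, w)
    if spec.illumination > 0:
        field = ndimage.gaussian_filter(rng.standard_normal((h, w)), min(h, w) / 4.0)
        field = field / max(np.abs(field).max(), 1e-12)
        frame_b = frame_b * (1.0 + spec.illumination * field)
    if spec.noise_sigma > 0:
        frame_b = frame_b + rng.normal(0.0, spec.noise_sigma, size=(h, w))
    if spec.illumination > 0 or spec.noise_sigma > 0:
        frame_b = np.clip(frame_b, 0.0, 1.0)

    margin = 10.0
    step = 12
    gy, gx = np.mgrid[margin : h - margin : step, margin : w - margin : step]
    pts_a = np.stack([gx.ravel(), gy.ravel()], axis=1).astype(np.float64)
    pts_b = _apply_homography_pts(H, pts_a)
    inside = (
        (pts_b[:, 0] >= margin)
        & (pts_b[:, 0] <= w - 1 - margin)
        & (pts_b[:, 1] >= margin)
        & (pts_b[:, 1] <= h - 1 - margin)
    )
    corr = np.hstack([pts_a[inside], pts_b[inside]])
    return FixturePair(
        frame_a=frame_a, frame_b=frame_b, true_H=H, true_correspondences=corr, spec=spec
    )


def inject_false_matches(
    pair: FixturePair, fraction: float, seed: int
) -> list[MatchPair]:
    """True correspondences as MatchPairs plus deliberately wrong pairs.

    Appends ``round(fraction * n)`` uniformly mislocated matches, each at
    least 10 px (reprojection) away from where the true homography would
    place its source point; every pair carries a ``truth`` label
    ("true" / "false") for benchmark scoring.
    """
    if not (0.0 <= fraction <= 0.5):
        raise ParameterError("fraction must be in [0, 0.5]")
    rng = np.random.default_rng(seed)
    h, w = pair.frame_a.shape
    matches: list[MatchPair] = []
    for xa, ya, xb, yb in pair.true_correspondences:
        matches.append(
            MatchPair(
                src=Keypoint(x=float(xa), y=float(ya)),
                dst=Keypoint(x=float(xb), y=float(yb)),
                distance=0.0,
                truth="true",
            )
        )
    n_false = round(fraction * len(pair.true_correspondences))
    for _ in range(n_false):
        xa = rng.uniform(5.0, w - 6.0)
        ya = rng.uniform(5.0, h - 6.0)
        target = _apply_homography_pts(pair.true_H, np.array([[xa, ya]]))[0]
        while True:
            xb = rng.uniform(5.0, w - 6.0)
            yb = rng.uniform(5.0, h - 6.0)
            if math.hypot(xb - target[0], yb - target[1]) >= 10.0:
                break
        matches.append(
            MatchPair(
                src=Keypoint(x=float(xa), y=float(ya)),
                dst=Keypoint(x=float(xb), y=float(yb)),
                distance=0.0,
                truth="false",
            )
        )
    return matches


PRESETS: dict[str, dict] = {
    "easy": dict(
        rotation=2.0,
        scale=1.0,
        translation=(20.0, 5.0),
        perspective=(0.0, 0.0),
        noise_sigma=0.005,
        illumination=0.05,
        vignette_strength=0.3,
    ),
    "hard": dict(
        rotation=8.0,
        scale=0.95,
        translation=(30.0, 10.0),
        perspective=(1e-5, -1e-5),
        noise_sigma=0.02,
        illumination=0.15,
        vignette_strength=0.5,
    ),
}


def preset_spec(preset: str, seed: int = 0, size: tuple[int, int] = (256, 256)) -> FixtureSpec:
    if preset not in PRESETS:
        raise ParameterError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    return FixtureSpec(size=size, seed=seed, **PRESETS[preset])


def write_fixture(pair: FixturePair, out_dir: str | os.PathLike) -> dict[str, str]:
    """Write a fixture pair to disk: 16-bit PNG frames, H and points.

    16-bit output keeps the round trip lossless enough that tests do not
    flake on quantisation.
    """
    import imageio.v3 as iio

    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    for name, frame in (("frame_a", pair.frame_a), ("frame_b", pair.frame_b)):
        p = os.path.join(out_dir, f"{name}.png")
        iio.imwrite(p, np.round(np.clip(frame, 0, 1) * 65535.0).astype(np.uint16))
        paths[name] = p
    hp = os.path.join(out_dir, "true_H.json")
    with open(hp, "w") as fh:
        json.dump({"H": pair.true_H.tolist()}, fh, indent=2)
    paths["true_H"] = hp
    cp = os.path.join(out_dir, "correspondences.csv")
    np.savetxt(
        cp,
        pair.true_correspondences,
        delimiter=",",
        header="x_a,y_a,x_b,y_b",
        comments="",
    )
    paths["correspondences"] = cp
    return paths
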