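"""Gaussian scale space and difference-of-Gaussians (DoG) pyramid.

The scale space of an image ``I(x, y)`` is the family ``L(x, y, sigma) =
G(sigma) * I`` of Gaussian-smoothed versions of the image, indexed by the
standard deviation ``sigma`` of the Gaussian kernel (the scale-space factor).
Blob-like structures of radius ~``sigma`` become extremal in the difference
of Gaussians ``D(x, y, sigma) = L(x, y, k*sigma) - L(x, y, sigma)``, where
``k`` is the constant scale ratio between adjacent levels.  The pyramid is
organised into octaves: within each octave sigma grows geometrically with
ratio ``k = 2**(1/s)`` over ``s + 3`` Gaussian levels, and each new octave
starts from the level at twice the base sigma, downsampled by a factor 2.

Coordinates are 0-based with ``x`` = column and ``y`` = row; pixel centers
sit at integer coordinates, and all scales are reported in pixels of the
full-resolution input frame.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, InputFormatError, ParameterError

#: Rec. 601 luminance weights used to collapse RGB to a single channel.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Convert an image array to a single-channel float image in [0, 1].

    Accepts 2-D arrays (already grayscale) and ``(H, W, 3)`` RGB arrays
    (an opaque alpha channel, if present, is dropped).  Integer inputs are
    divided by the maximum of their dtype; float inputs are assumed to be
    already scaled to [0, 1] and are clipped to that range.
    """
    arr = np.asarray(image)
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.ndim == 3 and arr.shape[2] == 1:
        arr = arr[:, :, 0]
    if arr.ndim not in (2, 3) or (arr.ndim == 3 and arr.shape[2] != 3):
        raise InputFormatError(
            f"expected a 2-D or (H, W, 3) image, got shape {arr.shape}"
        )
    if np.issubdtype(arr.dtype, np.integer):
        scale = float(np.iinfo(arr.dtype).max)
        arr = arr.astype(np.float64) / scale
    else:
        arr = arr.astype(np.float64)
    if not np.all(np.isfinite(arr)):
        raise InputFormatError("image contains non-finite pixel values")
    if arr.ndim == 3:
        w = np.asarray(LUMA_WEIGHTS)
        arr = arr @ w
    return np.clip(arr, 0.0, 1.0)


def load_image(path: str | os.PathLike) -> np.ndarray:
    """Read a PNG/TIFF image from disk and normalise it to grayscale [0, 1]."""
    import imageio.v3 as iio

    return to_grayscale(iio.imread(path))


def gaussian_kernel(sigma: float) -> np.ndarray:
    """Normalised 1-D Gaussian kernel truncated at radius ``ceil(4*sigma)``.

    The weights sum to 1 exactly (renormalised after truncation), so
    convolving a constant image leaves it unchanged.
    """
    if sigma <= 0:
        raise ParameterError(f"sigma must be positive, got {sigma}")
    radius = int(math.ceil(4.0 * sigma))
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def gaussian_blur(image: np.ndarray, sigma: float) -> np.ndarray:
    """Separable Gaussian convolution with reflective boundary handling.

    Reflection (rather than zero padding) avoids the dark-frame artefacts
    that zero padding produces on vignetted endoscopic images.
    """
    k = gaussian_kernel(sigma)
    img = np.asarray(image, dtype=np.float64)
    out = ndimage.convolve1d(img, k, axis=0, mode="reflect")
    out = ndimage.convolve1d(out, k, axis=1, mode="reflect")
    return out


@dataclass
class ScaleSpace:
    """Octave-organised Gaussian and DoG stacks.

    Attributes
    ----------
    gaussians:
        One ``(s + 3, H_o, W_o)`` array per octave of Gaussian levels.
    dogs:
        One ``(s + 2, H_o, W_o)`` array per octave; level ``i`` is the
        elementwise difference ``gaussians[i + 1] - gaussians[i]``.
    sigmas:
        Per-octave absolute sigma of each Gaussian level, in full-resolution
        pixels: ``sigma0 * base_scale * 2**octave * k**level``.
    base_scale:
        1.0 normally, 0.5 when the input was upsampled 2x before octave 0.
    """

    gaussians: list[np.ndarray]
    dogs: list[np.ndarray]
    sigmas: list[np.ndarray]
    s: int
    sigma0: float
    base_scale: float = 1.0
    _gradient_cache: dict = field(default_factory=dict, repr=False)

    @property
    def n_octaves(self) -> int:
        return len(self.gaussians)

    @property
    def k(self) -> float:
        """Scale ratio between adjacent levels within an octave."""
        return 2.0 ** (1.0 / self.s)

    def octave_scale(self, octave: int) -> float:
        """Pixel size of octave ``octave`` in full-resolution pixels."""
        return self.base_scale * (2.0 ** octave)

    def gradients(self, octave: int, level: int) -> tuple[np.ndarray, np.ndarray]:
        """Cached central-difference gradients (dy, dx) of a Gaussian level."""
        key = (octave, level)
        if key not in self._gradient_cache:
            g = self.gaussians[octave][level]
            dy, dx = np.gradient(g)
            self._gradient_cache[key] = (dy, dx)
        return self._gradient_cache[key]


def build_scale_space(
    image: np.ndarray,
    n_octaves: int = 4,
    s: int = 3,
    sigma0: float = 1.6,
    upsample: bool = False,
) -> ScaleSpace:
    """Build the Gaussian / DoG pyramid used for keypoint detection.

    Parameters
    ----------
    image:
        Single-channel float image; values need not be clipped (the pyramid
        is linear in intensity).
    n_octaves:
        Number of octaves; each successive octave halves both dimensions.
        The smallest octave must be at least 8x8.
    s:
        Intervals per octave; ``s + 3`` Gaussian levels are built so that
        DoG extrema can be localised over a full octave of scales.
    sigma0:
        Base smoothing of the first level of each octave.
    upsample:
        If True, bilinearly upsample the input 2x before building octave 0
        (recovers keypoints at sub-pixel scales; off by default).
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise InputFormatError("build_scale_space expects a single-channel image")
    if min(img.shape) < 16:
        raise ConfigurationError(
            f"image {img.shape} too small; need at least 16x16"
        )
    if s < 1:
        raise ParameterError(f"s must be >= 1, got {s}")
    if sigma0 <= 0:
        raise ParameterError(f"sigma0 must be positive, got {sigma0}")

    base_scale = 1.0
    if upsample:
        img = ndimage.zoom(img, 2.0, order=1, mode="reflect", grid_mode=True)
        base_scale = 0.5

    smallest = min(img.shape) // (2 ** (n_octaves - 1))
    if smallest < 8:
        raise ConfigurationError(
            f"{n_octaves} octaves leave a smallest octave of {smallest} px; "
            "need at least 8x8"
        )

    k = 2.0 ** (1.0 / s)
    n_levels = s + 3
    gaussians: list[np.ndarray] = []
    dogs: list[np.ndarray] = []
    sigmas: list[np.ndarray] = []

    base = img
    for o in range(n_octaves):
        levels = np.empty((n_levels,) + base.shape, dtype=np.float64)
        levels[0] = gaussian_blur(base, sigma0) if o == 0 else base
        for i in range(1, n_levels):
            # incremental blur: sigma_i = sigma0 * k**i within the octave
            delta = sigma0 * (k ** (i - 1)) * math.sqrt(k * k - 1.0)
            levels[i] = gaussian_blur(levels[i - 1], delta)
        gaussians.append(levels)
        dogs.append(levels[1:] - levels[:-1])
        sigmas.append(
            sigma0 * base_scale * (2.0 ** o) * k ** np.arange(n_levels)
        )
        # next octave seeds from the level at 2 * sigma0 (index s)
        base = levels[s][::2, ::2]

    return ScaleSpace(
        gaussians=gaussians,
        dogs=dogs,
        sigmas=sigmas,
        s=s,
        sigma0=sigma0,
        base_scale=base_scale,
    )


def dump_scale_space(ss: ScaleSpace, out_dir: str | os.PathLike) -> list[str]:
    """Write every Gaussian level as an 8-bit PNG for visual inspection.

    Files are named ``oct{i}_lvl{j}_sigma{sigma:.3f}.png``; returns the
    written paths.
    """
    import imageio.v3 as iio

    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for o, levels in enumerate(ss.gaussians):
        for j in range(levels.shape[0]):
            sigma = ss.sigmas[o][j]
            name = f"oct{o}_lvl{j}_sigma{sigma:.3f}.png"
            path = os.path.join(out_dir, name)
            arr = np.clip(levels[j], 0.0, 1.0)
            iio.imwrite(path, (arr * 255.0 + 0.5).astype(np.uint8))
            paths.append(path)
    return paths
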