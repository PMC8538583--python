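"""Filter bank and multilevel max-pooling image expansion.

One input image I is expanded into 42 images:

* Im1 = I, and six filtered variants Im2..Im7: rotations by 90/180/270
  degrees, a 3x3 median filter, a Gaussian filter (sigma 0.5), and
  multiplicative speckle noise of variance 0.05;
* for each of the seven, five compressed images by non-overlapping
  max-pooling with windows 2, 4, 8, 16 and 32 (levels t = 1..5).

Pooling with window 2^t over the full-resolution image is identical to t
successive 2x2 poolings because the maximum over a block factorizes; the
direct form is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi

from .imageset_io import GrayImage

#: number of pooling levels (windows 2^1 .. 2^5)
POOL_LEVELS = 5
#: bundle size: 7 source images, each at 6 scales (original + 5 pooled)
BUNDLE_SIZE = (1 + 6) * (1 + POOL_LEVELS)

DEFAULT_GAUSSIAN_SIGMA = 0.5
DEFAULT_SPECKLE_VARIANCE = 0.05


@dataclass(frozen=True)
class ImageBundle:
    """The 42 derived images of one input.

    ``ordering_map[i]`` gives, for the i-th member (0-based), its source
    index j in 1..7 (1 = original, 2..7 = filtered) and pooling level t in
    0..5 (0 = unpooled).  Member order is Im1..Im7 followed by the 35
    compressed images in source-major, level-minor order.
    """

    original: GrayImage
    filtered: tuple[GrayImage, ...]
    compressed: tuple[GrayImage, ...]

    def __post_init__(self) -> None:
        if len(self.filtered) != 6:
            raise ValueError(f"expected 6 filtered images, got {len(self.filtered)}")
        if len(self.compressed) != 7 * POOL_LEVELS:
            raise ValueError(
                f"expected {7 * POOL_LEVELS} compressed images, got {len(self.compressed)}"
            )

    def members(self) -> list[GrayImage]:
        """All 42 images in canonical order."""
        return [self.original, *self.filtered, *self.compressed]

    @property
    def ordering_map(self) -> list[tuple[int, int]]:
        """(source j in 1..7, level t in 0..5) for each of the 42 slots."""
        full = [(j, 0) for j in range(1, 8)]
        pooled = [(j, t) for j in range(1, 8) for t in range(1, POOL_LEVELS + 1)]
        return full + pooled

    def __len__(self) -> int:
        return BUNDLE_SIZE


def rotate_image(img: GrayImage, angle: int) -> GrayImage:
    """Rotate by a multiple of 90 degrees (counter-clockwise), losslessly.

    A pure index permutation: no interpolation, the pixel multiset is
    preserved.  90 and 270 degree rotations swap height and width.
    """
    if angle not in (90, 180, 270):
        raise ValueError(f"angle must be 90, 180 or 270, got {angle!r}")
    return GrayImage(np.rot90(img.pixels, k=angle // 90).copy())


def median_filter_3x3(img: GrayImage) -> GrayImage:
    """3x3 median filter with zero padding at the borders."""
    if img.height < 3 or img.width < 3:
        raise ValueError("median filter needs an image of at least 3x3")
    return GrayImage(ndi.median_filter(img.pixels, size=3, mode="constant", cval=0.0))


def gaussian_filter(img: GrayImage, sigma: float = DEFAULT_GAUSSIAN_SIGMA) -> GrayImage:
    """Gaussian smoothing with a normalized, truncated kernel.

    The kernel radius is ceil(2*sigma) per axis (a 3x3 kernel at the
    default sigma = 0.5) and borders replicate the edge pixel.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    radius = int(np.ceil(2.0 * sigma))
    out = ndi.gaussian_filter(img.pixels, sigma=sigma, mode="nearest", radius=radius)
    # separable normalized kernels can overshoot [0, 1] by rounding only
    return GrayImage(np.clip(out, 0.0, 1.0))


def gaussian_kernel(sigma: float = DEFAULT_GAUSSIAN_SIGMA) -> np.ndarray:
    """The 2-D kernel :func:`gaussian_filter` applies, for inspection/tests."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    radius = int(np.ceil(2.0 * sigma))
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    k1 = np.exp(-0.5 * (x / sigma) ** 2)
    k1 /= k1.sum()
    return np.outer(k1, k1)


def add_speckle_noise(
    img: GrayImage,
    variance: float = DEFAULT_SPECKLE_VARIANCE,
    rng: np.random.Generator | None = None,
) -> GrayImage:
    """Multiplicative (speckle) noise: ``J = I + n * I``.

    ``n`` is zero-mean uniform noise of the given variance, i.e. uniform on
    ``[-sqrt(3 v), +sqrt(3 v)]``.  The result is clipped to [0, 1].
    Deterministic given the generator state.
    """
    if variance < 0:
        raise ValueError(f"variance must be non-negative, got {variance}")
    if variance == 0:
        return GrayImage(img.pixels.copy())
    if rng is None:
        rng = np.random.default_rng()
    half = np.sqrt(3.0 * variance)
    n = rng.uniform(-half, half, size=img.pixels.shape)
    return GrayImage(np.clip(img.pixels + n * img.pixels, 0.0, 1.0))


def max_pool(img: GrayImage, window: int) -> GrayImage:
    """Non-overlapping max-pooling with a square window.

    Each output pixel is the maximum over its ``window x window`` block.
    Both image dimensions must be divisible by the window.
    """
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    h, w = img.pixels.shape
    if h % window or w % window:
        raise ValueError(
            f"image size {h}x{w} is not divisible by pooling window {window}"
        )
    blocks = img.pixels.reshape(h // window, window, w // window, window)
    return GrayImage(blocks.max(axis=(1, 3)))


def build_image_bundle(
    img: GrayImage,
    noise_rng: np.random.Generator | None = None,
    *,
    gaussian_sigma: float = DEFAULT_GAUSSIAN_SIGMA,
    speckle_variance: float = DEFAULT_SPECKLE_VARIANCE,
    pool_levels: int = POOL_LEVELS,
) -> ImageBundle:
    """Expand one image into its 42-member bundle.

    Order: the original, the six filtered variants (rotations 90/180/270,
    median, Gaussian, speckle), then the pooled images source-major and
    level-minor (source 1 levels 1..5, source 2 levels 1..5, ...).
    """
    if pool_levels != POOL_LEVELS:
        raise ValueError(f"pipeline is defined for {POOL_LEVELS} pooling levels")
    filtered = (
        rotate_image(img, 90),
        rotate_image(img, 180),
        rotate_image(img, 270),
        median_filter_3x3(img),
        gaussian_filter(img, gaussian_sigma),
        add_speckle_noise(img, speckle_variance, noise_rng),
    )
    sources = (img, *filtered)
    compressed = tuple(
        max_pool(src, 2**t)
        for src in sources
        for t in range(1, pool_levels + 1)
    )
    return ImageBundle(original=img, filtered=filtered, compressed=compressed)
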