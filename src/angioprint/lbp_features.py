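"""Uniform local-binary-pattern (LBP) features and their concatenation.

Each interior pixel is compared with its eight neighbors sampled on a
circle of radius 1 (the four diagonal positions by bilinear interpolation).
The comparison gamma(a, b) = 1 iff a - b >= 0, with a the neighbor and b
the center: a neighbor *equal* to the center counts as 1.  The eight bits
are packed most-significant-first, starting at the right neighbor and
proceeding counter-clockwise.

Codes with at most two circular 0/1 transitions are "uniform"; there are
exactly 58 of them for eight neighbors.  The histogram has 59 bins: the 58
uniform codes in ascending order, then one catch-all bin for everything
else.  Histograms are Euclidean-normalized by default.

A 42-member image bundle therefore yields a 59 * 42 = 2478-long feature
vector; feature column u + 59*(h-1) (1-based) is bin u of bundle slot h.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .imageset_io import GrayImage, SubjectDataset
from .preprocessing import BUNDLE_SIZE, ImageBundle, build_image_bundle

N_NEIGHBORS = 8
N_BINS = 59
N_FEATURES = N_BINS * BUNDLE_SIZE  # 2478

_SQ = np.sqrt(2.0) / 2.0
#: neighbor offsets (drow, dcol), right neighbor first, counter-clockwise
_OFFSETS = (
    (0.0, 1.0),
    (-_SQ, _SQ),
    (-1.0, 0.0),
    (-_SQ, -_SQ),
    (0.0, -1.0),
    (_SQ, -_SQ),
    (1.0, 0.0),
    (_SQ, _SQ),
)


def uniformity(code: int) -> int:
    """Number of circular 0<->1 transitions in an 8-bit pattern."""
    if not 0 <= code <= 255:
        raise ValueError(f"code must be an 8-bit value, got {code}")
    rotated = ((code << 1) | (code >> 7)) & 0xFF
    return bin(code ^ rotated).count("1")


def _build_bin_table() -> np.ndarray:
    """Map each 8-bit code to its histogram bin (uniform ascending, catch-all last)."""
    uniform_codes = [c for c in range(256) if uniformity(c) <= 2]
    table = np.full(256, N_BINS - 1, dtype=np.int64)
    for b, c in enumerate(uniform_codes):
        table[c] = b
    return table


_BIN_OF_CODE = _build_bin_table()
N_UNIFORM = int((_BIN_OF_CODE < N_BINS - 1).sum())  # 58


def _sample_offset(pixels: np.ndarray, dr: float, dc: float) -> np.ndarray:
    """Neighbor values at offset (dr, dc) from every interior pixel.

    Integer offsets are exact slices; fractional ones use bilinear
    interpolation on the four surrounding grid points.
    """
    h, w = pixels.shape
    r0, c0 = int(np.floor(dr)), int(np.floor(dc))
    fr, fc = dr - r0, dc - c0

    def block(ri: int, ci: int) -> np.ndarray:
        return pixels[1 + ri : h - 1 + ri, 1 + ci : w - 1 + ci]

    if fr == 0.0 and fc == 0.0:
        return block(r0, c0)
    return (
        (1 - fr) * (1 - fc) * block(r0, c0)
        + (1 - fr) * fc * block(r0, c0 + 1)
        + fr * (1 - fc) * block(r0 + 1, c0)
        + fr * fc * block(r0 + 1, c0 + 1)
    )


def _codes(pixels: np.ndarray, interpolation: str = "bilinear") -> np.ndarray:
    """LBP code at every interior pixel, vectorized."""
    center = pixels[1:-1, 1:-1]
    codes = np.zeros(center.shape, dtype=np.uint8)
    for k, (dr, dc) in enumerate(_OFFSETS):
        if interpolation == "nearest":
            dr, dc = round(dr), round(dc)
        neighbor = _sample_offset(pixels, dr, dc)
        np.bitwise_or(
            codes,
            (neighbor >= center).astype(np.uint8) << (N_NEIGHBORS - 1 - k),
            out=codes,
        )
    return codes


def lbp_code(block: np.ndarray, interpolation: str = "bilinear") -> int:
    """The 8-bit pattern code of a single 3x3 intensity block."""
    block = np.asarray(block, dtype=np.float64)
    if block.shape != (3, 3):
        raise ValueError(f"expected a 3x3 block, got shape {block.shape}")
    if not np.all(np.isfinite(block)):
        raise ValueError("block contains non-finite values")
    return int(_codes(block, interpolation)[0, 0])


@dataclass(frozen=True)
class LBPHistogram:
    """A 59-bin uniform-pattern histogram."""

    bins: np.ndarray
    normalized: bool

    def __post_init__(self) -> None:
        b = np.asarray(self.bins, dtype=np.float64)
        if b.shape != (N_BINS,):
            raise ValueError(f"expected {N_BINS} bins, got shape {b.shape}")
        object.__setattr__(self, "bins", b)


def lbp_histogram(
    img: GrayImage | np.ndarray,
    normalize: bool = True,
    interpolation: str = "bilinear",
) -> LBPHistogram:
    """59-bin uniform LBP histogram of an image.

    Unnormalized counts sum to (H-2)*(W-2); with ``normalize`` the histogram
    is scaled to unit Euclidean norm.
    """
    pixels = img.pixels if isinstance(img, GrayImage) else np.asarray(img, float)
    if pixels.shape[0] < 3 or pixels.shape[1] < 3:
        raise ValueError(
            f"image of shape {pixels.shape} is too small for 3x3 LBP blocks"
        )
    codes = _codes(pixels, interpolation)
    counts = np.bincount(
        _BIN_OF_CODE[codes.ravel()], minlength=N_BINS
    ).astype(np.float64)
    if normalize:
        counts = counts / np.linalg.norm(counts)
    return LBPHistogram(bins=counts, normalized=normalize)


@dataclass
class FeatureMatrix:
    """Per-sample concatenated LBP vectors with labels and column provenance.

    ``column_provenance[c]`` is ``(h, u)``: bundle slot h in 1..42 and
    histogram bin u in 1..59 of (0-based) column c.
    """

    values: np.ndarray
    labels: np.ndarray
    column_provenance: list[tuple[int, int]] = field(default_factory=list)
    config_hash: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2:
            raise ValueError("feature values must be a 2-D matrix")
        if len(self.labels) != self.values.shape[0]:
            raise ValueError("one label per row is required")
        if not self.column_provenance:
            self.column_provenance = default_provenance(self.values.shape[1])
        if len(self.column_provenance) != self.values.shape[1]:
            raise ValueError("one provenance entry per column is required")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def default_provenance(n_columns: int) -> list[tuple[int, int]]:
    """Column c (0-based) came from bundle slot c // 59 + 1, bin c % 59 + 1."""
    return [(c // N_BINS + 1, c % N_BINS + 1) for c in range(n_columns)]


def extract_features(
    bundle: ImageBundle,
    normalize: bool = True,
    interpolation: str = "bilinear",
) -> np.ndarray:
    """Concatenate the 42 member histograms into one 2478-long row."""
    members = bundle.members()
    if len(members) != BUNDLE_SIZE:
        raise ValueError(f"bundle has {len(members)} members, expected {BUNDLE_SIZE}")
    return np.concatenate(
        [lbp_histogram(m, normalize, interpolation).bins for m in members]
    )


def build_feature_matrix(
    ds: SubjectDataset,
    config=None,
    seed: int | None = None,
) -> FeatureMatrix:
    """Run preprocessing + LBP over a whole dataset, one row per sample.

    The speckle-noise stream is a single seeded generator advanced in
    dataset order, so the full matrix is reproducible from the seed alone.
    ``config`` is an optional :class:`~angioprint.config.PipelineConfig`;
    ``seed`` overrides its noise seed.
    """
    from .config import PipelineConfig  # deferred: config stays standalone

    cfg = config if config is not None else PipelineConfig()
    noise_seed = seed if seed is not None else cfg.noise_seed
    rng = np.random.default_rng(noise_seed)
    rows = np.empty((ds.n_images, N_FEATURES), dtype=np.float64)
    for i, img in enumerate(ds.images):
        bundle = build_image_bundle(
            img,
            rng,
            gaussian_sigma=cfg.gaussian_sigma,
            speckle_variance=cfg.speckle_variance,
            pool_levels=cfg.pool_levels,
        )
        rows[i] = extract_features(bundle, cfg.lbp_normalize, cfg.lbp_interpolation)
    return FeatureMatrix(
        values=rows,
        labels=np.array([lab for _, lab, _ in ds.samples]),
        column_provenance=default_provenance(N_FEATURES),
        config_hash=cfg.content_hash(),
    )
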