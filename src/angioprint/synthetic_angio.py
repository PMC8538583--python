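"""Synthetic angiogram phantoms: labelled vascular images for pipeline tests.

Each subject gets one random vessel tree — a connected, recursively
branching set of straight segments entering from the top image border,
with widths and contrast depths that shrink toward the periphery.  Frames
of a subject are renderings of that fixed tree under small per-frame
perturbations (similarity jitter, contrast scaling, additive Gaussian
noise), emulating repeated acquisitions of one anatomy: dark curvilinear
vessels over a bright, smoothly varying, noisy background.

Geometry is generated in the unit square with widths referenced to a
512-pixel canvas, so the same tree renders consistently at any canvas size
divisible by 32.  All randomness derives from ``numpy.random.SeedSequence``
children of a master seed: subject s uses spawn key (s,), frame f of
subject s uses (s, f), so datasets are byte-reproducible.

These phantoms are geometric, not physical: there is no projection or
fluoroscopy model, no pathology, and no inter-frame anatomy change.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.ndimage as ndi
from PIL import Image
from skimage.transform import SimilarityTransform, resize, warp

from .imageset_io import GrayImage, SubjectDataset

logger = logging.getLogger(__name__)

#: canvas size that segment widths are referenced to
REFERENCE_SIZE = 512


@dataclass(frozen=True)
class Segment:
    """One straight vessel piece, in unit-square coordinates."""

    start: tuple[float, float]  # (row, col)
    end: tuple[float, float]
    width: float  # pixels at the 512 reference size
    depth: float  # contrast depth in [0, 1]


@dataclass
class VesselTree:
    """A connected branching tree of segments for one subject."""

    segments: list[Segment]
    branching_depth: int
    subject_seed: int


@dataclass(frozen=True)
class SyntheticSpec:
    """Conditions of a synthetic identification study.

    Defaults: 12 subjects x 24 frames of 512 x 512 pixels, jitter of at
    most 2 degrees rotation and 4 pixels translation, contrast scaled
    uniformly in [0.9, 1.1], additive Gaussian noise of sigma 0.02.
    """

    n_subjects: int = 12
    frames_per_subject: int = 24
    image_size: int = 512
    max_rotation_deg: float = 2.0
    max_translation_px: float = 4.0
    contrast_range: tuple[float, float] = (0.9, 1.1)
    noise_sigma: float = 0.02
    master_seed: int = 7

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if self.frames_per_subject < 2:
            raise ValueError("need at least 2 frames per subject")
        if self.image_size % 32:
            raise ValueError("image_size must be divisible by 32")


def paper_scale_spec(**overrides) -> SyntheticSpec:
    """A 51-subject x 42-frame spec matching the public database's shape."""
    kwargs = dict(n_subjects=51, frames_per_subject=42)
    kwargs.update(overrides)
    return SyntheticSpec(**kwargs)


@dataclass(frozen=True)
class TreeParams:
    """Vessel-tree growth parameters (angles in radians, widths in px@512)."""

    depth: int = 5
    initial_width: float = 8.0
    initial_length: float = 0.28
    max_branch_angle: float = math.radians(40.0)
    length_ratio: tuple[float, float] = (0.6, 0.85)
    width_ratio: tuple[float, float] = (0.6, 0.8)
    two_child_prob: float = 0.7
    depth_range: tuple[float, float] = (0.35, 0.55)

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("branching depth must be at least 1")
        if not 6.0 - 1e-9 <= self.initial_width <= 10.0 + 1e-9:
            raise ValueError("initial width must lie in [6, 10] px")


def _clip_point(p: np.ndarray) -> np.ndarray:
    return np.clip(p, 0.02, 0.98)


def generate_subject_tree(
    subject_seed: int, params: TreeParams | None = None
) -> VesselTree:
    """Grow one random vessel tree, deterministically from ``subject_seed``.

    Recursive binary branching: each segment spawns one or two children
    whose direction is perturbed uniformly within +/-40 degrees and whose
    length and width shrink by random ratios in [0.6, 0.85] and [0.6, 0.8].
    """
    params = params or TreeParams()
    rng = np.random.default_rng(subject_seed)
    segments: list[Segment] = []

    # entry on the top border, heading downward with a random tilt
    start = np.array([0.02, rng.uniform(0.3, 0.7)])
    angle = math.pi / 2 + rng.uniform(-0.4, 0.4)  # measured from the col axis

    def grow(start: np.ndarray, angle: float, length: float, width: float,
             level: int) -> None:
        direction = np.array([math.sin(angle), math.cos(angle)])
        end = _clip_point(start + length * direction)
        depth_val = float(rng.uniform(*params.depth_range))
        segments.append(
            Segment(tuple(start), tuple(end), width, depth_val)
        )
        if level >= params.depth or width * np.mean(params.width_ratio) < 1.0:
            return
        n_children = 2 if rng.random() < params.two_child_prob else 1
        for _ in range(n_children):
            child_angle = angle + rng.uniform(
                -params.max_branch_angle, params.max_branch_angle
            )
            child_len = length * rng.uniform(*params.length_ratio)
            child_width = width * rng.uniform(*params.width_ratio)
            grow(end, child_angle, child_len, child_width, level + 1)

    grow(start, angle, params.initial_length, params.initial_width, 1)
    return VesselTree(
        segments=segments, branching_depth=params.depth, subject_seed=subject_seed
    )


def _render_depth_map(tree: VesselTree, size: int) -> np.ndarray:
    """Rasterize the tree as a contrast-depth map (0 = background).

    Per segment, an anti-aliased stroke: full depth within the half-width,
    decaying linearly over a ~0.8-pixel soft edge; overlapping segments
    combine by maximum.
    """
    depth_map = np.zeros((size, size), dtype=np.float64)
    scale = size / REFERENCE_SIZE
    edge = 0.8
    for seg in tree.segments:
        a = np.array(seg.start) * size
        b = np.array(seg.end) * size
        half_w = max(seg.width * scale, 0.8) / 2.0
        r0 = max(int(min(a[0], b[0]) - half_w - 2), 0)
        r1 = min(int(max(a[0], b[0]) + half_w + 3), size)
        c0 = max(int(min(a[1], b[1]) - half_w - 2), 0)
        c1 = min(int(max(a[1], b[1]) + half_w + 3), size)
        if r0 >= r1 or c0 >= c1:
            continue
        rr, cc = np.meshgrid(
            np.arange(r0, r1, dtype=np.float64),
            np.arange(c0, c1, dtype=np.float64),
            indexing="ij",
        )
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0.0:
            t = np.zeros_like(rr)
        else:
            t = ((rr - a[0]) * ab[0] + (cc - a[1]) * ab[1]) / denom
            t = np.clip(t, 0.0, 1.0)
        dist = np.hypot(rr - (a[0] + t * ab[0]), cc - (a[1] + t * ab[1]))
        profile = seg.depth * np.clip((half_w + edge - dist) / edge, 0.0, 1.0)
        np.maximum(depth_map[r0:r1, c0:c1], profile, out=depth_map[r0:r1, c0:c1])
    return depth_map


def _background(size: int, rng: np.random.Generator) -> np.ndarray:
    """Bright base with smooth low-frequency variation."""
    coarse = rng.uniform(-1.0, 1.0, size=(8, 8))
    return 0.75 + 0.05 * resize(coarse, (size, size), order=3, mode="edge")


def render_frame(
    tree: VesselTree,
    spec: SyntheticSpec,
    frame_rng: np.random.Generator,
    depth_map: np.ndarray | None = None,
) -> GrayImage:
    """Render one acquisition of a subject's tree.

    Pipeline: jitter the contrast-depth map by a random similarity
    transform, subtract it (scaled by a random contrast factor) from a
    bright low-frequency background, blur with sigma ~ 1, add Gaussian
    noise, clip to [0, 1].  Pass a precomputed ``depth_map`` to avoid
    re-rasterizing the same tree for every frame.
    """
    size = spec.image_size
    if depth_map is None:
        depth_map = _render_depth_map(tree, size)

    theta = math.radians(frame_rng.uniform(-spec.max_rotation_deg, spec.max_rotation_deg))
    scale_px = size / REFERENCE_SIZE
    tmax = spec.max_translation_px * scale_px
    trans = frame_rng.uniform(-tmax, tmax, size=2)
    contrast = frame_rng.uniform(*spec.contrast_range)

    center = np.array([size / 2.0, size / 2.0])
    # warp uses (x, y) = (col, row) conventions
    tform = (
        SimilarityTransform(translation=-center[::-1])
        + SimilarityTransform(rotation=theta)
        + SimilarityTransform(translation=center[::-1] + trans[::-1])
    )
    jittered = warp(depth_map, tform.inverse, order=1, mode="constant", cval=0.0)

    frame = _background(size, frame_rng) - contrast * jittered
    frame = ndi.gaussian_filter(frame, sigma=1.0, mode="nearest")
    frame = frame + frame_rng.normal(0.0, spec.noise_sigma, size=frame.shape)
    return GrayImage(np.clip(frame, 0.0, 1.0))


def vessel_mask(tree: VesselTree, size: int) -> np.ndarray:
    """Boolean mask of vessel pixels in the unjittered rendering."""
    return _render_depth_map(tree, size) > 0.0


def _subject_seed(master_seed: int, subject_index: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(subject_index,))


def generate_dataset(
    spec: SyntheticSpec,
    out_root: str | Path | None = None,
    force: bool = False,
    tree_params: TreeParams | None = None,
) -> SubjectDataset:
    """Generate a full labelled phantom dataset.

    With ``out_root`` the frames are written as 8-bit PNGs in the
    directory-per-subject layout (``subject_00/frame_000.png``...), and the
    in-memory dataset mirrors what a reload would produce (pixels quantized
    to 8 bits).  Regeneration with the same spec is byte-identical.
    Refuses to write into an existing non-empty directory unless ``force``.
    """
    root = Path(out_root) if out_root is not None else None
    if root is not None:
        if root.exists() and any(root.iterdir()) and not force:
            raise FileExistsError(
                f"output directory {root} is not empty; pass force=True to overwrite"
            )
        root.mkdir(parents=True, exist_ok=True)

    ds = SubjectDataset()
    n_digits = max(2, len(str(spec.n_subjects - 1)))
    for s in range(spec.n_subjects):
        subject_ss = _subject_seed(spec.master_seed, s)
        tree = generate_subject_tree(subject_ss, tree_params)
        depth_map = _render_depth_map(tree, spec.image_size)
        label = f"subject_{s:0{n_digits}d}"
        sdir = root / label if root is not None else None
        if sdir is not None:
            sdir.mkdir(exist_ok=True)
        for f in range(spec.frames_per_subject):
            frame_rng = np.random.default_rng(
                np.random.SeedSequence(entropy=spec.master_seed, spawn_key=(s, f))
            )
            frame = render_frame(tree, spec, frame_rng, depth_map=depth_map)
            raw = frame.to_uint8()
            path = None
            if sdir is not None:
                path = sdir / f"frame_{f:03d}.png"
                Image.fromarray(raw, mode="L").save(path)
            ds.samples.append((GrayImage.from_uint8(raw), label, path))
        logger.debug("subject %s: %d segments", label, len(tree.segments))
    return ds
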