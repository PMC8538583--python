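"""Dataset and artifact I/O.

Datasets live on disk as one directory per subject, each holding the frames
of that subject as JPEG or PNG files::

    root/
      subject_a/frame_000.png
      subject_a/frame_001.png
      subject_b/...

The directory name is the subject label.  Images are decoded to 8-bit
grayscale and rescaled to ``[0, 1]`` floats before any processing, which
fixes the scale that the multiplicative-noise filter assumes.

Feature matrices are persisted in a small self-describing binary container
with an embedded JSON header so that values, labels and per-column
provenance round-trip losslessly.
"""

from __future__ import annotations

import json
import logging
import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image, UnidentifiedImageError

logger = logging.getLogger(__name__)

#: side length must survive five halvings (window 2^5 = 32)
MIN_SIDE = 32

DEFAULT_EXTENSIONS = (".png", ".jpg", ".jpeg")

_FM_MAGIC = b"APFM0001"


class DatasetError(ValueError):
    """Raised for unreadable or structurally invalid datasets."""


class FormatError(ValueError):
    """Raised when a persisted artifact cannot be decoded."""


@dataclass(frozen=True)
class GrayImage:
    """A 2-D grayscale raster with intensities in ``[0, 1]``."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValueError(f"expected a 2-D array, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValueError("image contains non-finite intensities")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError("intensities must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @classmethod
    def from_uint8(cls, raw: np.ndarray) -> "GrayImage":
        """Build from an 8-bit raster by dividing by 255."""
        raw = np.asarray(raw)
        return cls(raw.astype(np.float64) / 255.0)

    def to_uint8(self) -> np.ndarray:
        return np.clip(np.rint(self.pixels * 255.0), 0, 255).astype(np.uint8)


@dataclass
class SubjectDataset:
    """An ordered collection of labelled grayscale images.

    ``samples`` is a list of ``(image, subject_label, source_path)`` tuples
    in deterministic (subject name, file name) order.  Integer class labels
    are assigned contiguously (1..n_subjects) in sorted label order.
    """

    samples: list[tuple[GrayImage, str, Path | None]] = field(default_factory=list)

    @property
    def n_images(self) -> int:
        return len(self.samples)

    @property
    def label_names(self) -> list[str]:
        return sorted({lab for _, lab, _ in self.samples})

    @property
    def n_subjects(self) -> int:
        return len(self.label_names)

    @property
    def labels(self) -> np.ndarray:
        """Contiguous integer labels, 1..n_subjects, in sample order."""
        index = {name: i + 1 for i, name in enumerate(self.label_names)}
        return np.array([index[lab] for _, lab, _ in self.samples], dtype=np.int64)

    @property
    def images(self) -> list[GrayImage]:
        return [img for img, _, _ in self.samples]


def _decode_grayscale(path: Path) -> np.ndarray:
    """Decode one raster file to an 8-bit grayscale array.

    RGB-encoded grayscale is accepted: color inputs are reduced by the
    standard luma transform (ITU-R 601-2, as used by Pillow's ``"L"`` mode).
    """
    try:
        with Image.open(path) as im:
            if im.mode != "L":
                im = im.convert("L")
            return np.asarray(im, dtype=np.uint8)
    except (UnidentifiedImageError, OSError, SyntaxError) as exc:
        raise DatasetError(f"cannot decode image file {path}: {exc}") from exc


def _conform_size(raw: np.ndarray, path: Path) -> np.ndarray:
    """Center-crop to the largest size with both sides >= 32 and divisible by 32."""
    h, w = raw.shape
    if h < MIN_SIDE or w < MIN_SIDE:
        raise DatasetError(
            f"image {path} is {h}x{w}; both sides must be at least {MIN_SIDE}"
        )
    nh, nw = (h // MIN_SIDE) * MIN_SIDE, (w // MIN_SIDE) * MIN_SIDE
    if (nh, nw) != (h, w):
        logger.warning("center-cropping %s from %dx%d to %dx%d", path, h, w, nh, nw)
        top, left = (h - nh) // 2, (w - nw) // 2
        raw = raw[top : top + nh, left : left + nw]
    return raw


def load_dataset(
    root_directory: str | Path,
    extensions: Sequence[str] = DEFAULT_EXTENSIONS,
) -> SubjectDataset:
    """Load a directory-per-subject image tree.

    Subjects are the immediate subdirectories of ``root_directory``; frames
    are the files within them whose suffix matches ``extensions``
    (case-insensitive).  Loading order is sorted by (subject directory name,
    file name), so two loads of the same tree are identical.

    Raises
    ------
    DatasetError
        If the root has no subject subdirectories, or any file fails to
        decode.  A subject with fewer than two frames only triggers a
        warning here; cross-validation re-validates class sizes.
    """
    root = Path(root_directory)
    if not root.is_dir():
        raise DatasetError(f"dataset root {root} is not a directory")
    subject_dirs = sorted(p for p in root.iterdir() if p.is_dir())
    if not subject_dirs:
        raise DatasetError(f"no subjects: {root} contains no subdirectories")

    exts = {e.lower() if e.startswith(".") else "." + e.lower() for e in extensions}
    ds = SubjectDataset()
    for sdir in subject_dirs:
        files = sorted(p for p in sdir.iterdir() if p.suffix.lower() in exts)
        if not files:
            raise DatasetError(f"subject directory {sdir} contains no image files")
        if len(files) < 2:
            warnings.warn(
                f"subject {sdir.name!r} has only {len(files)} frame(s); "
                "cross-validation folds are undefined for it",
                stacklevel=2,
            )
        for f in files:
            raw = _conform_size(_decode_grayscale(f), f)
            ds.samples.append((GrayImage.from_uint8(raw), sdir.name, f))
    return ds


# ---------------------------------------------------------------------------
# Feature-matrix container
# ---------------------------------------------------------------------------

def save_feature_matrix(fm, path: str | Path) -> None:
    """Persist a feature matrix losslessly.

    Container layout: magic bytes, an 8-byte little-endian header length, a
    JSON header (shape, labels, per-column provenance, config hash), then
    the raw C-order float64 value bytes.
    """
    path = Path(path)
    values = np.ascontiguousarray(fm.values, dtype=np.float64)
    header = {
        "shape": list(values.shape),
        "labels": [str(l) for l in fm.labels],
        "column_provenance": [list(map(int, p)) for p in fm.column_provenance],
        "config_hash": fm.config_hash,
    }
    blob = json.dumps(header).encode("utf-8")
    with open(path, "wb") as fh:
        fh.write(_FM_MAGIC)
        fh.write(struct.pack("<Q", len(blob)))
        fh.write(blob)
        fh.write(values.tobytes())


def load_feature_matrix(path: str | Path):
    """Load a feature matrix written by :func:`save_feature_matrix`."""
    from .lbp_features import FeatureMatrix  # deferred: avoids import cycle

    path = Path(path)
    data = path.read_bytes()
    if len(data) < len(_FM_MAGIC) + 8 or data[: len(_FM_MAGIC)] != _FM_MAGIC:
        raise FormatError(f"{path} is not a feature-matrix container")
    off = len(_FM_MAGIC)
    (hlen,) = struct.unpack_from("<Q", data, off)
    off += 8
    if off + hlen > len(data):
        raise FormatError(f"{path}: truncated header")
    try:
        header = json.loads(data[off : off + hlen].decode("utf-8"))
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: corrupt header: {exc}") from exc
    off += hlen
    shape = tuple(header["shape"])
    expected = int(np.prod(shape)) * 8
    payload = data[off:]
    if len(payload) != expected:
        raise FormatError(
            f"{path}: payload has {len(payload)} bytes, expected {expected} "
            f"for shape {shape}"
        )
    values = np.frombuffer(payload, dtype=np.float64).reshape(shape).copy()
    return FeatureMatrix(
        values=values,
        labels=np.array(header["labels"]),
        column_provenance=[tuple(p) for p in header["column_provenance"]],
        config_hash=header.get("config_hash", ""),
    )
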