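"""Pipeline configuration: one flat, sectioned, human-readable document.

Every default the method leaves open (filter parameters, LBP variant, NCA
optimizer settings, CV construction, phantom-generator conditions) is a
named field here, so a run is fully described by its config plus seeds.
The content hash identifies a configuration for provenance: it changes iff
any field changes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

_SECTIONS = {
    "preprocessing": ("gaussian_sigma", "median_window", "speckle_variance",
                      "pool_levels", "noise_seed"),
    "lbp": ("lbp_radius", "lbp_neighbors", "lbp_interpolation", "lbp_normalize"),
    "nca": ("nca_lambda", "nca_sigma", "nca_epochs", "nca_lr", "nca_seed",
            "select_fraction", "nested_selection"),
    "cv": ("cv_folds", "cv_neighbors", "cv_standardize", "cv_stratified", "cv_seed"),
    "synth": ("synth_subjects", "synth_frames", "synth_image_size",
              "synth_max_rotation_deg", "synth_max_translation_px",
              "synth_contrast_range", "synth_noise_sigma", "synth_master_seed"),
}


@dataclass
class PipelineConfig:
    # preprocessing
    gaussian_sigma: float = 0.5
    median_window: int = 3
    speckle_variance: float = 0.05
    pool_levels: int = 5
    noise_seed: int = 42
    # lbp
    lbp_radius: int = 1
    lbp_neighbors: int = 8
    lbp_interpolation: str = "bilinear"
    lbp_normalize: bool = True
    # nca (lambda None means 1/n_samples at fit time)
    nca_lambda: float | None = None
    nca_sigma: float = 1.0
    nca_epochs: int = 20
    nca_lr: float = 0.1
    nca_seed: int = 0
    select_fraction: float = 1.0 / 6.0
    nested_selection: bool = False
    # cv
    cv_folds: int = 10
    cv_neighbors: int = 1
    cv_standardize: bool = True
    cv_stratified: bool = True
    cv_seed: int = 0
    # synthetic generator
    synth_subjects: int = 12
    synth_frames: int = 24
    synth_image_size: int = 512
    synth_max_rotation_deg: float = 2.0
    synth_max_translation_px: float = 4.0
    synth_contrast_range: tuple = (0.9, 1.1)
    synth_noise_sigma: float = 0.02
    synth_master_seed: int = 7

    def to_dict(self) -> dict:
        d = asdict(self)
        d["synth_contrast_range"] = list(d["synth_contrast_range"])
        return d

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode("utf-8")
        return hashlib.sha256(blob).hexdigest()[:16]

    def save(self, path: str | Path) -> None:
        doc = {
            section: {k: self.to_dict()[k] for k in keys}
            for section, keys in _SECTIONS.items()
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text())
        flat: dict = {}
        for section_values in doc.values():
            flat.update(section_values)
        valid = {f.name for f in fields(cls)}
        unknown = set(flat) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "synth_contrast_range" in flat:
            flat["synth_contrast_range"] = tuple(flat["synth_contrast_range"])
        return cls(**flat)

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        valid = {f.name for f in fields(self)}
        unknown = set(kwargs) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = {**{f.name: getattr(self, f.name) for f in fields(self)}, **kwargs}
        return PipelineConfig(**d)
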