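"""Shared fixtures.

The heavy fixture (`default_run`) executes the full pipeline once on the
default 12-subject x 24-frame phantom study and is shared by every test
that needs it, so the end-to-end cost is paid a single time per session.
"""

from __future__ import annotations

import numpy as np
import pytest

from angioprint.classify_eval import evaluate_features
from angioprint.config import PipelineConfig
from angioprint.lbp_features import build_feature_matrix
from angioprint.synthetic_angio import SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """A quick 6-subject x 12-frame phantom set at 128 px."""
    spec = SyntheticSpec(
        n_subjects=6, frames_per_subject=12, image_size=128, master_seed=7
    )
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def default_run():
    """Feature matrix + evaluation report of the default phantom study.

    Conditions: 12 subjects x 24 frames, 512 x 512 px, generator master
    seed 7, default pipeline configuration.
    """
    cfg = PipelineConfig()
    spec = SyntheticSpec(
        n_subjects=cfg.synth_subjects,
        frames_per_subject=cfg.synth_frames,
        image_size=cfg.synth_image_size,
        max_rotation_deg=cfg.synth_max_rotation_deg,
        max_translation_px=cfg.synth_max_translation_px,
        contrast_range=cfg.synth_contrast_range,
        noise_sigma=cfg.synth_noise_sigma,
        master_seed=cfg.synth_master_seed,
    )
    ds = generate_dataset(spec)
    fm = build_feature_matrix(ds, cfg)
    report = evaluate_features(fm, cfg)
    return {"dataset": ds, "features": fm, "report": report, "config": cfg}
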