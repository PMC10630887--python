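"""Shared fixtures: small synthetic movies and slides with ground truth."""

import numpy as np
import pytest

from avatarquant import (
    AvatarConfig,
    SlideConfig,
    generate_avatar_movie,
    generate_ihc_slide,
)


@pytest.fixture(scope="session")
def small_movie():
    """One-frame artefact-free movie on the full default grid."""
    cfg = AvatarConfig(
        shape=(1, 40, 256, 256), seed=7, autofluorescence_density=0.0
    )
    movie, truth = generate_avatar_movie(cfg)
    return cfg, movie, truth


@pytest.fixture(scope="session")
def af_movie():
    """Two-frame movie with autofluorescent blobs on a reduced grid."""
    cfg = AvatarConfig(
        shape=(2, 24, 160, 160),
        seed=5,
        n_round=4,
        n_ramified=2,
        tumor_start_volume_um3=3.0e4,
        autofluorescence_density=0.15,
    )
    movie, truth = generate_avatar_movie(cfg)
    return cfg, movie, truth


@pytest.fixture(scope="session")
def slide():
    cfg = SlideConfig(seed=3)
    images, prestain, truth = generate_ihc_slide(cfg)
    return cfg, images, prestain, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
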