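"""Generator contracts: counts, schedules, determinism, label partition,
and the geometric fidelity loop closed through the morphometrics module."""

import numpy as np
import pandas as pd
import pytest

from avatarquant import (
    AvatarConfig,
    DistanceLaw,
    PlacementError,
    SlideConfig,
    compute_morphometrics,
    generate_annotation_volume,
    generate_avatar_movie,
    generate_ihc_slide,
)
from avatarquant.errors import DataError
from avatarquant.preprocess import CLASS_CODES


def test_requested_gam_counts_per_frame():
    cfg = AvatarConfig(
        shape=(3, 40, 256, 256), seed=1, n_round=10, n_ramified=5,
        autofluorescence_density=0.0,
    )
    _, truth = generate_avatar_movie(cfg)
    counts = truth.gams["shape_class"].value_counts()
    assert counts["round"] == 10
    assert counts["ramified"] == 5
    for t in range(3):
        frame = truth.distances[truth.distances["frame"] == t]
        assert (frame["shape_class"] == "round").sum() == 10
        assert (frame["shape_class"] == "ramified").sum() == 5


def test_tumor_volume_schedule_is_exact():
    cfg = AvatarConfig(
        shape=(2, 40, 256, 256), seed=2, tumor_volume_multiplier=0.5,
        autofluorescence_density=0.0,
    )
    _, truth = generate_avatar_movie(cfg)
    v0, v1 = truth.tumor_volumes_um3
    voxel_volume = np.prod(truth.spacing)
    assert abs(v1 - 0.5 * v0) <= voxel_volume


def test_same_config_and_seed_is_bit_identical():
    cfg = dict(shape=(1, 24, 128, 128), seed=9, n_round=3, n_ramified=2,
               tumor_start_volume_um3=2e4)
    m1, t1 = generate_avatar_movie(AvatarConfig(**cfg))
    m2, t2 = generate_avatar_movie(AvatarConfig(**cfg))
    assert m1.data.tobytes() == m2.data.tobytes()
    pd.testing.assert_frame_equal(t1.gams, t2.gams)
    pd.testing.assert_frame_equal(t1.distances, t2.distances)


def test_annotation_volume_partitions_the_grid(af_movie):
    _, _, truth = af_movie
    ann = generate_annotation_volume(truth, 0)
    counts = {k: int((ann == v).sum()) for k, v in CLASS_CODES.items()}
    assert sum(counts.values()) == ann.size
    # tumor voxels labelled tumor, autofluorescence outside tumor/gam kept
    assert np.all(ann[truth.tumor_masks[0]] == CLASS_CODES["tumor"])
    af_only = truth.af_mask & ~truth.tumor_masks[0] & (truth.gam_labels_3d == 0)
    assert np.all(ann[af_only] == CLASS_CODES["autofluorescence"])
    with pytest.raises(DataError):
        generate_annotation_volume(truth, truth.n_frames)


def test_phantom_circularity_matches_class_definitions(small_movie):
    """Round phantoms project above 0.6 and ramified below 0.35, measured
    with the same morphometrics operator the classifier uses."""
    _, _, truth = small_movie
    dets = {d.instance_id: d for d in compute_morphometrics(truth.gam_labels_2d())}
    for _, g in truth.gams.iterrows():
        c = dets[int(g["gam_id"])].circularity
        if g["shape_class"] == "round":
            assert c > 0.6
        else:
            assert c < 0.35


def test_distance_law_controls_proximity_fraction():
    cfg = AvatarConfig(
        shape=(1, 40, 256, 256), seed=4, n_round=5, n_ramified=3,
        distance_law=DistanceLaw(frac_near=1.0),
        autofluorescence_density=0.0,
    )
    _, truth = generate_avatar_movie(cfg)
    # placement distance is drawn <= 30; the recorded true distance uses the
    # rasterized phantom's centroid, which can sit a soma radius further out
    assert (truth.distances["distance_um"] <= 33.0).all()
    assert (truth.distances["distance_um"] <= 30.0).mean() > 0.8


def test_true_distance_zero_iff_center_in_tumor(small_movie):
    _, _, truth = small_movie
    d0 = truth.distances[truth.distances["frame"] == 0].set_index("gam_id")
    for gid, row in d0.iterrows():
        g = truth.gams.set_index("gam_id").loc[gid]
        inside = (
            np.linalg.norm(
                np.array([g["z_um"], g["y_um"], g["x_um"]])
                - truth.tumor_center_um
            )
            <= truth.tumor_radii_um[0]
        )
        assert (row["distance_um"] == 0.0) == bool(inside)


def test_overcrowded_grid_raises_placement_error():
    cfg = AvatarConfig(
        shape=(1, 16, 64, 64), seed=0, n_round=200, n_ramified=0,
        tumor_start_volume_um3=5e3,
    )
    with pytest.raises(PlacementError, match="round"):
        generate_avatar_movie(cfg)


def test_config_validation():
    with pytest.raises(DataError):
        AvatarConfig(n_round=-1)
    with pytest.raises(DataError):
        AvatarConfig(tumor_volume_multiplier=0.0)
    with pytest.raises(DataError):
        AvatarConfig(autofluorescence_density=1.5)
    with pytest.raises(DataError):
        AvatarConfig(spacing=(0.0, 1.0, 1.0))


# --- IHC slides -----------------------------------------------------------

def test_slide_sox2_fraction_by_construction():
    cfg = SlideConfig(seed=1, n_cells=50, sox2_positive_fraction=0.4)
    _, _, truth = generate_ihc_slide(cfg)
    assert len(truth.cells) == 50
    assert truth.cells["sox2_positive"].sum() == 20


def test_slide_prestain_equals_background_exactly(slide):
    _, _, prestain, truth = slide
    assert np.array_equal(prestain, truth.background)


def test_slide_zero_effect_means_equal_in_expectation():
    pos_means, neg_means = [], []
    for seed in range(12):
        cfg = SlideConfig(seed=seed, gal1_effect=0.0, n_cells=40)
        _, _, truth = generate_ihc_slide(cfg)
        cells = truth.cells
        pos_means.append(cells[cells.sox2_positive]["gal1_mean"].mean())
        neg_means.append(cells[~cells.sox2_positive]["gal1_mean"].mean())
    # both populations draw from the same law; sample means agree closely
    assert abs(np.mean(pos_means) - np.mean(neg_means)) < 2.0


def test_slide_determinism_and_placement_error():
    a = generate_ihc_slide(SlideConfig(seed=5))
    b = generate_ihc_slide(SlideConfig(seed=5))
    assert a[0]["dapi"].tobytes() == b[0]["dapi"].tobytes()
    with pytest.raises(PlacementError, match="nucleus"):
        generate_ihc_slide(SlideConfig(seed=0, shape=(64, 64), n_cells=500))
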