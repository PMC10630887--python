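"""Anisotropic distance maps, 3D center inference, and proximity filters."""

import numpy as np
import pandas as pd
import pytest

from avatarquant import (
    TumorMask,
    filter_within,
    gam_distances,
    infer_z_centers,
    tumor_distance_map,
)
from avatarquant.errors import DataError


def brute_force_distance_map(mask, spacing):
    """O(N*M) nearest-tumor-voxel search between voxel centers."""
    tumor = np.argwhere(mask) * np.asarray(spacing)
    out = np.zeros(mask.shape)
    for idx in np.ndindex(mask.shape):
        p = np.asarray(idx) * np.asarray(spacing)
        out[idx] = np.min(np.linalg.norm(tumor - p, axis=1))
    return out


def single_voxel_mask(shape=(12, 12, 12), at=(0, 0, 0), spacing=(1, 1, 1)):
    m = np.zeros(shape, dtype=bool)
    m[at] = True
    return TumorMask(mask=m, spacing=spacing)


def test_axis_aligned_distances():
    dmap = tumor_distance_map(single_voxel_mask())
    assert dmap.values[0, 0, 5] == pytest.approx(5.0)
    dmap_z = tumor_distance_map(single_voxel_mask(spacing=(2.0, 1.0, 1.0)))
    assert dmap_z.values[3, 0, 0] == pytest.approx(6.0)


@pytest.mark.parametrize("spacing", [(1, 1, 1), (3.0, 0.8, 0.8)])
def test_distance_map_equals_brute_force_oracle(rng, spacing):
    mask = rng.random((14, 14, 14)) < 0.02
    mask[7, 7, 7] = True  # never empty
    tm = TumorMask(mask=mask, spacing=spacing)
    dmap = tumor_distance_map(tm)
    oracle = brute_force_distance_map(mask, spacing)
    assert np.allclose(dmap.values, oracle, atol=1e-6)
    assert np.all(dmap.values[mask] == 0)


def test_empty_mask_raises():
    tm = TumorMask(mask=np.zeros((4, 4, 4), bool), spacing=(1, 1, 1))
    with pytest.raises(DataError, match="empty"):
        tumor_distance_map(tm)


def test_translation_invariance(rng):
    mask = np.zeros((16, 16, 16), dtype=bool)
    mask[4:7, 5:8, 6:9] = True
    tm1 = TumorMask(mask, (1.5, 1.0, 1.0))
    tm2 = TumorMask(np.roll(mask, (2, 3, 1), axis=(0, 1, 2)), (1.5, 1.0, 1.0))
    d1 = tumor_distance_map(tm1).values
    d2 = tumor_distance_map(tm2).values
    assert np.allclose(np.roll(d1, (2, 3, 1), axis=(0, 1, 2))[4:12, 4:12, 4:12],
                       d2[4:12, 4:12, 4:12])


def test_isotropic_point_distance_is_euclidean_norm():
    dmap = tumor_distance_map(single_voxel_mask(at=(2, 3, 4)))
    assert dmap.values[5, 7, 8] == pytest.approx(np.linalg.norm([3, 4, 4]))


# --- center inference -----------------------------------------------------

def test_single_slice_signal_gives_exact_z():
    vol = np.zeros((10, 20, 20))
    lab = np.zeros((20, 20), np.int32)
    lab[8:12, 8:12] = 1
    vol[6, 8:12, 8:12] = 50.0
    centers = infer_z_centers(lab, vol, spacing=(2.0, 1.0, 1.0))
    assert centers.loc[0, "z_vox"] == pytest.approx(6.0)
    assert centers.loc[0, "z_um"] == pytest.approx(12.0)
    assert not centers.loc[0, "low_confidence"]


def test_spherical_phantom_z_within_one_slice(small_movie):
    from avatarquant import match_instances_iou, max_project, segment_gams_2d

    cfg, movie, truth = small_movie
    gam = movie.channel("gam", 0)
    labels = segment_gams_2d(max_project(gam))
    centers = infer_z_centers(labels, gam, cfg.spacing)
    res = match_instances_iou(labels, truth.gam_labels_2d(), iou_threshold=0.3)
    truth_z = truth.gams.set_index("gam_id")["z_vox"]
    by_id = centers.set_index("instance_id")
    errs = [abs(by_id.loc[p, "z_vox"] - truth_z[t]) for p, t, _ in res.pairs]
    assert max(errs) <= 1.0


def test_two_phantoms_stacked_in_z_are_flagged():
    vol = np.zeros((20, 16, 16))
    lab = np.zeros((16, 16), np.int32)
    lab[6:10, 6:10] = 1
    vol[4, 6:10, 6:10] = 80.0
    vol[14, 6:10, 6:10] = 80.0
    centers = infer_z_centers(lab, vol, spacing=(1, 1, 1))
    assert centers.loc[0, "low_confidence"]
    assert 4.0 < centers.loc[0, "z_vox"] < 14.0


def test_z_inference_validation():
    vol = np.zeros((4, 8, 8))
    with pytest.raises(DataError):
        infer_z_centers(np.zeros((9, 9), np.int32), vol, (1, 1, 1))
    with pytest.raises(DataError):
        infer_z_centers(np.zeros((8, 8), np.int32), vol, (1, 1, 1),
                        method="psychic")


# --- distance lookup and proximity filter ---------------------------------

def test_center_in_tumor_reports_zero_distance():
    mask = np.zeros((8, 8, 8), dtype=bool)
    mask[3:5, 3:5, 3:5] = True
    dmap = tumor_distance_map(TumorMask(mask, (1, 1, 1)))
    centers = pd.DataFrame(
        [{"instance_id": 1, "z_vox": 3.0, "y_vox": 4.0, "x_vox": 4.0}]
    )
    out = gam_distances(centers, dmap)
    assert out.loc[0, "distance_um"] == 0.0


def test_distance_lookup_and_out_of_grid():
    dmap = tumor_distance_map(single_voxel_mask())
    centers = pd.DataFrame(
        [{"instance_id": 1, "z_vox": 0.0, "y_vox": 0.0, "x_vox": 5.0}]
    )
    assert gam_distances(centers, dmap).loc[0, "distance_um"] == 5.0
    bad = pd.DataFrame(
        [{"instance_id": 1, "z_vox": -3.0, "y_vox": 0.0, "x_vox": 0.0}]
    )
    with pytest.raises(DataError, match="outside"):
        gam_distances(bad, dmap)


def test_filter_within_boundary_inclusive():
    rec = pd.DataFrame({"distance_um": [0.0, 29.9, 30.0, 30.1]})
    assert len(filter_within(rec)) == 3
    assert len(filter_within(rec, radius_um=0.0)) == 1
    assert len(filter_within(rec.iloc[0:0])) == 0
    with pytest.raises(DataError):
        filter_within(rec, radius_um=-1.0)
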