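"""Slide quantification: registration, background correction, nucleus
segmentation, per-cell scoring and patient-level GAL1 summaries."""

import numpy as np
import pandas as pd
import pytest

from avatarquant import (
    expand_labels,
    match_instances_iou,
    patient_gal1_scores,
    quantile_normalize,
    register_images,
    rolling_ball,
    score_cells,
    segment_nuclei,
    subtract_prestain,
)
from avatarquant.errors import (
    DataError,
    DegenerateInputError,
    RegistrationError,
)
from avatarquant.ihc import sox2_masked_gal1, trim_z


@pytest.fixture(scope="module")
def textured_image():
    rng = np.random.default_rng(1)
    img = np.zeros((200, 200))
    yy, xx = np.mgrid[:200, :200]
    for _ in range(40):
        cy, cx = rng.uniform(20, 180, 2)
        img += rng.uniform(50, 150) * np.exp(
            -(((yy - cy) ** 2 + (xx - cx) ** 2) / 18.0)
        )
    return img


# --- registration ---------------------------------------------------------

def test_self_registration_is_identity(textured_image):
    model, _ = register_images(textured_image, textured_image)
    H = model.params / model.params[2, 2]
    assert np.abs(H - np.eye(3)).max() < 1e-3


def test_translation_recovered_within_half_pixel(textured_image):
    moving = np.roll(textured_image, (6, 9), axis=(0, 1))
    model, warped = register_images(moving, textured_image)
    # homography maps moving (x, y) onto fixed (x, y)
    assert model.params[0, 2] == pytest.approx(-9.0, abs=0.5)
    assert model.params[1, 2] == pytest.approx(-6.0, abs=0.5)
    interior = (slice(20, 180), slice(20, 180))
    assert np.abs(warped[interior] - textured_image[interior]).max() < 1e-6


def test_featureless_image_fails_registration(textured_image):
    with pytest.raises(RegistrationError):
        register_images(np.zeros((100, 100)), textured_image)


# --- rolling ball ---------------------------------------------------------

def test_rolling_ball_flattens_constant():
    out = rolling_ball(np.full((60, 60), 37.0), radius=15)
    assert np.allclose(out, 0.0)


def test_rolling_ball_preserves_small_spot():
    img = np.full((80, 80), 40.0)
    img[40, 40] += 100.0
    out = rolling_ball(img, radius=20)
    assert out[40, 40] == pytest.approx(100.0, rel=0.05)


def test_rolling_ball_removes_gradient_background(rng):
    yy, xx = np.mgrid[:120, :120]
    gradient = 30.0 + 0.3 * xx
    img = gradient.copy()
    spots = [(30, 30), (60, 90), (90, 45)]
    for cy, cx in spots:
        img[cy - 2:cy + 3, cx - 2:cx + 3] += 120.0
    out = rolling_ball(img, radius=25)
    off_spot = np.ones_like(img, dtype=bool)
    for cy, cx in spots:
        off_spot[cy - 6:cy + 7, cx - 6:cx + 7] = False
    assert out[off_spot].max() < 0.05 * (gradient.max() - gradient.min())


def test_rolling_ball_radius_validation():
    with pytest.raises(DataError):
        rolling_ball(np.zeros((50, 50)), radius=60)
    with pytest.raises(DataError):
        rolling_ball(np.zeros((50, 50)), radius=0)


# --- pre-stain subtraction ------------------------------------------------

def test_prestain_trivial_cases(rng):
    img = rng.uniform(0, 100, (30, 30))
    assert np.allclose(subtract_prestain(img, img), 0.0)
    assert np.allclose(subtract_prestain(img, np.zeros_like(img)), img)
    with pytest.raises(DataError):
        subtract_prestain(img, img[:10])


def test_prestain_subtraction_improves_marker_correlation(slide):
    _, images, prestain, truth = slide
    gal1_truth = np.zeros_like(prestain)
    lab = truth.nucleus_labels
    for _, c in truth.cells.iterrows():
        gal1_truth[lab == c["cell_id"]] = c["gal1_mean"]
    raw = images["gal1"].ravel()
    corrected = subtract_prestain(images["gal1"], prestain).ravel()
    gt = gal1_truth.ravel()
    assert np.corrcoef(corrected, gt)[0, 1] > np.corrcoef(raw, gt)[0, 1]


# --- quantile normalization ----------------------------------------------

def test_quantile_normalize_examples():
    a, b = quantile_normalize([np.array([1.0, 2, 3]), np.array([4.0, 5, 6])])
    assert np.allclose(a, [2.5, 3.5, 4.5]) and np.allclose(b, [2.5, 3.5, 4.5])
    same = np.array([3.0, 1.0, 2.0])
    x, y = quantile_normalize([same, same.copy()])
    assert np.allclose(x, same) and np.allclose(y, same)


def test_quantile_normalize_defining_property_and_idempotence(rng):
    vecs = [rng.normal(size=50), rng.exponential(size=50), rng.uniform(size=50)]
    normed = quantile_normalize(vecs)
    sorted_ref = np.sort(normed[0])
    for v in normed[1:]:
        assert np.allclose(np.sort(v), sorted_ref)
    again = quantile_normalize(normed)
    for v1, v2 in zip(normed, again):
        assert np.allclose(v1, v2)
    # rank order preserved within each vector
    for raw, nv in zip(vecs, normed):
        assert np.array_equal(np.argsort(raw, kind="stable"),
                              np.argsort(nv, kind="stable"))


def test_quantile_normalize_length_mismatch(rng):
    a, b = quantile_normalize([rng.normal(size=40), rng.normal(size=25)])
    assert len(a) == 40 and len(b) == 25
    # distributions match through quantile interpolation
    qs = np.linspace(0.05, 0.95, 10)
    assert np.allclose(np.quantile(a, qs), np.quantile(b, qs), atol=0.3)
    with pytest.raises(DataError):
        quantile_normalize([np.arange(5.0)])


# --- nucleus segmentation and expansion -----------------------------------

def test_nucleus_count_recovery(slide):
    _, images, prestain, truth = slide
    dapi = subtract_prestain(images["dapi"], prestain)
    labels = segment_nuclei(dapi)
    assert labels.max() == len(truth.cells)
    res = match_instances_iou(labels, truth.nucleus_labels, iou_threshold=0.3)
    assert res.precision >= 0.95 and res.recall >= 0.95


def test_touching_nuclei_are_split():
    yy, xx = np.mgrid[:80, :80]
    img = np.full((80, 80), 5.0)
    img[((yy - 40) ** 2 / 64 + (xx - 33) ** 2 / 100) <= 1] = 150.0
    img[((yy - 40) ** 2 / 64 + (xx - 52) ** 2 / 100) <= 1] = 150.0
    labels = segment_nuclei(img, block_size=51, min_size=30)
    assert labels.max() == 2


def test_blank_dapi_gives_zero_objects():
    assert segment_nuclei(np.zeros((64, 64))).max() == 0


def test_watershed_labels_partition_foreground(slide):
    _, images, prestain, _ = slide
    dapi = subtract_prestain(images["dapi"], prestain)
    labels = segment_nuclei(dapi)
    # no overlaps by construction (single label image); labels nonneg ints
    assert labels.min() == 0 and labels.dtype.kind == "i"


def test_expand_labels_contract():
    lab = np.zeros((30, 30), np.int32)
    lab[15, 10] = 1
    grown = expand_labels(lab, distance=5)
    yy, xx = np.mgrid[:30, :30]
    disk = ((yy - 15) ** 2 + (xx - 10) ** 2) <= 25.0
    assert np.array_equal(grown > 0, disk)
    two = np.zeros((20, 20), np.int32)
    two[10, 5] = 1
    two[10, 9] = 2  # 4 px apart
    g2 = expand_labels(two, 5)
    assert set(np.unique(g2)) == {0, 1, 2}
    assert (g2 == 1).sum() > 1 and (g2 == 2).sum() > 1
    assert g2[10, 5] == 1 and g2[10, 9] == 2  # originals preserved
    with pytest.raises(DataError):
        expand_labels(two, -1)


def test_nucleus_subset_of_expansion(slide):
    _, images, prestain, _ = slide
    dapi = subtract_prestain(images["dapi"], prestain)
    nuclei = segment_nuclei(dapi)
    grown = expand_labels(nuclei, 5)
    sel = nuclei > 0
    assert np.array_equal(grown[sel], nuclei[sel])


# --- per-cell scoring -----------------------------------------------------

def test_score_cells_uniform_and_zero():
    lab = np.zeros((20, 20), np.int32)
    lab[5:15, 5:15] = 1
    marker = np.where(lab == 1, 7.5, 0.0)
    cells = score_cells(lab, lab, {"m": marker})
    assert cells.loc[0, "m"] == pytest.approx(7.5)
    assert cells.loc[0, "nuclear_size_px"] == 100
    zeros = score_cells(lab, lab, {"m": np.zeros((20, 20))})
    assert zeros.loc[0, "m"] == 0.0


def test_score_cells_quantile_convention():
    """95 px at 10 and 5 px at 100 under linear interpolation."""
    lab = np.zeros((10, 10), np.int32)
    lab.ravel()[:100] = 1
    marker = np.full(100, 10.0)
    marker[:5] = 100.0
    expected = np.quantile(np.sort(marker), 0.95)  # = 14.5
    cells = score_cells(lab, lab, {"m": marker.reshape(10, 10)})
    assert cells.loc[0, "m"] == pytest.approx(expected)
    assert expected == pytest.approx(14.5)


# --- patient scores -------------------------------------------------------

def _cells_table(gal1_pos, gal1_neg, sample="S1", patient="P1"):
    rows = []
    for g in gal1_pos:
        rows.append({"patient_id": patient, "sample_id": sample,
                     "sox2": 100.0, "gal1": g})
    for g in gal1_neg:
        rows.append({"patient_id": patient, "sample_id": sample,
                     "sox2": 5.0, "gal1": g})
    return pd.DataFrame(rows)


def test_z_trimming_caps_at_five():
    assert trim_z(9.0) == 5.0
    assert trim_z(-7.2) == -5.0
    # one extreme SOX2+ cell: its within-sample Z exceeds 5 and is trimmed
    cells = _cells_table([200.0] + [10.0] * 20, [10.0] * 30)
    scores, scored = patient_gal1_scores(cells, sox2_rule="fixed",
                                         sox2_value=50.0)
    extreme = scored.loc[scored["gal1"].idxmax(), "gal1_z"]
    raw_z = (200.0 - cells["gal1"].mean()) / cells["gal1"].std(ddof=1)
    assert raw_z > 5.0
    assert extreme == 5.0


def test_constant_sample_raises_named_error():
    cells = _cells_table([10.0] * 5, [])
    with pytest.raises(DegenerateInputError, match="S1"):
        patient_gal1_scores(cells, sox2_rule="fixed", sox2_value=50.0)


def test_too_few_positive_cells_raises():
    cells = _cells_table([10.0], [5.0] * 10)
    with pytest.raises(DegenerateInputError, match="SOX2"):
        patient_gal1_scores(cells, sox2_rule="fixed", sox2_value=50.0)


def test_effect_separates_patient_scores():
    a = _cells_table([80.0, 85, 78, 90], [40.0] * 8, "A1", "A")
    b = _cells_table([45.0, 42, 48, 50], [40.0] * 8, "B1", "B")
    scores, _ = patient_gal1_scores(
        pd.concat([a, b], ignore_index=True),
        sox2_rule="fixed", sox2_value=50.0,
    )
    assert scores["A"] > scores["B"]


def test_sox2_masked_gal1_zero_outside_positive_cells():
    lab = np.zeros((12, 12), np.int32)
    lab[2:5, 2:5] = 1
    lab[7:10, 7:10] = 2
    gal1 = np.full((12, 12), 3.0)
    masked = sox2_masked_gal1(lab, [2], gal1)
    assert np.all(masked[lab == 2] == 3.0)
    assert np.all(masked[lab != 2] == 0.0)
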