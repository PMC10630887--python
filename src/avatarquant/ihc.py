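"""Multiplex IHC slide quantification.

Stages mirror the slide-processing chain: corner-based registration of the
pre-stain image onto the stained scan, rolling-ball background correction,
pre-stain (tissue autofluorescence) subtraction, quantile normalisation of
intensity distributions across samples, DAPI nucleus segmentation
(local threshold -> distance map -> watershed), 5-px label expansion to
capture cytoplasmic marker signal, a per-cell 95%-quantile intensity
summary, and trimmed within-sample Z-scores of GAL1 in SOX2-positive tumor
cells averaged per patient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage.feature import (
    BRIEF,
    corner_harris,
    corner_peaks,
    match_descriptors,
    peak_local_max,
)
from skimage.filters import threshold_local, threshold_otsu
from skimage.measure import ransac, regionprops
from skimage.morphology import remove_small_objects
from skimage.restoration import rolling_ball as _sk_rolling_ball
from skimage.segmentation import expand_labels as _sk_expand_labels
from skimage.segmentation import watershed
from skimage.transform import ProjectiveTransform, warp

from .errors import DataError, DegenerateInputError, RegistrationError

#: pixels by which nucleus labels are expanded to catch cytoplasmic signal
EXPANSION_PX = 5
#: per-cell intensity summary quantile (linear interpolation convention)
SUMMARY_QUANTILE = 0.95
#: trimmed Z-score range
Z_TRIM = (-5.0, 5.0)


# ---------------------------------------------------------------------------
# registration
# ---------------------------------------------------------------------------

def register_images(
    moving: np.ndarray,
    fixed: np.ndarray,
    max_corners: int = 300,
    min_distance: int = 7,
    residual_threshold: float = 2.0,
    max_trials: int = 1000,
    seed: int = 0,
):
    """Estimate a projective transform mapping ``moving`` onto ``fixed``.

    Harris corners are detected on both images, described by BRIEF patch
    descriptors, matched (cross-checked), and a homography is fit by RANSAC.
    Returns ``(transform, warped)`` where ``warped`` is the moving image
    resampled into the fixed frame.

    Raises
    ------
    RegistrationError
        If fewer than 4 inlier matches survive (diagnostics included).
    """
    moving = np.asarray(moving, dtype=np.float64)
    fixed = np.asarray(fixed, dtype=np.float64)

    def _keypoints(img):
        if img.max() == img.min():
            return np.empty((0, 2))
        response = corner_harris(img)
        return corner_peaks(
            response, min_distance=min_distance, num_peaks=max_corners,
            threshold_rel=0.01,
        )

    kp_m, kp_f = _keypoints(moving), _keypoints(fixed)
    extractor = BRIEF(patch_size=25, rng=seed)
    extractor.extract(moving, kp_m)
    desc_m, kp_m = extractor.descriptors, kp_m[extractor.mask]
    extractor = BRIEF(patch_size=25, rng=seed)
    extractor.extract(fixed, kp_f)
    desc_f, kp_f = extractor.descriptors, kp_f[extractor.mask]
    if len(kp_m) < 4 or len(kp_f) < 4:
        raise RegistrationError(
            f"too few corners (moving: {len(kp_m)}, fixed: {len(kp_f)}); "
            "need >= 4"
        )
    matches = match_descriptors(desc_m, desc_f, cross_check=True)
    if len(matches) < 4:
        raise RegistrationError(
            f"only {len(matches)} descriptor matches; need >= 4"
        )
    # transforms act on (x, y) coordinates
    src = kp_m[matches[:, 0]][:, ::-1].astype(np.float64)
    dst = kp_f[matches[:, 1]][:, ::-1].astype(np.float64)
    model, inliers = ransac(
        (src, dst),
        ProjectiveTransform,
        min_samples=4,
        residual_threshold=residual_threshold,
        max_trials=max_trials,
        rng=seed,
    )
    n_inliers = 0 if inliers is None else int(inliers.sum())
    if model is None or n_inliers < 4:
        raise RegistrationError(
            f"RANSAC found {n_inliers} inliers of {len(matches)} matches; "
            "need >= 4"
        )
    warped = warp(moving, model.inverse, output_shape=fixed.shape,
                  preserve_range=True)
    return model, warped


# ---------------------------------------------------------------------------
# intensity corrections
# ---------------------------------------------------------------------------

def rolling_ball(image: np.ndarray, radius: float = 50.0) -> np.ndarray:
    """Rolling-ball background correction; output clipped at 0."""
    image = np.asarray(image, dtype=np.float64)
    if radius <= 0:
        raise DataError("rolling-ball radius must be > 0")
    if radius >= min(image.shape):
        raise DataError(
            f"rolling-ball radius {radius} >= smallest image extent "
            f"{min(image.shape)}"
        )
    background = _sk_rolling_ball(image, radius=radius)
    return np.maximum(image - background, 0.0)


def subtract_prestain(measured: np.ndarray, prestain: np.ndarray) -> np.ndarray:
    """Autofluorescence removal: ``max(measured - prestain, 0)`` elementwise.

    The pre-stain image must already be registered onto the measured frame.
    """
    measured = np.asarray(measured, dtype=np.float64)
    prestain = np.asarray(prestain, dtype=np.float64)
    if measured.shape != prestain.shape:
        raise DataError(
            f"shape mismatch: measured {measured.shape} vs prestain "
            f"{prestain.shape}"
        )
    return np.maximum(measured - prestain, 0.0)


def quantile_normalize(vectors: list[np.ndarray]) -> list[np.ndarray]:
    """Force all vectors to share the same (rank-wise mean) distribution.

    Equal-length vectors get the classic treatment: sorted values are
    averaged rank by rank and each vector's values are replaced by the
    reference value at their (stable-sort) rank.  Vectors of unequal length
    are mapped through quantile interpolation onto the pooled reference.
    Idempotent, and rank order within each vector is preserved.
    """
    vecs = [np.asarray(v, dtype=np.float64).ravel() for v in vectors]
    if len(vecs) < 2:
        raise DataError("quantile normalization needs >= 2 vectors")
    lengths = {len(v) for v in vecs}
    if len(lengths) == 1:
        ref = np.mean([np.sort(v) for v in vecs], axis=0)
        out = []
        for v in vecs:
            order = np.argsort(v, kind="stable")
            res = np.empty_like(v)
            res[order] = ref
            out.append(res)
        return out
    # unequal lengths: common quantile grid of the longest vector
    n_ref = max(lengths)
    qs = np.linspace(0.0, 1.0, n_ref)
    ref = np.mean([np.quantile(v, qs) for v in vecs], axis=0)
    out = []
    for v in vecs:
        n = len(v)
        pos = np.linspace(0.0, 1.0, n) if n > 1 else np.array([0.5])
        ref_v = np.interp(pos, qs, ref)
        order = np.argsort(v, kind="stable")
        res = np.empty_like(v)
        res[order] = ref_v
        out.append(res)
    return out


# ---------------------------------------------------------------------------
# segmentation and per-cell scoring
# ---------------------------------------------------------------------------

def segment_nuclei(
    dapi: np.ndarray,
    block_size: int = 51,
    offset: float = 0.0,
    min_size: int = 40,
    min_peak_distance: int = 7,
) -> np.ndarray:
    """Nucleus instance segmentation from the DAPI channel.

    Foreground by local mean thresholding (window ``block_size``, constant
    ``offset`` subtracted from the local mean), then a Euclidean distance
    map whose maxima seed a watershed that splits touching nuclei; objects
    below ``min_size`` px are removed.  A blank image yields zero objects.
    """
    dapi = np.asarray(dapi, dtype=np.float64)
    if dapi.ndim != 2:
        raise DataError("DAPI image must be 2D")
    if block_size % 2 == 0:
        raise DataError("block_size must be odd")
    if dapi.max() == dapi.min():
        return np.zeros(dapi.shape, dtype=np.int32)
    thr = threshold_local(dapi, block_size=block_size, method="mean",
                          offset=offset)
    mask = dapi > thr
    mask = remove_small_objects(mask, max_size=min_size - 1)
    if not mask.any():
        return np.zeros(dapi.shape, dtype=np.int32)
    dist = ndi.distance_transform_edt(mask)
    peaks = peak_local_max(
        dist, min_distance=min_peak_distance, labels=mask,
        exclude_border=False,
    )
    markers = np.zeros(dapi.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    if markers.max() == 0:
        labels, _ = ndi.label(mask)
        labels = labels.astype(np.int32)
    else:
        labels = watershed(-dist, markers, mask=mask).astype(np.int32)
    counts = np.bincount(labels.ravel())
    small = np.flatnonzero(counts < min_size)
    labels[np.isin(labels, small)] = 0
    ids = np.unique(labels)
    remap = np.zeros(ids.max() + 1, dtype=np.int32)
    remap[ids[ids > 0]] = np.arange(1, (ids > 0).sum() + 1)
    return remap[labels]


def expand_labels(labels: np.ndarray, distance: float = EXPANSION_PX) -> np.ndarray:
    """Grow each nucleus label outward by up to ``distance`` px.

    Growth stops where competing labels meet, so expanded masks stay
    disjoint and nuclei are preserved.
    """
    if distance < 0:
        raise DataError("expansion distance must be >= 0")
    return _sk_expand_labels(np.asarray(labels), distance=distance)


@dataclass
class CellObject:
    """One segmented cell with its per-marker summary intensities."""

    cell_id: int
    nuclear_size_px: int
    markers: dict[str, float]  # marker -> 95%-quantile intensity
    sox2_positive: bool | None = None
    gal1_z: float | None = None


def score_cells(
    expanded_labels: np.ndarray,
    nucleus_labels: np.ndarray,
    marker_images: dict[str, np.ndarray],
    quantile: float = SUMMARY_QUANTILE,
) -> pd.DataFrame:
    """Per-cell marker summaries over the expanded masks.

    Because markers are not expressed over the whole cell surface, each
    cell's expression is summarised by the ``quantile`` (default 95%,
    linear interpolation between order statistics) of the pixel intensities
    inside its expanded mask.  Nuclear size is the nucleus-mask pixel count.

    Returns a DataFrame with one row per cell: ``cell_id``,
    ``nuclear_size_px`` and one column per marker.
    """
    expanded_labels = np.asarray(expanded_labels)
    nucleus_labels = np.asarray(nucleus_labels)
    for name, img in marker_images.items():
        if np.asarray(img).shape != expanded_labels.shape:
            raise DataError(f"marker '{name}' shape mismatch")
    nuc_sizes = np.bincount(nucleus_labels.ravel())
    rows = []
    for rp in regionprops(expanded_labels):
        cid = int(rp.label)
        sel = expanded_labels == cid
        row = {
            "cell_id": cid,
            "nuclear_size_px": int(nuc_sizes[cid]) if cid < len(nuc_sizes) else 0,
        }
        for name, img in marker_images.items():
            vals = np.asarray(img, dtype=np.float64)[sel]
            row[name] = float(np.quantile(vals, quantile)) if len(vals) else 0.0
        rows.append(row)
    cols = ["cell_id", "nuclear_size_px", *marker_images.keys()]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# patient-level GAL1 scores
# ---------------------------------------------------------------------------

def sox2_gate(
    sox2_summaries: np.ndarray, rule: str = "otsu", value: float | None = None
) -> np.ndarray:
    """Boolean SOX2-positivity per cell from per-cell SOX2 summaries.

    Rules: ``otsu`` (threshold chosen per sample on the summary
    distribution), ``fixed`` (``value`` is the threshold) or ``quantile``
    (``value`` in (0,1); cells above that quantile are positive).
    """
    s = np.asarray(sox2_summaries, dtype=np.float64)
    if rule == "otsu":
        if len(np.unique(s)) < 2:
            raise DegenerateInputError(
                "SOX2 summaries are constant; Otsu gate undefined"
            )
        return s > threshold_otsu(s)
    if rule == "fixed":
        if value is None:
            raise DataError("fixed SOX2 gate needs a threshold value")
        return s > value
    if rule == "quantile":
        if value is None or not 0 < value < 1:
            raise DataError("quantile SOX2 gate needs value in (0, 1)")
        return s > np.quantile(s, value)
    raise DataError(f"unknown SOX2 gating rule '{rule}'")


def patient_gal1_scores(
    cells: pd.DataFrame,
    sox2_rule: str = "otsu",
    sox2_value: float | None = None,
    trim: tuple[float, float] = Z_TRIM,
    normalize_over: str = "all",
) -> tuple[pd.Series, pd.DataFrame]:
    """Trimmed-Z GAL1 score per patient over SOX2-positive tumor cells.

    ``cells`` must carry columns ``patient_id``, ``sample_id``, ``sox2``
    and ``gal1`` (per-cell summary intensities).  Within each core /
    whole-slide sample, GAL1 summaries are standardised to Z-scores, trimmed
    to [-5, 5]; the scores of the SOX2-positive (tumor) cells are then
    averaged per patient.

    ``normalize_over`` chooses the standardisation population per sample:
    ``"all"`` (default) uses every segmented cell of the sample, so the
    patient score measures how strongly tumor cells express GAL1 relative
    to the section as a whole; ``"gated"`` standardises within the
    SOX2-positive subset only (its patient means are centred on zero by
    construction, useful only for outlier diagnostics).

    Returns ``(per-patient scores, gated per-cell table with gal1_z)``.

    Raises
    ------
    DegenerateInputError
        If a sample has fewer than 2 SOX2-positive cells or zero GAL1
        standard deviation in its normalisation population (the offending
        sample is named).
    """
    required = {"patient_id", "sample_id", "sox2", "gal1"}
    if not required.issubset(cells.columns):
        raise DataError(f"cells table needs columns {sorted(required)}")
    if normalize_over not in ("all", "gated"):
        raise DataError("normalize_over must be 'all' or 'gated'")
    lo, hi = trim
    scored = []
    for sample, sub in cells.groupby("sample_id"):
        pos = sox2_gate(sub["sox2"].to_numpy(), rule=sox2_rule, value=sox2_value)
        gated = sub[pos].copy()
        if len(gated) < 2:
            raise DegenerateInputError(
                f"sample '{sample}' has {len(gated)} SOX2-positive cells; "
                "need >= 2"
            )
        ref = (gated if normalize_over == "gated" else sub)["gal1"].to_numpy(
            dtype=np.float64
        )
        sd = ref.std(ddof=1)
        if sd == 0:
            raise DegenerateInputError(
                f"sample '{sample}' has zero GAL1 sd in its normalisation "
                "population; Z-score undefined"
            )
        g = gated["gal1"].to_numpy(dtype=np.float64)
        gated["gal1_z"] = np.clip((g - ref.mean()) / sd, lo, hi)
        scored.append(gated)
    scored = pd.concat(scored, ignore_index=True)
    per_patient = scored.groupby("patient_id")["gal1_z"].mean()
    return per_patient, scored


def trim_z(z, lo: float = Z_TRIM[0], hi: float = Z_TRIM[1]):
    """Trim Z-scores into the [-5, 5] range (outlier damping)."""
    return np.clip(z, lo, hi)


def sox2_masked_gal1(
    expanded_labels: np.ndarray,
    sox2_positive_ids,
    gal1_image: np.ndarray,
) -> np.ndarray:
    """GAL1 image multiplied by the binary SOX2-positive cell mask.

    Visualization aid: GAL1 staining outside SOX2-positive (tumor) cells is
    zeroed.
    """
    mask = np.isin(expanded_labels, np.asarray(list(sox2_positive_ids)))
    return np.where(mask, np.asarray(gal1_image, dtype=np.float64), 0.0)
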