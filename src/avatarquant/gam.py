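"""GAM detection and morphotype classification on 2D max projections.

Macrophages/microglia around the tumor (GAMs) are detected on the maximum
intensity projection of the GAM channel.  Each detected footprint is
summarised by its area ``A``, perimeter ``p`` and circularity

    c = 4 * pi * A / p**2,

which is 1 for a perfect circle and approaches 0 for elongated, branched
shapes.  Cells with c > 0.6 are classified *round* (amoeboid, reactive) and
cells with c < 0.35 *ramified* (surveillant); the band in between is kept as
an explicit *intermediate* class so that threshold-sensitive counts remain
reversible.

Instance segmentations are validated against reference annotations by
one-to-one intersection-over-union (IoU) matching.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from skimage.filters import apply_hysteresis_threshold, gaussian, threshold_otsu
from skimage.measure import regionprops
from skimage.morphology import h_maxima
from skimage.segmentation import watershed

from .errors import DataError, DegenerateInputError

#: circularity above which a GAM is called round
ROUND_THRESHOLD = 0.6
#: circularity below which a GAM is called ramified
RAMIFIED_THRESHOLD = 0.35


@dataclass
class GamDetection2D:
    """One GAM footprint on the 2D projection with its morphometrics."""

    instance_id: int
    area_px: float
    perimeter_px: float
    circularity: float
    shape_class: str
    centroid_yx: tuple[float, float]
    touches_border: bool = False


@dataclass
class MatchResult:
    """Outcome of IoU matching between predicted and reference instances."""

    pairs: list[tuple[int, int, float]]  # (predicted id, truth id, IoU)
    false_positive_ids: list[int]
    false_negative_ids: list[int]
    precision: float
    recall: float
    mean_iou: float

    @property
    def n_true_positive(self) -> int:
        return len(self.pairs)


def max_project(volume: np.ndarray) -> np.ndarray:
    """Maximum intensity projection of a (Z, Y, X) volume along z."""
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise DataError(f"expected a 3D volume, got ndim={volume.ndim}")
    return volume.max(axis=0)


def classify_shape(circularity: float) -> str:
    """Map a circularity value to {round, ramified, intermediate}.

    Round means c > 0.6, ramified c < 0.35; the gap is 'intermediate' and is
    excluded from round/ramified counts downstream.
    """
    if circularity < 0:
        raise DataError(f"circularity must be >= 0, got {circularity}")
    if circularity > ROUND_THRESHOLD:
        return "round"
    if circularity < RAMIFIED_THRESHOLD:
        return "ramified"
    return "intermediate"


def circularity(area: float, perimeter: float) -> float:
    """4*pi*A/p**2, unclamped (rasterized near-circles may exceed 1)."""
    if perimeter <= 0:
        raise DegenerateInputError("perimeter must be positive")
    return 4.0 * np.pi * area / perimeter**2


def compute_morphometrics(
    label_image: np.ndarray, perimeter_estimator: str = "crofton"
) -> list[GamDetection2D]:
    """Per-instance area, perimeter and circularity of a 2D label image.

    The perimeter estimator matters: the naive boundary-step count biases
    circularity downward enough to push rasterized disks below the round
    threshold, so the default is the low-bias Crofton estimator (4
    directions).  ``perimeter_estimator`` is recorded by callers in output
    metadata because the 0.6/0.35 class thresholds are estimator-sensitive.
    """
    label_image = np.asarray(label_image)
    if label_image.ndim != 2:
        raise DataError("label image must be 2D")
    if perimeter_estimator not in ("crofton", "contour"):
        raise DataError(f"unknown perimeter estimator '{perimeter_estimator}'")
    h, w = label_image.shape
    out: list[GamDetection2D] = []
    for rp in regionprops(label_image):
        if perimeter_estimator == "crofton":
            p = rp.perimeter_crofton
        else:
            p = rp.perimeter
        if p <= 0:
            # single-pixel object under the contour estimator: use the
            # estimator's minimum (one isolated pixel seen by Crofton)
            p = rp.perimeter_crofton if rp.perimeter_crofton > 0 else np.pi
        a = float(rp.area)
        c = circularity(a, p)
        minr, minc, maxr, maxc = rp.bbox
        out.append(
            GamDetection2D(
                instance_id=int(rp.label),
                area_px=a,
                perimeter_px=float(p),
                circularity=float(c),
                shape_class=classify_shape(c),
                centroid_yx=tuple(rp.centroid),
                touches_border=bool(
                    minr == 0 or minc == 0 or maxr == h or maxc == w
                ),
            )
        )
    return out


# --- instance segmentation backends -------------------------------------

_BACKENDS: dict[str, callable] = {}


def register_backend(name: str, fn) -> None:
    """Register an instance-segmentation backend.

    A backend is ``fn(image, seed, **params) -> label image``.  The default
    'classical' backend is a smooth/threshold/watershed chain; an external
    learned segmenter (e.g. a trained deep model) can be plugged in here
    without touching the rest of the pipeline.
    """
    _BACKENDS[name] = fn


def _classical_backend(
    image: np.ndarray,
    seed: int = 0,
    sigma: float = 0.7,
    threshold: float | None = None,
    min_area: int = 20,
    min_seed_height: float = 2.0,
    seed_prominence: float = 3.0,
    low_fraction: float = 0.4,
) -> np.ndarray:
    """Smooth -> hysteresis threshold -> watershed split.

    Detection uses the high threshold (Otsu unless a fixed value is given);
    the object extent additionally keeps pixels above ``low_fraction`` of it
    that connect to a detection, so the dim thin processes of ramified cells
    stay attached to their soma.  Watershed seeds are the h-maxima of the
    mask's distance map (prominence >= ``seed_prominence`` px, height >=
    ``min_seed_height`` px): touching compact cells each keep a prominent
    peak and get split, while the ridge along a thin process is never
    prominent relative to its soma and cannot split the cell.  Mask
    components without any seed are labelled as single objects.
    """
    image = np.asarray(image, dtype=np.float64)
    smoothed = gaussian(image, sigma=sigma, preserve_range=True)
    if threshold is None:
        if smoothed.max() == smoothed.min():
            return np.zeros(image.shape, dtype=np.int32)
        threshold = threshold_otsu(smoothed)
    mask = apply_hysteresis_threshold(
        smoothed, low_fraction * threshold, threshold
    )
    if not mask.any():
        return np.zeros(image.shape, dtype=np.int32)
    dist = ndi.distance_transform_edt(mask)
    seeds = h_maxima(dist, seed_prominence) & (dist >= min_seed_height)
    # 8-connectivity: a diagonal maximum plateau is one marker, not two
    markers, _ = ndi.label(seeds, structure=np.ones((3, 3), dtype=bool))
    markers = markers.astype(np.int32)
    if markers.max() == 0:
        labels, _ = ndi.label(mask)
    else:
        labels = watershed(-dist, markers, mask=mask)
        # components too thin to hold any seed stay one object each
        unseeded = mask & (labels == 0)
        if unseeded.any():
            extra, n_extra = ndi.label(unseeded)
            extra[extra > 0] += labels.max()
            labels = labels + extra
    # drop specks below the minimum area, then relabel densely
    counts = np.bincount(labels.ravel())
    small = np.flatnonzero(counts < min_area)
    labels[np.isin(labels, small)] = 0
    ids = np.unique(labels)
    remap = np.zeros(ids.max() + 1, dtype=np.int32)
    remap[ids[ids > 0]] = np.arange(1, (ids > 0).sum() + 1)
    return remap[labels]


register_backend("classical", _classical_backend)


def segment_gams_2d(
    image: np.ndarray, backend: str = "classical", seed: int = 0, **params
) -> np.ndarray:
    """Segment GAM instances on a 2D projection image.

    Returns a non-overlapping int label image (0 = background).  The default
    backend smooths, thresholds (Otsu or a fixed value), splits touching
    objects by a distance-map watershed and discards objects below the
    minimum area (default 20 px^2).
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise DataError("GAM segmentation operates on 2D projections")
    if backend not in _BACKENDS:
        raise DataError(
            f"unknown segmentation backend '{backend}'; "
            f"registered: {sorted(_BACKENDS)}"
        )
    return _BACKENDS[backend](image, seed=seed, **params)


def _pairwise_iou(pred: np.ndarray, truth: np.ndarray):
    """Sparse IoU table between all predicted and truth labels."""
    pred = pred.ravel()
    truth = truth.ravel()
    both = (pred > 0) | (truth > 0)
    pred, truth = pred[both], truth[both]
    n_t = int(truth.max()) + 1
    pair_codes, inter = np.unique(
        pred.astype(np.int64) * n_t + truth.astype(np.int64), return_counts=True
    )
    area_p = np.bincount(pred)
    area_t = np.bincount(truth)
    ious = []
    for code, i in zip(pair_codes, inter):
        pid, tid = int(code // n_t), int(code % n_t)
        if pid == 0 or tid == 0:
            continue
        union = area_p[pid] + area_t[tid] - i
        ious.append((pid, tid, i / union))
    return ious


def match_instances_iou(
    predicted: np.ndarray, truth: np.ndarray, iou_threshold: float = 0.5
) -> MatchResult:
    """One-to-one greedy IoU matching of predicted vs reference instances.

    Candidate pairs are taken in descending IoU order (ties broken by lower
    truth id, then lower predicted id); each object participates in at most
    one match and pairs below ``iou_threshold`` stay unmatched.  Precision =
    TP/(TP+FP), recall = TP/(TP+FN).
    """
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise DataError(
            f"shape mismatch: predicted {predicted.shape} vs truth {truth.shape}"
        )
    if not 0 < iou_threshold <= 1:
        raise DataError("iou_threshold must be in (0, 1]")
    pred_ids = set(np.unique(predicted)) - {0}
    truth_ids = set(np.unique(truth)) - {0}
    candidates = sorted(
        _pairwise_iou(predicted, truth), key=lambda x: (-x[2], x[1], x[0])
    )
    used_p: set[int] = set()
    used_t: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    for pid, tid, iou in candidates:
        if iou < iou_threshold or pid in used_p or tid in used_t:
            continue
        pairs.append((pid, tid, float(iou)))
        used_p.add(pid)
        used_t.add(tid)
    tp = len(pairs)
    fp = sorted(pred_ids - used_p)
    fn = sorted(truth_ids - used_t)
    precision = tp / (tp + len(fp)) if (tp + len(fp)) else 0.0
    recall = tp / (tp + len(fn)) if (tp + len(fn)) else 0.0
    mean_iou = float(np.mean([x[2] for x in pairs])) if pairs else 0.0
    return MatchResult(
        pairs=pairs,
        false_positive_ids=[int(i) for i in fp],
        false_negative_ids=[int(i) for i in fn],
        precision=precision,
        recall=recall,
        mean_iou=mean_iou,
    )
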