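"""End-to-end orchestration of the movie and slide pipelines.

``run_avatar`` executes, per in-focus frame: (optional) bleed-through and
autofluorescence correction, 3D tumor segmentation and volume, 2D GAM
detection on the max projection, morphometrics and morphotype
classification, 3D center inference, the anisotropic distance map and
per-GAM distances, then assembles the per-timepoint metrics table.

``run_ihc`` executes: pre-stain registration, (optional) rolling-ball
correction, pre-stain subtraction, nucleus segmentation, 5-px expansion,
per-cell 95%-quantile scoring, and trimmed-Z GAL1 patient summaries.

Both are deterministic given (inputs, config) and log parameters and
per-stage counts.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .config import RunConfig
from .errors import AvatarQuantError, StageError
from .gam import compute_morphometrics, max_project, segment_gams_2d
from .ihc import (
    expand_labels,
    patient_gal1_scores,
    quantile_normalize,
    register_images,
    rolling_ball,
    score_cells,
    segment_nuclei,
    subtract_prestain,
)
from .movie import AvatarMovie, read_movie, subtract_bleedthrough
from .preprocess import PixelClassifier, remove_autofluorescence
from .spatial import gam_distances, infer_z_centers, tumor_distance_map
from .trend import build_metrics_table
from .tumor import segment_tumor

logger = logging.getLogger("avatarquant")


def _stage(name, frame=None):
    """Decorator-free stage wrapper: re-raise with stage context."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, StageError):
                raise StageError(name, frame, exc) from exc
            return False

    return _Ctx()


def run_avatar(
    config: RunConfig,
    movie: AvatarMovie | None = None,
    classifier: PixelClassifier | None = None,
):
    """Run the full movie-quantification pipeline.

    ``movie`` may be passed directly; otherwise it is read from
    ``config.movie_path``.  Returns a dict with the metrics table, the
    per-GAM record table, and per-frame tumor masks; CSVs (and optionally
    masks) are written under ``config.output_dir``.
    """
    if movie is None and config.movie_path is None:
        raise AvatarQuantError("no movie given and no movie_path configured")
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logger.info("avatarquant %s run-avatar seed=%d", __version__, config.seed)

    if movie is None:
        with _stage("read_movie"):
            movie = read_movie(
                config.movie_path,
                channels=config.channels or None,
                spacing=config.spacing,
                frame_interval_min=config.frame_interval_min,
            )
    if classifier is None and config.classifier_path:
        classifier = PixelClassifier.load(config.classifier_path)

    spacing = movie.spacing
    tumor_masks = []
    gam_label_images = []
    gam_rows = []
    for t in range(movie.n_frames):
        if not movie.in_focus[t]:
            break  # this frame and all subsequent ones are dropped
        tumor_vol = np.asarray(movie.channel("tumor", t), dtype=np.float64)
        gam_vol = np.asarray(movie.channel("gam", t), dtype=np.float64)
        if config.do_bleedthrough and "vessel" in movie.channels:
            with _stage("bleedthrough", t):
                vessel = subtract_bleedthrough(
                    movie.channel("vessel", t), tumor_vol,
                    config.bleedthrough_coefficient,
                )
                del vessel  # corrected vessel channel not used downstream
        if config.do_autofluorescence:
            if classifier is None:
                raise StageError(
                    "autofluorescence", t,
                    AvatarQuantError("no trained classifier available"),
                )
            with _stage("autofluorescence", t):
                stack = np.stack([tumor_vol, gam_vol])
                if "tumor" in config.remove_autofluorescence_channels:
                    tumor_vol = remove_autofluorescence(
                        tumor_vol, classifier, feature_volume=stack
                    )
                if "gam" in config.remove_autofluorescence_channels:
                    gam_vol = remove_autofluorescence(
                        gam_vol, classifier, feature_volume=stack
                    )
        with _stage("segment_tumor", t):
            tmask = segment_tumor(
                tumor_vol, spacing, sigma=config.tumor_sigma_px,
                keep=config.tumor_keep,
            )
        tumor_masks.append(tmask)
        with _stage("segment_gams", t):
            projection = max_project(gam_vol)
            labels = segment_gams_2d(
                projection, backend=config.gam_backend, seed=config.seed,
                sigma=config.gam_sigma_px, min_area=config.gam_min_area_px,
            )
            detections = compute_morphometrics(
                labels, perimeter_estimator=config.perimeter_estimator
            )
        gam_label_images.append(labels)
        with _stage("spatial_metrics", t):
            centers = infer_z_centers(
                labels, gam_vol, spacing, method=config.z_inference
            )
            dmap = tumor_distance_map(tmask)
            centers = gam_distances(centers, dmap)
        det_by_id = {d.instance_id: d for d in detections}
        for _, row in centers.iterrows():
            d = det_by_id[int(row["instance_id"])]
            gam_rows.append(
                {
                    "frame": t,
                    "instance_id": d.instance_id,
                    "area_px": d.area_px,
                    "perimeter_px": d.perimeter_px,
                    "circularity": d.circularity,
                    "shape_class": d.shape_class,
                    "touches_border": d.touches_border,
                    "z_um": row["z_um"],
                    "y_um": row["y_um"],
                    "x_um": row["x_um"],
                    "distance_um": row["distance_um"],
                    "low_confidence": row["low_confidence"],
                }
            )
        logger.info(
            "frame %d: tumor %.0f um^3, %d GAMs", t, tmask.volume_um3,
            len(detections),
        )
        if config.write_masks:
            tifffile.imwrite(
                out_dir / f"tumor_mask_t{t:03d}.tif",
                tmask.mask.astype(np.uint8) * 255,
            )
            tifffile.imwrite(out_dir / f"gam_labels_t{t:03d}.tif",
                             labels.astype(np.uint16))

    gam_records = pd.DataFrame(
        gam_rows,
        columns=[
            "frame", "instance_id", "area_px", "perimeter_px", "circularity",
            "shape_class", "touches_border", "z_um", "y_um", "x_um",
            "distance_um", "low_confidence",
        ],
    )
    n_kept = len(tumor_masks)
    with _stage("metrics_table"):
        metrics = build_metrics_table(
            tumor_masks,
            gam_records,
            movie.frame_times_min()[:n_kept],
            in_focus=movie.in_focus[:n_kept],
            injection_offset_hpi=config.injection_offset_hpi,
            proximity_radius_um=config.proximity_radius_um,
        )
    metrics_meta = metrics.copy()
    metrics_meta.attrs["perimeter_estimator"] = config.perimeter_estimator
    metrics.to_csv(out_dir / "metrics.csv", index=False)
    gam_records.to_csv(out_dir / "gam_records.csv", index=False)
    return {
        "metrics": metrics,
        "gam_records": gam_records,
        "tumor_masks": tumor_masks,
        "gam_labels": gam_label_images,
    }


def run_ihc(
    config: RunConfig,
    images: dict[str, np.ndarray],
    prestain: np.ndarray | None = None,
    sample_id: str = "S1",
    patient_id: str = "P1",
    register_prestain: bool = False,
):
    """Run the slide-quantification pipeline on one sample.

    ``images`` maps channel names (``dapi`` required; markers such as
    ``sox2``, ``gal1``) to 2D arrays.  Returns a dict with the per-cell
    table and label images; CSVs are written under ``config.output_dir``.
    """
    if "dapi" not in images:
        raise AvatarQuantError("IHC pipeline requires a 'dapi' channel")
    if config.do_prestain_subtraction and prestain is None:
        raise AvatarQuantError(
            "pre-stain subtraction enabled but no pre-stain image given"
        )
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    work = {k: np.asarray(v, dtype=np.float64) for k, v in images.items()}
    if prestain is not None and register_prestain:
        with _stage("register"):
            _, prestain = register_images(
                np.asarray(prestain, dtype=np.float64), work["dapi"],
                seed=config.seed,
            )
    if config.do_rolling_ball:
        with _stage("rolling_ball"):
            work = {
                k: rolling_ball(v, radius=config.rolling_ball_radius_px)
                for k, v in work.items()
            }
            if prestain is not None:
                prestain = rolling_ball(
                    np.asarray(prestain, dtype=np.float64),
                    radius=config.rolling_ball_radius_px,
                )
    if config.do_prestain_subtraction:
        with _stage("prestain_subtraction"):
            work = {
                k: subtract_prestain(v, prestain) for k, v in work.items()
            }
    if config.do_quantile_normalization and len(work) >= 2:
        with _stage("quantile_normalization"):
            keys = sorted(work)
            normed = quantile_normalize([work[k].ravel() for k in keys])
            work = {
                k: n.reshape(work[k].shape) for k, n in zip(keys, normed)
            }
    with _stage("segment_nuclei"):
        nuclei = segment_nuclei(
            work["dapi"],
            block_size=config.nucleus_block_size,
            offset=config.nucleus_offset,
            min_size=config.nucleus_min_size_px,
        )
        expanded = expand_labels(nuclei, distance=config.expansion_px)
    with _stage("score_cells"):
        markers = {k: v for k, v in work.items() if k != "dapi"}
        cells = score_cells(
            expanded, nuclei, markers, quantile=config.summary_quantile
        )
    cells["sample_id"] = sample_id
    cells["patient_id"] = patient_id
    cells.to_csv(out_dir / f"cells_{sample_id}.csv", index=False)
    logger.info("sample %s: %d cells", sample_id, len(cells))
    return {"cells": cells, "nuclei": nuclei, "expanded": expanded}


def score_cohort(
    cell_tables: list[pd.DataFrame],
    sox2_rule: str = "otsu",
    sox2_value: float | None = None,
):
    """Concatenate per-sample cell tables and compute patient GAL1 scores."""
    cells = pd.concat(cell_tables, ignore_index=True)
    cells = cells.rename(columns={"sox2": "sox2", "gal1": "gal1"})
    scores, scored_cells = patient_gal1_scores(
        cells, sox2_rule=sox2_rule, sox2_value=sox2_value
    )
    return scores, scored_cells
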