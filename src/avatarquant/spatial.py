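"""3D localisation of GAMs and anisotropic distance-to-tumor metrics.

GAMs are detected on the 2D max projection; their z position is inferred
from the GAM-channel signal under each footprint (intensity-weighted
centroid of the z-profile).  Distance to the tumor is read off an
anisotropic Euclidean distance transform (EDT) of the tumor-mask complement,
in micrometres: the map is 0 on tumor voxels, so a GAM whose center lies
inside or in contact with the tumor is at distance 0 by construction, and
elsewhere it equals the shortest center-to-center distance to any tumor
voxel under the physical (z, y, x) spacing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from scipy.signal import find_peaks

from .errors import DataError
from .tumor import TumorMask

#: proximity radius used for the "GAMs near the tumor" subset, micrometres
PROXIMITY_RADIUS_UM = 30.0


@dataclass
class DistanceMap:
    """Per-voxel shortest distance to the tumor, in micrometres."""

    values: np.ndarray  # (Z, Y, X) float, >= 0, 0 on tumor voxels
    spacing: tuple[float, float, float]

    @property
    def voxel_diagonal_um(self) -> float:
        return float(np.sqrt(np.sum(np.square(self.spacing))))


def tumor_distance_map(mask: TumorMask) -> DistanceMap:
    """Anisotropic EDT of the tumor-mask complement, in micrometres.

    Raises
    ------
    DataError
        If the mask is empty (no tumor to measure distances to).
    """
    if not mask.mask.any():
        raise DataError("tumor mask is empty; distance map undefined")
    values = ndi.distance_transform_edt(~mask.mask, sampling=mask.spacing)
    return DistanceMap(values=values, spacing=tuple(mask.spacing))


def infer_z_centers(
    label_image: np.ndarray,
    gam_volume: np.ndarray,
    spacing: tuple[float, float, float],
    method: str = "weighted_centroid",
    bimodality_prominence: float = 0.25,
) -> pd.DataFrame:
    """Lift 2D footprints to 3D centers using the GAM-channel z-profiles.

    For each labelled footprint, (y, x) is the intensity-weighted centroid
    on the projection and z is either the intensity-weighted centroid of the
    summed z-profile under the footprint (default) or the z of maximum mean
    intensity (``method='max_intensity'``).  A footprint whose z-profile has
    two or more prominent peaks (two cells overlapping in projection) is
    flagged ``low_confidence``.

    Returns a DataFrame with voxel coordinates (``z_vox, y_vox, x_vox``),
    physical coordinates in micrometres (``z_um, y_um, x_um``) and the
    confidence flag, one row per instance.
    """
    label_image = np.asarray(label_image)
    gam_volume = np.asarray(gam_volume, dtype=np.float64)
    if gam_volume.ndim != 3:
        raise DataError("gam_volume must be 3D")
    if label_image.shape != gam_volume.shape[1:]:
        raise DataError("label image must match the volume's (y, x) shape")
    if method not in ("weighted_centroid", "max_intensity"):
        raise DataError(f"unknown z-inference method '{method}'")
    sz, sy, sx = spacing
    projection = gam_volume.max(axis=0)
    zs = np.arange(gam_volume.shape[0], dtype=np.float64)
    rows = []
    for lab in np.unique(label_image):
        if lab == 0:
            continue
        fp = label_image == lab
        if not fp.any():
            raise DataError(f"empty footprint for label {lab}")
        w2d = projection[fp]
        ys, xs = np.nonzero(fp)
        wsum = w2d.sum()
        if wsum <= 0:
            w2d = np.ones_like(w2d)
            wsum = w2d.sum()
        y_c = float((ys * w2d).sum() / wsum)
        x_c = float((xs * w2d).sum() / wsum)
        profile = gam_volume[:, fp].sum(axis=1)
        # the cell occupies few slices; remove the per-slice background
        # pedestal so the camera floor cannot drag the centroid to mid-stack
        profile = np.clip(profile - np.median(profile), 0.0, None)
        psum = profile.sum()
        if psum <= 0:
            z_c = float(zs.mean())
        elif method == "weighted_centroid":
            z_c = float((zs * profile).sum() / psum)
        else:
            z_c = float(np.argmax(profile))
        peaks, _ = find_peaks(
            profile, prominence=bimodality_prominence * max(profile.max(), 1e-12)
        )
        rows.append(
            {
                "instance_id": int(lab),
                "z_vox": z_c,
                "y_vox": y_c,
                "x_vox": x_c,
                "z_um": z_c * sz,
                "y_um": y_c * sy,
                "x_um": x_c * sx,
                "low_confidence": len(peaks) >= 2,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "instance_id", "z_vox", "y_vox", "x_vox",
            "z_um", "y_um", "x_um", "low_confidence",
        ],
    )


def gam_distances(centers: pd.DataFrame, dmap: DistanceMap) -> pd.DataFrame:
    """Distance to the tumor surface for each GAM center, in micrometres.

    The distance is the map value at the center's nearest voxel; centers on
    tumor voxels therefore report 0.  Centers outside the grid raise.
    """
    shape = dmap.values.shape
    out = centers.copy()
    dists = []
    for _, row in centers.iterrows():
        idx = tuple(
            int(round(v)) for v in (row["z_vox"], row["y_vox"], row["x_vox"])
        )
        if any(i < 0 or i >= s for i, s in zip(idx, shape)):
            raise DataError(
                f"GAM center {idx} lies outside the volume grid {shape}"
            )
        dists.append(float(dmap.values[idx]))
    out["distance_um"] = dists
    return out


def filter_within(
    records: pd.DataFrame, radius_um: float = PROXIMITY_RADIUS_UM
) -> pd.DataFrame:
    """Subset of GAM records within ``radius_um`` of the tumor (inclusive)."""
    if radius_um < 0:
        raise DataError("radius must be >= 0")
    if len(records) == 0:
        return records.copy()
    return records[records["distance_um"] <= radius_um].copy()
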