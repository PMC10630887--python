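"""Tumor segmentation in 3D and physical-volume measurement.

Per timepoint, the tumor channel is denoised with a Gaussian blur and
binarised by Otsu's threshold computed on that frame (a per-frame threshold
absorbs photobleaching and expression drift over 8-16 h recordings).  The
physical volume is the voxel count times the anisotropic voxel volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from skimage.filters import threshold_otsu

from .errors import DataError, DegenerateInputError


@dataclass
class TumorMask:
    """Boolean 3D tumor segmentation with its voxel calibration."""

    mask: np.ndarray  # (Z, Y, X) bool
    spacing: tuple[float, float, float]  # (z, y, x) um

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise DataError("tumor mask must be 3D")
        if any(s <= 0 for s in self.spacing):
            raise DataError("spacing must be positive")

    @property
    def voxel_volume_um3(self) -> float:
        sz, sy, sx = self.spacing
        return float(sz * sy * sx)

    @property
    def volume_um3(self) -> float:
        return float(self.mask.sum()) * self.voxel_volume_um3


def _otsu_threshold(volume: np.ndarray, max_exact_levels: int = 4096) -> float:
    """Otsu's threshold, exact over observed intensity levels when few.

    With at most ``max_exact_levels`` distinct values the histogram is built
    on the exact levels, so the returned threshold maximizes inter-class
    variance over the observed levels (matches an exhaustive search);
    otherwise the standard 256-bin histogram is used.
    """
    levels, counts = np.unique(volume, return_counts=True)
    if len(levels) <= max_exact_levels:
        return threshold_otsu(hist=(counts, levels))
    return threshold_otsu(volume)


def segment_tumor(
    volume: np.ndarray,
    spacing: tuple[float, float, float],
    sigma: float = 1.0,
    keep: str = "all",
) -> TumorMask:
    """Gaussian blur + Otsu threshold segmentation of the tumor channel.

    ``sigma`` is the in-plane blur in pixels; along z it is scaled by the
    spacing ratio so the blur is roughly isotropic in physical space.
    ``keep='largest'`` restricts the mask to the largest 26-connected
    component; the default keeps all components because invasive tumors
    fragment.

    Raises
    ------
    DegenerateInputError
        If the volume is constant (Otsu threshold undefined).
    """
    volume = np.asarray(volume, dtype=np.float64)
    if volume.ndim != 3:
        raise DataError("tumor segmentation expects a 3D volume")
    if keep not in ("all", "largest"):
        raise DataError(f"keep must be 'all' or 'largest', got '{keep}'")
    if volume.max() == volume.min():
        raise DegenerateInputError(
            "constant volume: Otsu threshold is undefined"
        )
    sz, sy, sx = spacing
    if sigma > 0:
        sigma_zyx = (sigma * sy / sz, sigma, sigma * sy / sx)
        blurred = ndi.gaussian_filter(volume, sigma=sigma_zyx)
    else:
        blurred = volume
    if blurred.max() == blurred.min():
        raise DegenerateInputError("blurred volume is constant")
    thr = _otsu_threshold(blurred)
    mask = blurred > thr
    if keep == "largest" and mask.any():
        labels, n = ndi.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
        if n > 1:
            counts = np.bincount(labels.ravel())
            counts[0] = 0
            mask = labels == int(np.argmax(counts))
    return TumorMask(mask=mask, spacing=tuple(spacing))


def tumor_volume(mask: TumorMask) -> float:
    """Physical tumor volume in um^3 (voxel count x voxel volume)."""
    return mask.volume_um3
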