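"""Movie container and TIFF I/O.

An :class:`AvatarMovie` holds a 5D intensity record indexed ``(t, channel,
z, y, x)`` together with its physical calibration: the voxel spacing in
micrometres (anisotropic, z usually coarser than xy), the frame interval in
minutes, and the mapping from channel role (``tumor``, ``gam``, ``vessel``)
to channel index.  Per-frame QC flags mark frames in which the embryo moved
out of focus; downstream metric assembly drops a flagged frame and every
frame after it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile

from .errors import DataError, DegenerateInputError

#: canonical channel roles; at least tumor and gam must be present
CHANNEL_ROLES = ("tumor", "gam", "vessel")


@dataclass
class AvatarMovie:
    """5D fluorescence record of one zebrafish avatar, axes (T, C, Z, Y, X).

    Parameters
    ----------
    data
        Non-negative intensities, float32 or integer, shape (T, C, Z, Y, X).
    channels
        Mapping role -> channel index, e.g. ``{"tumor": 0, "gam": 1}``.
    spacing
        Voxel spacing ``(z, y, x)`` in micrometres.
    frame_interval_min
        Time between consecutive frames in minutes.
    in_focus
        Boolean per-frame QC flag; ``False`` marks an out-of-focus frame.
    """

    data: np.ndarray
    channels: dict[str, int]
    spacing: tuple[float, float, float]
    frame_interval_min: float = 20.0
    in_focus: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 5:
            raise DataError(
                f"movie data must be 5D (T,C,Z,Y,X), got ndim={self.data.ndim}"
            )
        if not np.all(np.isfinite(self.data)) or self.data.min() < 0:
            raise DataError("movie intensities must be finite and >= 0")
        if any(s <= 0 for s in self.spacing):
            raise DataError(f"voxel spacing must be positive, got {self.spacing}")
        for role in ("tumor", "gam"):
            if role not in self.channels:
                raise DataError(f"required channel role '{role}' missing")
        n_ch = self.data.shape[1]
        for role, idx in self.channels.items():
            if not 0 <= idx < n_ch:
                raise DataError(f"channel index {idx} for '{role}' out of range")
        if self.in_focus is None:
            self.in_focus = np.ones(self.n_frames, dtype=bool)
        else:
            self.in_focus = np.asarray(self.in_focus, dtype=bool)
            if self.in_focus.shape != (self.n_frames,):
                raise DataError("in_focus must have one flag per frame")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        """(Z, Y, X) shape of one volume."""
        return self.data.shape[2:]

    def channel(self, role: str, t: int | None = None) -> np.ndarray:
        """Return the volume(s) of one channel role.

        With ``t`` given, a single (Z, Y, X) volume; otherwise (T, Z, Y, X).
        """
        if role not in self.channels:
            raise DataError(f"no channel with role '{role}'")
        c = self.channels[role]
        return self.data[:, c] if t is None else self.data[t, c]

    def frame_times_min(self) -> np.ndarray:
        """Acquisition time of each frame in minutes since movie start."""
        return np.arange(self.n_frames) * float(self.frame_interval_min)


def write_movie(movie: AvatarMovie, path) -> None:
    """Write a movie as a multi-page TIFF with TCZYX axis metadata.

    Calibration (spacing, frame interval, channel roles, QC flags) is stored
    in the ImageJ-style / JSON metadata so that :func:`read_movie` round-trips
    the object losslessly.
    """
    meta = {
        "axes": "TCZYX",
        "spacing_um": list(movie.spacing),
        "frame_interval_min": movie.frame_interval_min,
        "channels": movie.channels,
        "in_focus": [bool(f) for f in movie.in_focus],
    }
    tifffile.imwrite(str(path), movie.data, metadata=meta)


def read_movie(
    path,
    axes: str | None = None,
    channels: dict[str, int] | None = None,
    spacing: tuple[float, float, float] | None = None,
    frame_interval_min: float | None = None,
) -> AvatarMovie:
    """Read a multi-page TIFF movie.

    Axis order is taken from file metadata when present; otherwise ``axes``
    must be supplied (e.g. ``"ZYX"`` for a single-frame single-channel
    stack — missing T/C axes are inserted with length 1).  Calibration
    stored at write time is restored; explicit arguments override it.
    """
    try:
        with tifffile.TiffFile(str(path)) as tif:
            series = tif.series[0]
            data = series.asarray()
            file_axes = series.axes
            shaped = tif.shaped_metadata
    except (FileNotFoundError, IsADirectoryError):
        raise
    except Exception as exc:  # corrupt / non-TIFF
        raise DataError(f"cannot read TIFF movie from {path}: {exc}") from None

    meta = {}
    if shaped:
        meta = dict(shaped[0])
    axes_order = axes or meta.get("axes") or file_axes
    if axes_order is None or any(a not in "TCZYXQ" for a in axes_order):
        raise DataError(
            "axis order is ambiguous; pass axes= explicitly (e.g. 'TCZYX')"
        )
    axes_order = axes_order.replace("Q", "T")  # tifffile names unknown axes Q
    if len(axes_order) != data.ndim:
        raise DataError(
            f"axes '{axes_order}' do not match array of ndim {data.ndim}"
        )
    # insert missing singleton axes, then sort to TCZYX
    for a in "TCZYX":
        if a not in axes_order:
            data = data[np.newaxis]
            axes_order = a + axes_order
    order = [axes_order.index(a) for a in "TCZYX"]
    data = np.transpose(data, order)

    channels = channels or meta.get("channels")
    if channels is None:
        if data.shape[1] >= 2:
            channels = {"tumor": 0, "gam": 1}
            if data.shape[1] >= 3:
                channels["vessel"] = 2
        else:
            raise DataError("channel roles unknown; pass channels= mapping")
    spacing = tuple(spacing or meta.get("spacing_um") or (1.0, 1.0, 1.0))
    interval = frame_interval_min or meta.get("frame_interval_min") or 20.0
    in_focus = meta.get("in_focus")
    if in_focus is not None:
        in_focus = np.asarray(in_focus, dtype=bool)
    return AvatarMovie(
        data=data,
        channels=dict(channels),
        spacing=spacing,
        frame_interval_min=float(interval),
        in_focus=in_focus,
        metadata={k: v for k, v in meta.items() if k not in ("shape", "axes")},
    )


def subtract_bleedthrough(
    target: np.ndarray, source: np.ndarray, coefficient: float
) -> np.ndarray:
    """Remove bleed-through of ``source`` into ``target``.

    Returns ``max(target - coefficient * source, 0)`` elementwise; used to
    remove tumor-signal bleed-through from the vascular channel.
    """
    target = np.asarray(target, dtype=np.float64)
    source = np.asarray(source, dtype=np.float64)
    if target.shape != source.shape:
        raise DataError(
            f"shape mismatch: target {target.shape} vs source {source.shape}"
        )
    if coefficient < 0:
        raise DataError("bleed-through coefficient must be >= 0")
    return np.maximum(target - coefficient * source, 0.0)


def estimate_bleedthrough(
    target: np.ndarray, source: np.ndarray, source_mask: np.ndarray
) -> float:
    """Least-squares bleed-through coefficient on source-only voxels.

    Fits ``target ~ coefficient * source`` over ``source_mask`` (voxels known
    to contain only the bleeding signal, e.g. tumor-only voxels).
    """
    s = np.asarray(source, dtype=np.float64)[source_mask]
    t = np.asarray(target, dtype=np.float64)[source_mask]
    denom = float(np.dot(s, s))
    if denom == 0:
        raise DegenerateInputError("source has no signal on the given mask")
    return float(np.dot(s, t) / denom)
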