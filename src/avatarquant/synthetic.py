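"""Synthetic avatar movies and IHC slides with known ground truth.

The generator emulates the statistical and geometric structure the
quantification pipeline assumes, so that every downstream stage can be
tested against a known answer without the deposited imaging data:

* a bright, compact (spherical) tumor whose true volume follows a
  per-frame multiplicative schedule;
* round GAM phantoms (near-spherical, projected circularity > 0.6) and
  ramified GAM phantoms (a soma with 2-4 curved processes, projected
  circularity < 0.35), placed at controlled true distances from the tumor
  surface;
* spatially smooth autofluorescent blobs present in BOTH the tumor and GAM
  channels;
* Poisson shot noise on the signal plus additive Gaussian read noise, on an
  anisotropic voxel grid.

For the slide pipeline, fields of touching elliptical nuclei carry DAPI /
SOX2 / GAL1 intensities drawn from configured distributions on top of a
smooth background that is exactly reproduced in the pre-stain image.

Generation is a pure function of (config, seed): identical inputs give
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from .errors import DataError, PlacementError
from .gam import compute_morphometrics
from .movie import AvatarMovie
from .preprocess import CLASS_CODES


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class DistanceLaw:
    """Mixture law for true GAM center-to-tumor-surface distances (um).

    A fraction ``frac_near`` of GAMs is drawn uniformly within the proximity
    band [0, near_max]; the rest uniformly in (near_max, far_max] — so both
    the near-tumor subset and far surveillant GAMs exist by construction.
    """

    frac_near: float = 0.5
    near_max_um: float = 30.0
    far_max_um: float = 55.0

    def sample(self, rng: np.random.Generator) -> float:
        if rng.random() < self.frac_near:
            return float(rng.uniform(0.0, self.near_max_um))
        return float(rng.uniform(self.near_max_um, self.far_max_um))


@dataclass
class AvatarConfig:
    """Parameters of one synthetic avatar movie.

    Defaults describe a typical overnight confocal recording: a 256x256x40
    grid at (3.0, 0.8, 0.8) um voxel spacing, one frame every 20 minutes,
    a tumor of 1e5 um^3 (a few hundred engrafted cells) shrinking by 5% per
    frame, and 20 GAMs split 12 round / 8 ramified.
    """

    shape: tuple[int, int, int, int] = (10, 40, 256, 256)  # (T, Z, Y, X)
    spacing: tuple[float, float, float] = (3.0, 0.8, 0.8)  # um (z, y, x)
    frame_interval_min: float = 20.0
    n_round: int = 12
    n_ramified: int = 8
    tumor_start_volume_um3: float = 1.0e5
    tumor_volume_multiplier: float = 0.95
    distance_law: DistanceLaw = field(default_factory=DistanceLaw)
    autofluorescence_density: float = 0.15
    poisson_gain: float = 0.5
    gaussian_sd: float = 2.0
    include_vessel: bool = False
    vessel_bleedthrough: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if any(int(s) <= 0 for s in self.shape):
            raise DataError(f"grid shape must be positive, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise DataError("voxel spacing must be positive")
        if self.n_round < 0 or self.n_ramified < 0:
            raise DataError("GAM counts must be >= 0")
        if self.tumor_volume_multiplier <= 0:
            raise DataError("tumor volume multiplier must be > 0")
        if not 0.0 <= self.autofluorescence_density <= 1.0:
            raise DataError("autofluorescence density must be in [0, 1]")
        if self.tumor_start_volume_um3 <= 0:
            raise DataError("tumor start volume must be > 0")


@dataclass
class GroundTruth:
    """Everything the generator knows about a movie.

    The true tumor volume is the analytic sphere volume of the schedule
    (exact under the multiplier); the rasterized mask realises it on the
    voxel grid.  GAM phantoms are static across frames, so their true
    distance to the (shrinking) tumor surface changes per frame.
    """

    spacing: tuple[float, float, float]
    tumor_masks: np.ndarray          # (T, Z, Y, X) bool
    tumor_volumes_um3: np.ndarray    # (T,) analytic
    tumor_center_um: np.ndarray      # (3,) physical (z, y, x)
    tumor_radii_um: np.ndarray       # (T,)
    gam_labels_3d: np.ndarray        # (Z, Y, X) int32 instance labels
    af_mask: np.ndarray              # (Z, Y, X) bool
    gams: pd.DataFrame               # gam_id, shape_class, center coords
    distances: pd.DataFrame          # frame, gam_id, shape_class, distance_um

    @property
    def n_frames(self) -> int:
        return self.tumor_masks.shape[0]

    def gam_labels_2d(self) -> np.ndarray:
        """Projected instance labels (valid because footprints are disjoint
        in projection by construction)."""
        return self.gam_labels_3d.max(axis=0).astype(np.int32)


def generate_annotation_volume(truth: GroundTruth, t: int) -> np.ndarray:
    """Per-voxel class-label volume for frame ``t``.

    Classes follow :data:`~avatarquant.preprocess.CLASS_CODES`; precedence
    where structures overlap is tumor > gam > autofluorescence, and
    background is the complement, so labels partition the grid.
    """
    if not 0 <= t < truth.n_frames:
        raise DataError(f"frame {t} out of range [0, {truth.n_frames})")
    labels = np.zeros(truth.gam_labels_3d.shape, dtype=np.uint8)
    labels[truth.af_mask] = CLASS_CODES["autofluorescence"]
    labels[truth.gam_labels_3d > 0] = CLASS_CODES["gam"]
    labels[truth.tumor_masks[t]] = CLASS_CODES["tumor"]
    return labels


# ---------------------------------------------------------------------------
# phantom rasterization helpers
# ---------------------------------------------------------------------------

def _stamp_spheres(mask, centers_um, radii_um, spacing):
    """Rasterize a union of spheres (physical coordinates) into ``mask``."""
    sz, sy, sx = spacing
    Z, Y, X = mask.shape
    for c, r in zip(centers_um, radii_um):
        lo = [max(0, int((c[i] - r) / s)) for i, s in enumerate(spacing)]
        hi = [
            min(n, int((c[i] + r) / s) + 2)
            for i, (s, n) in enumerate(zip(spacing, (Z, Y, X)))
        ]
        if any(l >= h for l, h in zip(lo, hi)):
            continue
        zz, yy, xx = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        d2 = (
            (zz * sz - c[0]) ** 2
            + (yy * sy - c[1]) ** 2
            + (xx * sx - c[2]) ** 2
        )
        mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= d2 <= r**2


def _round_phantom(center_um, rng, spacing, grid_shape):
    """Near-spherical phantom (axis ratio <= 1.3) as a voxel mask."""
    r = rng.uniform(3.4, 4.8)  # um
    ratio = rng.uniform(1.0, 1.3)
    # slight in-plane ellipticity: stretch y by `ratio`
    mask = np.zeros(grid_shape, dtype=bool)
    sz, sy, sx = spacing
    lo = [
        max(0, int((center_um[i] - r * ratio) / s))
        for i, s in enumerate(spacing)
    ]
    hi = [
        min(n, int((center_um[i] + r * ratio) / s) + 2)
        for i, (s, n) in enumerate(zip(spacing, grid_shape))
    ]
    zz, yy, xx = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    d2 = (
        ((zz * sz - center_um[0]) / r) ** 2
        + ((yy * sy - center_um[1]) / (r * ratio)) ** 2
        + ((xx * sx - center_um[2]) / r) ** 2
    )
    mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = d2 <= 1.0
    return mask, r * ratio


def _ramified_phantom(center_um, rng, spacing, grid_shape):
    """Soma plus 2-4 curved thin processes, mostly in-plane."""
    soma_r = rng.uniform(1.6, 2.1)  # um
    n_arms = int(rng.integers(3, 5))
    arm_w = 1.3  # um, tube radius
    centers = [np.asarray(center_um, dtype=float)]
    radii = [soma_r]
    base = rng.uniform(0.0, 2 * np.pi)
    max_reach = soma_r
    for k in range(n_arms):
        theta = base + 2 * np.pi * k / n_arms + rng.uniform(-0.3, 0.3)
        length = rng.uniform(5.0, 7.0) * soma_r
        bend = rng.uniform(-0.5, 0.5) / max(length, 1e-6)  # rad per um
        # small z excursion, capped so thin arms never fall between slices
        zdrift = rng.uniform(-0.4, 0.4)  # total um over the arm
        n_steps = max(int(length / 0.5), 4)
        pos = np.asarray(center_um, dtype=float)
        ang = theta
        for s in range(1, n_steps + 1):
            step = length / n_steps
            ang += bend * step
            pos = pos + np.array(
                [zdrift / n_steps, np.sin(ang) * step, np.cos(ang) * step]
            )
            centers.append(pos.copy())
            radii.append(arm_w)
        max_reach = max(max_reach, length + arm_w)
    mask = np.zeros(grid_shape, dtype=bool)
    _stamp_spheres(mask, centers, radii, spacing)
    return mask, max_reach


def _projected_circularity(mask3d) -> float:
    proj = mask3d.any(axis=0).astype(np.int32)
    dets = compute_morphometrics(proj)
    if len(dets) != 1:
        return np.nan  # fragmented in projection; caller retries
    return dets[0].circularity


# ---------------------------------------------------------------------------
# movie generation
# ---------------------------------------------------------------------------

def _tumor_radius_um(volume_um3: float) -> float:
    return (3.0 * volume_um3 / (4.0 * np.pi)) ** (1.0 / 3.0)


def generate_avatar_movie(config: AvatarConfig):
    """Generate one synthetic avatar movie and its ground truth.

    Returns ``(AvatarMovie, GroundTruth)``.  Raises
    :class:`~avatarquant.errors.PlacementError` when the requested number of
    phantoms cannot be placed without projected overlap (overcrowded grid).
    """
    rng = np.random.default_rng(config.seed)
    T, Z, Y, X = config.shape
    sz, sy, sx = config.spacing
    grid_shape = (Z, Y, X)
    extent_um = np.array([Z * sz, Y * sy, X * sx])
    tumor_center = extent_um / 2.0

    volumes = config.tumor_start_volume_um3 * (
        config.tumor_volume_multiplier ** np.arange(T)
    )
    radii = _tumor_radius_um(volumes)
    if radii[0] * 2 > min(extent_um):
        raise DataError("tumor does not fit in the grid; enlarge the shape")

    # --- tumor masks ----------------------------------------------------
    zz, yy, xx = np.ogrid[:Z, :Y, :X]
    d2_center = (
        (zz * sz - tumor_center[0]) ** 2
        + (yy * sy - tumor_center[1]) ** 2
        + (xx * sx - tumor_center[2]) ** 2
    )
    tumor_masks = np.stack([d2_center <= r**2 for r in radii])

    # --- GAM phantom placement -----------------------------------------
    gam_labels = np.zeros(grid_shape, dtype=np.int32)
    kinds = ["round"] * config.n_round + ["ramified"] * config.n_ramified
    placed: list[dict] = []
    occupied_yx: list[tuple[float, float, float]] = []  # (y_um, x_um, reach)
    for i, kind in enumerate(kinds):
        ok = False
        for _ in range(500):
            d = config.distance_law.sample(rng)
            u = rng.normal(size=3)
            u[0] *= 0.35  # recordings are flat: GAMs spread mostly in-plane
            u /= np.linalg.norm(u)
            center = tumor_center + (radii[0] + d) * u
            # snap to the nearest slice plane so thin processes rasterize
            # continuously under coarse z sampling
            center[0] = np.clip(round(center[0] / sz), 0, None) * sz
            reach = 16.0 if kind == "ramified" else 7.0
            margin = np.array([max(3.0 * sz, 8.0), reach, reach])
            if np.any(center < margin) or np.any(center > extent_um - margin):
                continue
            if any(
                np.hypot(center[1] - oy, center[2] - ox) < reach + oreach + 3.0
                for oy, ox, oreach in occupied_yx
            ):
                continue
            if kind == "round":
                mask, fp = _round_phantom(center, rng, config.spacing, grid_shape)
                c_lo, c_hi = 0.62, np.inf
            else:
                mask, fp = _ramified_phantom(center, rng, config.spacing, grid_shape)
                c_lo, c_hi = -np.inf, 0.22
            circ = _projected_circularity(mask)
            if not (np.isfinite(circ) and c_lo < circ < c_hi):
                continue
            ok = True
            break
        if not ok:
            raise PlacementError(
                f"failed to place {kind} phantom {i + 1} of {len(kinds)} "
                f"(n_round={config.n_round}, n_ramified={config.n_ramified}): "
                "grid too crowded"
            )
        gam_labels[mask] = i + 1
        occupied_yx.append((center[1], center[2], fp))
        # true center = intensity-weighted centroid of the phantom voxels
        vox = np.argwhere(mask)
        centroid_um = vox.mean(axis=0) * np.array(config.spacing)
        placed.append(
            {
                "gam_id": i + 1,
                "shape_class": kind,
                "z_um": centroid_um[0],
                "y_um": centroid_um[1],
                "x_um": centroid_um[2],
                "z_vox": centroid_um[0] / sz,
                "y_vox": centroid_um[1] / sy,
                "x_vox": centroid_um[2] / sx,
                "projected_circularity": circ,
            }
        )
    gams = pd.DataFrame(
        placed,
        columns=[
            "gam_id", "shape_class", "z_um", "y_um", "x_um",
            "z_vox", "y_vox", "x_vox", "projected_circularity",
        ],
    )

    # --- autofluorescent blobs (both channels) --------------------------
    n_af = int(round(config.autofluorescence_density * 20))
    af_field = np.zeros(grid_shape, dtype=np.float32)
    for _ in range(n_af):
        for _try in range(200):
            cy, cx = rng.uniform(15, Y - 15) * sy, rng.uniform(15, X - 15) * sx
            cz = rng.uniform(2, Z - 2) * sz
            if all(
                np.hypot(cy - oy, cx - ox) > oreach + 14.0
                for oy, ox, oreach in occupied_yx
            ):
                break
        else:
            raise PlacementError("failed to place autofluorescent blob")
        sig_xy = rng.uniform(3.5, 7.0)  # um
        amp = rng.uniform(60.0, 90.0)
        zz2 = ((zz * sz - cz) / (2.0 * sig_xy)) ** 2
        yy2 = ((yy * sy - cy) / sig_xy) ** 2
        xx2 = ((xx * sx - cx) / sig_xy) ** 2
        af_field += amp * np.exp(-0.5 * (zz2 + yy2 + xx2))
    af_mask = af_field > 25.0

    # --- distances per frame -------------------------------------------
    dist_rows = []
    for t in range(T):
        for _, g in gams.iterrows():
            c = np.array([g["z_um"], g["y_um"], g["x_um"]])
            d = max(0.0, float(np.linalg.norm(c - tumor_center)) - radii[t])
            dist_rows.append(
                {
                    "frame": t,
                    "gam_id": int(g["gam_id"]),
                    "shape_class": g["shape_class"],
                    "distance_um": d,
                }
            )
    distances = pd.DataFrame(
        dist_rows, columns=["frame", "gam_id", "shape_class", "distance_um"]
    )

    # --- intensities ----------------------------------------------------
    gam_amp = rng.uniform(140.0, 180.0, size=len(kinds))
    psf = (0.4, 0.7, 0.7)
    n_channels = 3 if config.include_vessel else 2
    data = np.zeros((T, n_channels, Z, Y, X), dtype=np.float32)
    gam_clean_base = np.zeros(grid_shape, dtype=np.float32)
    for i in range(len(kinds)):
        gam_clean_base[gam_labels == i + 1] = gam_amp[i]
    gam_clean_base += af_field
    gam_clean = ndi.gaussian_filter(gam_clean_base, psf) + 5.0
    for t in range(T):
        tumor_clean = np.where(tumor_masks[t], 180.0, 0.0).astype(np.float32)
        tumor_clean += af_field
        tumor_clean = ndi.gaussian_filter(tumor_clean, psf) + 5.0
        for ci, clean in enumerate((tumor_clean, gam_clean)):
            shot = rng.poisson(clean * config.poisson_gain) / config.poisson_gain
            noisy = shot + rng.normal(0.0, config.gaussian_sd, size=grid_shape)
            data[t, ci] = np.maximum(noisy, 0.0)
        if config.include_vessel:
            vessel = config.vessel_bleedthrough * tumor_clean
            shot = rng.poisson(vessel * config.poisson_gain) / config.poisson_gain
            data[t, 2] = np.maximum(
                shot + rng.normal(0.0, config.gaussian_sd, size=grid_shape), 0.0
            )

    channels = {"tumor": 0, "gam": 1}
    if config.include_vessel:
        channels["vessel"] = 2
    movie = AvatarMovie(
        data=data,
        channels=channels,
        spacing=config.spacing,
        frame_interval_min=config.frame_interval_min,
        metadata={"generator_seed": config.seed},
    )
    truth = GroundTruth(
        spacing=config.spacing,
        tumor_masks=tumor_masks,
        tumor_volumes_um3=volumes,
        tumor_center_um=tumor_center,
        tumor_radii_um=radii,
        gam_labels_3d=gam_labels,
        af_mask=af_mask,
        gams=gams,
        distances=distances,
    )
    return movie, truth


# ---------------------------------------------------------------------------
# IHC slide generation
# ---------------------------------------------------------------------------

@dataclass
class SlideConfig:
    """Parameters of one synthetic multiplex IF slide.

    ``gal1_effect`` shifts the mean GAL1 intensity of SOX2-positive cells
    relative to ``gal1_base``; an effect of 0 makes the two populations
    identical in expectation.
    """

    shape: tuple[int, int] = (384, 384)
    n_cells: int = 60
    sox2_positive_fraction: float = 0.4
    nucleus_radius_px: tuple[float, float] = (6.0, 9.0)
    min_separation_factor: float = 0.95  # of summed radii; <1 lets nuclei touch
    dapi_amp: tuple[float, float] = (140.0, 180.0)
    sox2_amp_positive: float = 120.0
    sox2_amp_negative: float = 12.0
    gal1_base: float = 40.0
    gal1_effect: float = 30.0
    gal1_sd: float = 8.0
    background_amp: float = 30.0
    noise_sd: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 1:
            raise DataError("n_cells must be >= 1")
        if not 0.0 <= self.sox2_positive_fraction <= 1.0:
            raise DataError("sox2_positive_fraction must be in [0, 1]")


@dataclass
class SlideTruth:
    """Ground truth of one synthetic slide."""

    nucleus_labels: np.ndarray    # (Y, X) int32
    cells: pd.DataFrame           # cell_id, y, x, sox2_positive, gal1_mean
    background: np.ndarray        # the smooth field == pre-stain image


def generate_ihc_slide(config: SlideConfig):
    """Generate (measured channel images, pre-stain image, ground truth).

    Returns ``(images, prestain, truth)`` where ``images`` maps channel name
    (``dapi``, ``sox2``, ``gal1``) to a float32 image.  The pre-stain image
    equals the smooth background field exactly (no marker signal, no noise).
    """
    rng = np.random.default_rng(config.seed)
    Y, X = config.shape
    r_lo, r_hi = config.nucleus_radius_px

    # smooth background: broad Gaussian bumps + a gentle plane
    yy, xx = np.mgrid[:Y, :X].astype(np.float64)
    background = config.background_amp * (
        0.3 + 0.2 * xx / X + 0.1 * yy / Y
    )
    for _ in range(4):
        cy, cx = rng.uniform(0, Y), rng.uniform(0, X)
        sig = rng.uniform(0.2, 0.4) * min(Y, X)
        background += (
            config.background_amp
            * rng.uniform(0.2, 0.5)
            * np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sig**2)))
        )
    background = background.astype(np.float32)

    # nucleus placement: dart throwing, touching allowed
    placed = []
    for i in range(config.n_cells):
        for _try in range(400):
            ry = rng.uniform(r_lo, r_hi)
            rx = ry * rng.uniform(0.7, 1.0)
            ang = rng.uniform(0, np.pi)
            cy = rng.uniform(r_hi + 2, Y - r_hi - 2)
            cx = rng.uniform(r_hi + 2, X - r_hi - 2)
            if all(
                np.hypot(cy - p["y"], cx - p["x"])
                >= config.min_separation_factor * (max(ry, rx) + p["r"])
                for p in placed
            ):
                placed.append(
                    {"cell_id": i + 1, "y": cy, "x": cx, "ry": ry, "rx": rx,
                     "angle": ang, "r": max(ry, rx)}
                )
                break
        else:
            raise PlacementError(
                f"failed to place nucleus {i + 1} of {config.n_cells}: "
                "field too crowded"
            )

    labels = np.zeros((Y, X), dtype=np.int32)
    for p in placed:
        ca, sa = np.cos(p["angle"]), np.sin(p["angle"])
        dy, dx = yy - p["y"], xx - p["x"]
        u = ca * dx + sa * dy
        v = -sa * dx + ca * dy
        inside = (u / p["rx"]) ** 2 + (v / p["ry"]) ** 2 <= 1.0
        labels[inside & (labels == 0)] = p["cell_id"]

    n_pos = int(round(config.sox2_positive_fraction * config.n_cells))
    pos_ids = set(rng.choice(config.n_cells, size=n_pos, replace=False) + 1)

    dapi = np.zeros((Y, X), dtype=np.float32)
    sox2 = np.zeros((Y, X), dtype=np.float32)
    gal1 = np.zeros((Y, X), dtype=np.float32)
    # GAL1 is cytoplasmic: paint it on a small dilation of the nucleus
    expanded = ndi.grey_dilation(labels, size=(7, 7))
    expanded = np.where(labels > 0, labels, expanded)
    cells_rows = []
    for p in placed:
        cid = p["cell_id"]
        is_pos = cid in pos_ids
        nucleus = labels == cid
        dapi[nucleus] = rng.uniform(*config.dapi_amp)
        sox2[nucleus] = (
            config.sox2_amp_positive if is_pos else config.sox2_amp_negative
        )
        mu = config.gal1_base + (config.gal1_effect if is_pos else 0.0)
        g = float(rng.normal(mu, config.gal1_sd))
        gal1[expanded == cid] = max(g, 0.0)
        cells_rows.append(
            {
                "cell_id": cid, "y": p["y"], "x": p["x"],
                "sox2_positive": is_pos, "gal1_mean": max(g, 0.0),
            }
        )
    cells = pd.DataFrame(
        cells_rows, columns=["cell_id", "y", "x", "sox2_positive", "gal1_mean"]
    )

    images = {}
    for name, signal in (("dapi", dapi), ("sox2", sox2), ("gal1", gal1)):
        sm = ndi.gaussian_filter(signal, 1.0)
        noisy = sm + background + rng.normal(0, config.noise_sd, size=(Y, X))
        images[name] = np.maximum(noisy, 0.0).astype(np.float32)

    truth = SlideTruth(
        nucleus_labels=labels, cells=cells, background=background
    )
    return images, background.copy(), truth
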