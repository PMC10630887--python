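"""Per-movie metric tables and Mann-Kendall trend statistics.

The Mann-Kendall test asks whether a time series drifts monotonically.  Its
statistic is

    S = sum_{i<j} sign(x_j - x_i),

with Kendall's tau as the tie-corrected normalisation of S.  For short
tie-free series (n <= 10) the two-sided p-value is exact, computed from the
permutation-null distribution of S via the inversion-count generating
function; otherwise the normal approximation with tie-corrected variance
and continuity correction is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import DataError
from .spatial import PROXIMITY_RADIUS_UM

#: imaging-window hour ranges (hours post injection) used for the
#: start / mid / end labels of 1 dpi and 5 dpi recordings
DEFAULT_WINDOWS_HPI = {
    "start": ((24.0, 26.0), (114.0, 116.0)),
    "mid": ((30.0, 32.0),),
    "end": ((37.0, 39.0), (117.0, 119.0)),
}


@dataclass
class TrendResult:
    """Mann-Kendall trend test outcome."""

    S: int
    tau: float
    p_value: float
    n: int


def _exact_s_distribution(n: int) -> np.ndarray:
    """Null counts of inversion numbers of a random permutation of size n.

    ``counts[k]`` = number of permutations with k inversions, obtained from
    the generating function  prod_{i=1..n-1} (1 + x + ... + x^i).  For a
    tie-free series, S = n(n-1)/2 - 2k, so this is the exact permutation
    distribution of S.
    """
    counts = np.array([1.0])
    for i in range(1, n):
        kernel = np.ones(i + 1)
        counts = np.convolve(counts, kernel)
    return counts


def mann_kendall(series) -> TrendResult:
    """Two-sided Mann-Kendall trend test on a 1D series.

    Exact p for tie-free series with n <= 10; tie-corrected normal
    approximation with continuity correction otherwise.  A constant series
    gives S = 0, tau = 0, p = 1.
    """
    x = np.asarray(series, dtype=np.float64)
    if x.ndim != 1:
        raise DataError("series must be 1D")
    n = len(x)
    if n < 3:
        raise DataError(f"Mann-Kendall requires n >= 3, got n={n}")
    if not np.all(np.isfinite(x)):
        raise DataError("series contains non-finite values")

    diff_sign = np.sign(x[:, None] - x[None, :])
    S = int(np.triu(diff_sign.T, k=1).sum())

    n_pairs = n * (n - 1) // 2
    _, tie_counts = np.unique(x, return_counts=True)
    ties = tie_counts[tie_counts > 1]
    d2 = n_pairs - int(np.sum(ties * (ties - 1) // 2))
    tau = S / np.sqrt(n_pairs * d2) if d2 > 0 else 0.0

    if d2 == 0 or S == 0:
        p = 1.0
    elif len(ties) == 0 and n <= 10:
        counts = _exact_s_distribution(n)
        k = np.arange(len(counts))
        s_values = n_pairs - 2 * k
        tail = counts[np.abs(s_values) >= abs(S)].sum()
        p = float(tail / counts.sum())
    else:
        var = (
            n * (n - 1) * (2 * n + 5)
            - np.sum(ties * (ties - 1) * (2 * ties + 5))
        ) / 18.0
        z = (S - np.sign(S)) / np.sqrt(var)
        p = float(2.0 * norm.sf(abs(z)))
    return TrendResult(S=S, tau=float(tau), p_value=min(p, 1.0), n=n)


def label_window(hpi: float, windows: dict | None = None) -> str | None:
    """Map an hours-post-injection time to a start/mid/end window label."""
    windows = windows or DEFAULT_WINDOWS_HPI
    for label, ranges in windows.items():
        for lo, hi in ranges:
            if lo <= hpi <= hi:
                return label
    return None


def build_metrics_table(
    tumor_masks,
    gam_records: pd.DataFrame,
    frame_times_min,
    in_focus=None,
    injection_offset_hpi: float | None = None,
    proximity_radius_um: float = PROXIMITY_RADIUS_UM,
) -> pd.DataFrame:
    """Assemble the per-timepoint metrics table of one movie.

    Parameters
    ----------
    tumor_masks
        Sequence of :class:`~avatarquant.tumor.TumorMask`, one per frame.
    gam_records
        Tidy per-GAM table with at least columns ``frame``, ``shape_class``
        and ``distance_um``.
    frame_times_min
        Acquisition time of each frame in minutes since movie start.
    in_focus
        Optional boolean QC flags; the first out-of-focus frame and all
        subsequent frames are removed from the table.
    injection_offset_hpi
        Hours post injection at movie start; enables start/mid/end window
        labels when given.

    Returns
    -------
    DataFrame with one row per retained frame: tumor volume (um^3), round /
    ramified / total GAM counts, mean and median distance (um, NaN when no
    GAMs) and the count within the proximity radius.
    """
    frame_times_min = np.asarray(frame_times_min, dtype=np.float64)
    n = len(frame_times_min)
    if n == 0:
        raise DataError("no timepoints")
    if len(tumor_masks) != n:
        raise DataError("one tumor mask per frame required")
    if in_focus is None:
        in_focus = np.ones(n, dtype=bool)
    in_focus = np.asarray(in_focus, dtype=bool)
    bad = np.flatnonzero(~in_focus)
    last = int(bad[0]) if len(bad) else n  # drop flagged frame and the rest

    rows = []
    for t in range(last):
        sub = gam_records[gam_records["frame"] == t]
        n_round = int((sub["shape_class"] == "round").sum())
        n_ram = int((sub["shape_class"] == "ramified").sum())
        dists = sub["distance_um"].to_numpy(dtype=np.float64)
        t_min = float(frame_times_min[t])
        window = None
        if injection_offset_hpi is not None:
            window = label_window(injection_offset_hpi + t_min / 60.0)
        rows.append(
            {
                "frame": t,
                "t_min": t_min,
                "window": window,
                "tumor_volume_um3": tumor_masks[t].volume_um3,
                "n_round": n_round,
                "n_ramified": n_ram,
                "n_total": int(len(sub)),
                "mean_distance_um": float(np.mean(dists)) if len(dists) else np.nan,
                "median_distance_um": float(np.median(dists)) if len(dists) else np.nan,
                "n_within_30um": int((dists <= proximity_radius_um).sum()),
            }
        )
    return pd.DataFrame(rows)
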