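"""Per-track dynamics: MSD, diffusion coefficient, maximum distance,
velocity, and per-cell/ensemble summaries with group comparison.

Conventions
-----------
* MSD uses overlapping windows (all start points) at lags 1…max_lag,
  default max_lag 7.
* The diffusion coefficient is the OLS slope of MSD vs lag time with a
  free intercept (the intercept absorbs static localization error),
  divided by 4 (2-D Brownian MSD = 4Dτ).  ``convention="slope"`` keeps
  the raw slope for pipelines that define D as the slope itself.
  Negative fitted slopes are clamped to zero and flagged.
* Velocity is total path length divided by elapsed time; maximum
  distance is the farthest excursion from the track start.
* Log diffusion summaries use log10; zero/clamped D are tallied
  separately since their log is undefined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import MannWhitneyResult, mann_whitney
from .tracks import Track, TrackSet

DEFAULT_MAX_LAG = 7


@dataclass
class MSDProfile:
    """Mean squared displacement per time lag for one track."""

    lags_s: np.ndarray     # τ_k = k·Δt
    msd_um2: np.ndarray
    n_pairs: np.ndarray    # displacement pairs averaged per lag

    def __post_init__(self) -> None:
        self.lags_s = np.asarray(self.lags_s, dtype=float)
        self.msd_um2 = np.asarray(self.msd_um2, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=int)
        if not (len(self.lags_s) == len(self.msd_um2) == len(self.n_pairs)):
            raise ValueError("lag, msd, n_pairs lengths differ")
        if len(self.lags_s) < 1:
            raise ValueError("profile needs at least one lag")
        if np.any(self.msd_um2 < 0) or np.any(self.n_pairs <= 0):
            raise ValueError("msd must be >= 0 and n_pairs > 0")


def msd(track: Track, max_lag: int = DEFAULT_MAX_LAG) -> MSDProfile:
    """Time-averaged MSD over lags 1…max_lag (overlapping windows).

    msd_k = mean over i of |r(t_i + kΔt) − r(t_i)|².  The track must be
    longer than ``max_lag`` points.  Assumes consecutive frames (the
    tracking pipeline produces gap-free tracks).
    """
    n = len(track)
    if n <= max_lag:
        raise ValueError(
            f"track of {n} points too short for max_lag {max_lag}; "
            f"need at least {max_lag + 1} points")
    pos = track.positions
    lags = np.arange(1, max_lag + 1)
    vals = np.empty(max_lag)
    npair = np.empty(max_lag, dtype=int)
    for k in lags:
        d = pos[k:] - pos[:-k]
        vals[k - 1] = float(np.mean(np.sum(d * d, axis=1)))
        npair[k - 1] = n - k
    return MSDProfile(lags * track.frame_interval, vals, npair)


@dataclass
class DiffusionFit:
    """OLS fit of an MSD profile."""

    D: float             # µm²/s under the chosen convention
    slope: float         # raw fitted slope, µm²/s
    intercept: float     # µm²
    clamped: bool        # True if a negative slope was clamped to 0
    convention: str      # "slope/4" or "slope"


def diffusion_coefficient(profile: MSDProfile,
                          convention: str = "slope/4") -> DiffusionFit:
    """Diffusion coefficient from the slope of MSD vs lag time.

    Ordinary least squares with a free intercept over all lags of the
    profile.  ``convention="slope/4"`` (default) applies the 2-D
    Brownian relation MSD = 4Dτ; ``"slope"`` reports the raw slope.
    A negative fitted slope yields D = 0 with ``clamped=True``.
    """
    if convention not in ("slope/4", "slope"):
        raise ValueError("convention must be 'slope/4' or 'slope'")
    x, y = profile.lags_s, profile.msd_um2
    if len(x) < 2:
        raise ValueError("need at least two lags to fit a slope")
    if np.ptp(x) == 0:
        raise ValueError("all lags equal; slope undefined")
    slope, intercept = np.polyfit(x, y, 1)
    d = slope / 4.0 if convention == "slope/4" else slope
    clamped = d < 0
    return DiffusionFit(max(d, 0.0), float(slope), float(intercept),
                        bool(clamped), convention)


def max_distance(track: Track) -> float:
    """Farthest Euclidean distance from the track start, µm."""
    disp = track.positions - track.positions[0]
    return float(np.max(np.linalg.norm(disp, axis=1)))


def track_velocity(track: Track) -> float:
    """Mean speed: total path length divided by elapsed time, µm/s."""
    t = track.t_s
    elapsed = t[-1] - t[0]
    if elapsed <= 0:
        raise ValueError("elapsed time must be positive")
    steps = np.diff(track.positions, axis=0)
    path = float(np.sum(np.linalg.norm(steps, axis=1)))
    return path / elapsed


@dataclass
class DynamicsSummary:
    """Per-track metrics plus per-cell and ensemble medians."""

    per_track: pd.DataFrame   # track_id, cell_id, D, log10_D, d_max_um, velocity_um_s
    per_cell: pd.DataFrame    # cell_id, median_* columns, n_tracks
    ensemble: pd.Series       # medians over all tracks
    n_zero_D: int             # tracks whose D was 0 (log10 undefined)


def summarize(tracks: TrackSet, cell_map: dict | None = None,
              max_lag: int = DEFAULT_MAX_LAG,
              convention: str = "slope/4") -> DynamicsSummary:
    """Per-track D, max distance and velocity with cell-level medians.

    ``cell_map`` maps track_id → cell label; omitted tracks fall back to
    the track's own ``cell_id`` (error if neither is available).
    Tracks shorter than ``max_lag + 1`` points are skipped for D but
    still contribute distance and velocity.
    """
    rows = []
    for tr in tracks:
        if cell_map is not None:
            if tr.track_id not in cell_map:
                raise KeyError(f"track {tr.track_id} missing from cell_map")
            cell = cell_map[tr.track_id]
        elif tr.cell_id is not None:
            cell = tr.cell_id
        else:
            raise ValueError(
                f"track {tr.track_id} has no cell assignment; pass cell_map")
        if len(tr) > max_lag:
            fit = diffusion_coefficient(msd(tr, max_lag), convention)
            d_val = fit.D
        else:
            d_val = np.nan
        rows.append({
            "track_id": tr.track_id, "cell_id": cell,
            "D_um2_per_s": d_val,
            "log10_D": np.log10(d_val) if d_val and d_val > 0 else np.nan,
            "d_max_um": max_distance(tr),
            "velocity_um_s": track_velocity(tr),
        })
    per_track = pd.DataFrame(rows)
    if per_track.empty:
        raise ValueError("empty track set")
    n_zero = int((per_track["D_um2_per_s"] == 0).sum())

    metric_cols = ["D_um2_per_s", "log10_D", "d_max_um", "velocity_um_s"]
    per_cell = (per_track.groupby("cell_id")[metric_cols].median()
                .add_prefix("median_").reset_index())
    per_cell["n_tracks"] = per_track.groupby("cell_id").size().values
    ensemble = per_track[metric_cols].median().add_prefix("median_")
    return DynamicsSummary(per_track, per_cell, ensemble, n_zero)


def compare_groups(a, b) -> MannWhitneyResult:
    """Two-tailed Mann–Whitney U between two groups of per-cell (or
    per-track) statistics; exact for small samples."""
    return mann_whitney(a, b)
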