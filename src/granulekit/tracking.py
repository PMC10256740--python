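"""Movie-to-tracks pipeline: background correction, spot detection,
frame-to-frame linking, and track-length filtering.

The stages follow the standard granule-tracking recipe: rolling-ball
background subtraction (default radius 3 px), Laplacian-of-Gaussian
detection at the scale of a ~0.5 µm granule with sub-pixel quadratic
refinement, greedy mutually-nearest-neighbor linking without gap
closing, and a track-length filter keeping tracks longer than 20 frames
(≥ 21 points at 10 frames/s, i.e. > 2 s).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import feature, filters, restoration

from .tracks import MovieStack, TrackSet

DEFAULT_DIAMETER_UM = 0.5
DEFAULT_ROLLING_BALL_RADIUS = 3
DEFAULT_MIN_FRAMES = 21

SPOT_COLUMNS = ["frame", "x_um", "y_um", "quality"]


def rolling_ball_subtract(frame: np.ndarray,
                          radius: int = DEFAULT_ROLLING_BALL_RADIUS) -> np.ndarray:
    """Subtract a rolling-ball background estimate from one frame.

    The background is the grayscale opening of the image by a ball of
    the given radius (the classic rolling-ball estimate); the result is
    clipped to be non-negative.
    """
    frame = np.asarray(frame, dtype=float)
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if radius >= min(frame.shape):
        raise ValueError(
            f"radius {radius} too large for image of shape {frame.shape}")
    background = restoration.rolling_ball(frame, radius=radius)
    return np.clip(frame - background, 0.0, None)


def _log_response(img: np.ndarray, sigma_px: float) -> np.ndarray:
    """Scale-normalized negative Laplacian of Gaussian (bright spots > 0)."""
    return -(sigma_px ** 2) * ndimage.gaussian_laplace(img, sigma_px)


def _subpixel_offset(patch3: np.ndarray) -> float:
    """1-D quadratic-fit peak offset from a 3-sample neighborhood."""
    denom = patch3[0] - 2.0 * patch3[1] + patch3[2]
    if denom >= 0:  # flat or non-concave; no refinement
        return 0.0
    off = 0.5 * (patch3[0] - patch3[2]) / denom
    return float(np.clip(off, -0.5, 0.5))


def detect_spots(movie: MovieStack, diameter: float = DEFAULT_DIAMETER_UM,
                 quality_threshold: float | None = None,
                 subtract_background: bool = True,
                 rolling_ball_radius: int = DEFAULT_ROLLING_BALL_RADIUS) -> pd.DataFrame:
    """Detect diffraction-limited spots in every frame.

    Laplacian-of-Gaussian detection at scale σ = diameter/(2√2) with
    local-maximum selection and sub-pixel refinement by a quadratic fit
    to the LoG response.  ``quality`` is the scale-normalized LoG
    response at the peak.  When ``quality_threshold`` is None an Otsu
    threshold on the pooled per-movie LoG-response distribution is used
    (background pixels vs spot responses; degenerate distributions keep
    all candidates).

    Returns a DataFrame with columns frame, x_um, y_um, quality.
    """
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    sigma_px = (diameter / (2.0 * math.sqrt(2.0))) / movie.pixel_size
    if sigma_px < 0.5:
        raise ValueError(
            f"diameter {diameter} µm is below one pixel at "
            f"pixel_size {movie.pixel_size} µm — undetectable scale")
    min_dist = max(1, int(round(sigma_px)))

    cand_frames: list[tuple[int, np.ndarray, np.ndarray]] = []
    for f in range(movie.n_frames):
        img = movie.frames[f].astype(float)
        if subtract_background:
            img = rolling_ball_subtract(img, rolling_ball_radius)
        resp = _log_response(img, sigma_px)
        peaks = feature.peak_local_max(resp, min_distance=min_dist,
                                       threshold_abs=1e-9, exclude_border=1)
        cand_frames.append((f, resp, peaks))

    if quality_threshold is None:
        # pool (a subsample of) the response distribution over the movie:
        # background responses sit near zero, spot responses far above
        pooled = np.concatenate([resp.ravel() for _, resp, _ in cand_frames])
        if pooled.size > 2_000_000:
            stride = pooled.size // 2_000_000 + 1
            pooled = pooled[::stride]
        if np.unique(pooled).size >= 2:
            quality_threshold = float(filters.threshold_otsu(pooled))
        else:
            quality_threshold = 0.0

    rows = []
    for f, resp, peaks in cand_frames:
        for py, px in peaks:
            q = resp[py, px]
            if q < quality_threshold:
                continue
            dx = _subpixel_offset(resp[py, px - 1:px + 2]) if 0 < px < resp.shape[1] - 1 else 0.0
            dy = _subpixel_offset(resp[py - 1:py + 2, px]) if 0 < py < resp.shape[0] - 1 else 0.0
            rows.append({"frame": f,
                         "x_um": (px + dx) * movie.pixel_size,
                         "y_um": (py + dy) * movie.pixel_size,
                         "quality": float(q)})
    spots = pd.DataFrame(rows, columns=SPOT_COLUMNS)
    return spots.sort_values(["frame", "y_um", "x_um"]).reset_index(drop=True)


def link_spots(spots: pd.DataFrame, max_displacement: float,
               frame_interval: float) -> TrackSet:
    """Link per-frame spots into tracks by mutual nearest neighbors.

    For each consecutive frame pair, spot i (frame t) and spot j
    (frame t+1) are joined iff each is the other's nearest neighbor and
    their distance is ≤ ``max_displacement`` (µm).  Unmatched spots
    start new tracks.  No gap closing: a spot missing for one frame
    splits its trajectory.  Ties are broken deterministically by lower
    spot index after sorting by (frame, y, x).
    """
    if max_displacement <= 0:
        raise ValueError("max_displacement must be positive")
    spots = spots.sort_values(["frame", "y_um", "x_um"], kind="stable").reset_index(drop=True)
    if spots.empty:
        return TrackSet(pd.DataFrame(columns=["track_id", "frame", "x_um", "y_um"]),
                        frame_interval)

    spots = spots.copy()
    spots["track_id"] = -1
    next_id = 0
    frames = sorted(spots["frame"].unique())
    idx_by_frame = {f: spots.index[spots["frame"] == f].to_numpy() for f in frames}

    # first frame: every spot opens a track
    for i in idx_by_frame[frames[0]]:
        spots.at[i, "track_id"] = next_id
        next_id += 1

    for fa, fb in zip(frames[:-1], frames[1:]):
        ia, ib = idx_by_frame[fa], idx_by_frame[fb]
        linked_b = set()
        if fb - fa == 1 and len(ia) and len(ib):
            pa = spots.loc[ia, ["x_um", "y_um"]].to_numpy()
            pb = spots.loc[ib, ["x_um", "y_um"]].to_numpy()
            d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
            nn_a = d.argmin(axis=1)  # ties -> lower index (argmin convention)
            nn_b = d.argmin(axis=0)
            for k, i in enumerate(ia):
                j = nn_a[k]
                if nn_b[j] == k and d[k, j] <= max_displacement:
                    spots.at[ib[j], "track_id"] = spots.at[i, "track_id"]
                    linked_b.add(ib[j])
        for j in ib:
            if j not in linked_b:
                spots.at[j, "track_id"] = next_id
                next_id += 1

    data = spots[["track_id", "frame", "x_um", "y_um"]].copy()
    return TrackSet(data, frame_interval)


def filter_tracks(tracks: TrackSet, min_frames: int = DEFAULT_MIN_FRAMES) -> TrackSet:
    """Keep tracks with at least ``min_frames`` points.

    The default (21) implements a strictly-greater-than-20-frames
    length threshold.  Idempotent.
    """
    if min_frames < 2:
        raise ValueError("min_frames must be >= 2")
    sizes = tracks.data.groupby("track_id").size()
    keep = sizes.index[sizes >= min_frames]
    return tracks.subset(keep)


def track_movie(movie: MovieStack, diameter: float = DEFAULT_DIAMETER_UM,
                quality_threshold: float | None = None,
                max_displacement: float = 0.5,
                min_frames: int = DEFAULT_MIN_FRAMES,
                subtract_background: bool = True) -> TrackSet:
    """Full detection → linking → filtering pipeline for one movie."""
    spots = detect_spots(movie, diameter, quality_threshold,
                         subtract_background=subtract_background)
    linked = link_spots(spots, max_displacement, movie.frame_interval)
    return filter_tracks(linked, min_frames)
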