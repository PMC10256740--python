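"""Kymographs, processive-run calling, and two-channel co-transport.

A kymograph resamples each movie frame along a line ROI (bilinear
interpolation, optional width-averaging perpendicular to the line) and
stacks the profiles as columns, so a particle moving along the line
appears as a sloped trace whose slope is its velocity.

A processive run is a maximal monotone excursion of ≥ 2 µm along the
track's principal displacement axis — the signature of motor-driven
transport.  Co-transport asks whether, during such runs in a reference
channel, some partner-channel track stays within a capture radius for
most of the run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .tracks import MovieStack, Track, TrackSet

DEFAULT_MIN_RUN_UM = 2.0
DEFAULT_MAX_GAP_UM = 0.5
DEFAULT_MIN_OVERLAP_FRACTION = 0.5


@dataclass
class LineROI:
    """Polyline ROI in µm with an averaging width in pixels."""

    vertices: np.ndarray  # (N, 2) (x, y) µm
    width: int = 1

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[0] < 2:
            raise ValueError("LineROI needs at least 2 vertices")
        if self.length <= 0:
            raise ValueError("LineROI must have positive length")
        if self.width < 1 or self.width % 2 == 0:
            raise ValueError("width must be a positive odd pixel count")

    @property
    def length(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.vertices, axis=0), axis=1)))


@dataclass
class Kymograph:
    """Position-along-line × frame intensity matrix."""

    values: np.ndarray       # (n_positions, n_frames)
    position_step: float     # µm between rows
    frame_interval: float    # s between columns

    @property
    def n_positions(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


def _sample_points(roi: LineROI, step: float) -> tuple[np.ndarray, np.ndarray]:
    """Arclength-uniform sample points along the polyline and the local
    unit normals (for width averaging)."""
    verts = roi.vertices
    seg = np.diff(verts, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    n_samples = int(np.ceil(total / step)) + 1
    s = np.linspace(0.0, total, n_samples)
    pts = np.empty((n_samples, 2))
    normals = np.empty((n_samples, 2))
    j = 0
    for i, si in enumerate(s):
        while j < len(seg_len) - 1 and si > cum[j + 1]:
            j += 1
        frac = 0.0 if seg_len[j] == 0 else (si - cum[j]) / seg_len[j]
        pts[i] = verts[j] + frac * seg[j]
        t = seg[j] / seg_len[j]
        normals[i] = (-t[1], t[0])
    return pts, normals


def make_kymograph(movie: MovieStack, roi: LineROI) -> Kymograph:
    """Resample a movie along a line ROI into a kymograph.

    Intensity is sampled at ``pixel_size`` steps along the polyline by
    bilinear interpolation and averaged across ``roi.width`` parallel
    offsets perpendicular to the local line direction.
    """
    step = movie.pixel_size
    pts, normals = _sample_points(roi, step)
    wx, wy = movie.field_um
    if (pts[:, 0].min() < 0 or pts[:, 1].min() < 0
            or pts[:, 0].max() > wx or pts[:, 1].max() > wy):
        raise ValueError("ROI extends outside the field of view")

    half = (roi.width - 1) // 2
    offsets = np.arange(-half, half + 1) * step
    kymo = np.zeros((len(pts), movie.n_frames))
    for off in offsets:
        sample = pts + off * normals
        # map_coordinates expects (row, col) = (y, x) in pixel units
        coords = np.stack([sample[:, 1] / movie.pixel_size,
                           sample[:, 0] / movie.pixel_size])
        for f in range(movie.n_frames):
            kymo[:, f] += ndimage.map_coordinates(
                movie.frames[f].astype(float), coords, order=1, mode="nearest")
    kymo /= len(offsets)
    return Kymograph(kymo, position_step=step, frame_interval=movie.frame_interval)


def run_from_kymo_line(p0: tuple[float, int], p1: tuple[float, int],
                       frame_interval: float) -> tuple[float, float]:
    """Distance and velocity of a trace drawn on a kymograph.

    ``p0``/``p1`` are (position µm, frame index) endpoints; returns
    (distance µm, velocity µm/s).
    """
    (s0, f0), (s1, f1) = p0, p1
    if f1 <= f0:
        raise ValueError("p1 must be at a later frame than p0")
    dist = abs(s1 - s0)
    return float(dist), float(dist / ((f1 - f0) * frame_interval))


@dataclass
class RunEvent:
    """One maximal monotone excursion along the principal axis."""

    track_id: int
    start_frame: int
    end_frame: int
    displacement_um: float
    direction: int  # ±1 along the principal axis

    def __post_init__(self) -> None:
        if self.end_frame <= self.start_frame:
            raise ValueError("end_frame must exceed start_frame")
        if self.displacement_um < 0:
            raise ValueError("displacement must be >= 0")


def _principal_axis(pos: np.ndarray) -> np.ndarray:
    centered = pos - pos.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return vt[0]


def call_processive_runs(track: Track,
                         min_run: float = DEFAULT_MIN_RUN_UM) -> list[RunEvent]:
    """Call maximal monotone excursions of ≥ ``min_run`` µm.

    Positions are projected on the track's first principal component
    (granule transport in a neurite is effectively 1-D along the
    process); consecutive steps of equal sign are merged into
    excursions, zero steps extend the current excursion, and excursions
    whose net displacement reaches ``min_run`` are reported.
    """
    if min_run <= 0:
        raise ValueError("min_run must be positive")
    pos = track.positions
    proj = pos @ _principal_axis(pos)
    steps = np.diff(proj)
    signs = np.sign(steps)

    runs: list[RunEvent] = []
    start = 0
    cur_sign = 0.0
    for i, s in enumerate(signs):
        if s == 0 or s == cur_sign:
            continue
        if cur_sign != 0:
            disp = abs(proj[i] - proj[start])
            if disp >= min_run:
                runs.append(RunEvent(track.track_id, int(track.frame[start]),
                                     int(track.frame[i]), float(disp),
                                     int(cur_sign)))
            start = i
        cur_sign = s
    if cur_sign != 0:
        disp = abs(proj[-1] - proj[start])
        if disp >= min_run:
            runs.append(RunEvent(track.track_id, int(track.frame[start]),
                                 int(track.frame[-1]), float(disp),
                                 int(cur_sign)))
    return runs


@dataclass
class CoTransportResult:
    """Fraction of reference tracks with processive runs that are
    accompanied by a partner-channel track."""

    fraction: float
    n_with_runs: int
    n_cotransported: int
    per_track: pd.DataFrame  # track_id, n_runs, cotransported


def cotransport_fraction(reference: TrackSet, partner: TrackSet,
                         max_gap: float = DEFAULT_MAX_GAP_UM,
                         min_overlap_fraction: float = DEFAULT_MIN_OVERLAP_FRACTION,
                         min_run: float = DEFAULT_MIN_RUN_UM) -> CoTransportResult:
    """Two-channel co-transport fraction.

    A reference track with ≥ 1 processive run counts as co-transported
    if, for some run, a single partner track lies within ``max_gap`` µm
    of the reference position for at least ``min_overlap_fraction`` of
    the run's frames.  The fraction is over reference tracks that have
    runs; both channels must share a time base.
    """
    if reference.n_tracks == 0:
        raise ValueError("reference track set is empty")
    if abs(reference.frame_interval - partner.frame_interval) > 1e-12:
        raise ValueError("channels do not share a time base")

    partner_tracks = list(partner)
    rows = []
    n_with_runs = 0
    n_cot = 0
    for tr in reference:
        runs = call_processive_runs(tr, min_run)
        if not runs:
            rows.append({"track_id": tr.track_id, "n_runs": 0,
                         "cotransported": False})
            continue
        n_with_runs += 1
        cot = False
        for run in runs:
            in_run = (tr.frame >= run.start_frame) & (tr.frame <= run.end_frame)
            rf, rp = tr.frame[in_run], tr.positions[in_run]
            for ptr in partner_tracks:
                common, ia, ib = np.intersect1d(rf, ptr.frame,
                                                return_indices=True)
                if common.size == 0:
                    continue
                gap = np.linalg.norm(rp[ia] - ptr.positions[ib], axis=1)
                frac = float(np.sum(gap <= max_gap)) / len(rf)
                if frac >= min_overlap_fraction:
                    cot = True
                    break
            if cot:
                break
        n_cot += cot
        rows.append({"track_id": tr.track_id, "n_runs": len(runs),
                     "cotransported": bool(cot)})

    frac = n_cot / n_with_runs if n_with_runs else 0.0
    return CoTransportResult(float(frac), n_with_runs, n_cot,
                             pd.DataFrame(rows))
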