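"""Readers and writers for movies, masks, tables and geometries.

Movies travel as multi-page TIFF with physical calibration embedded in
ImageJ-style metadata and duplicated in a JSON sidecar
(``<path>.json``); on conflict the sidecar wins.  Tables are CSV/TSV
with unit-suffixed column names (x_um, ct, tags_per_kb ...); unknown
extra columns are preserved with a warning.  Round-trips are lossless
for all table types.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .geometry import NeuriteGeometry
from .tracks import TRACK_COLUMNS, MovieStack, TrackSet

SPOT_COLUMNS = ["frame", "x_um", "y_um", "quality"]


class MissingMetadataError(ValueError):
    """A movie file carries no physical calibration."""


class SchemaError(ValueError):
    """A table is missing required columns."""


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_movie(movie: MovieStack, path: str | Path) -> Path:
    """Write a movie as multi-page TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(
        path, movie.frames.astype(np.float32),
        imagej=True,
        resolution=(1.0 / movie.pixel_size, 1.0 / movie.pixel_size),
        metadata={"unit": "um", "finterval": movie.frame_interval,
                  "axes": "TYX"},
    )
    meta = {"pixel_size_um": movie.pixel_size,
            "frame_interval_s": movie.frame_interval,
            "channel": movie.channel}
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_movie(path: str | Path) -> MovieStack:
    """Read a multi-page TIFF movie with its calibration.

    Pixel size and frame interval are taken from the JSON sidecar if
    present, else from ImageJ TIFF metadata; a movie without either
    raises :class:`MissingMetadataError` naming the missing fields.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tf:
            frames = tf.asarray()
            ij = tf.imagej_metadata or {}
            page = tf.pages[0]
            res = page.tags.get("XResolution")
    except tifffile.TiffFileError as err:
        raise ValueError(f"malformed TIFF file {path}: {err}") from err
    if frames.ndim == 2:
        frames = frames[None]

    pixel_size = None
    frame_interval = ij.get("finterval")
    if res is not None and res.value[0]:
        num, den = res.value
        if num:
            pixel_size = den / num
    channel = ""

    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        pixel_size = meta.get("pixel_size_um", pixel_size)
        frame_interval = meta.get("frame_interval_s", frame_interval)
        channel = meta.get("channel", "")

    missing = [name for name, val in
               [("pixel_size_um", pixel_size), ("frame_interval_s", frame_interval)]
               if val is None]
    if missing:
        raise MissingMetadataError(
            f"{path} lacks calibration field(s) {missing}: embed ImageJ "
            "metadata or provide a JSON sidecar")
    return MovieStack(np.asarray(frames, dtype=float), float(pixel_size),
                      float(frame_interval), channel)


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(mask).astype(np.uint8))
    return path


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary/label mask from TIFF or PNG."""
    path = Path(path)
    if path.suffix.lower() == ".png":
        from imageio import v3 as iio
        arr = iio.imread(path)
        if arr.ndim == 3:
            arr = arr[..., 0]
    else:
        arr = tifffile.imread(path)
    return np.asarray(arr)


def _check_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table is missing column(s) {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        warnings.warn(f"{what} table has extra column(s) {extra}; preserved",
                      stacklevel=3)


def write_tracks(tracks: TrackSet, path: str | Path) -> Path:
    path = Path(path)
    df = tracks.data.copy()
    df.attrs = {}
    df.to_csv(path, index=False)
    meta = {"frame_interval_s": tracks.frame_interval}
    _sidecar_path(path).write_text(json.dumps(meta))
    if tracks.meta is not None:
        tracks.meta.to_csv(path.with_suffix(".truth.csv"), index=False)
    return path


def read_tracks(path: str | Path,
                frame_interval: float | None = None) -> TrackSet:
    path = Path(path)
    df = pd.read_csv(path)
    _check_columns(df, TRACK_COLUMNS + (["cell_id"] if "cell_id" in df.columns else []),
                   "tracks")
    if frame_interval is None:
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise MissingMetadataError(
                f"{path} has no frame_interval: pass one or provide the sidecar")
        frame_interval = json.loads(sidecar.read_text())["frame_interval_s"]
    return TrackSet(df, float(frame_interval))


def write_spots(spots: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    spots.to_csv(path, index=False)
    return path


def read_spots(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, [c for c in SPOT_COLUMNS if c in df.columns] or SPOT_COLUMNS,
                   "spots")
    return df


def write_counts(counts: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    counts.to_csv(path, sep="\t")
    return path


def read_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 1:
        raise SchemaError(f"count table {path} has no sample columns")
    return df


def write_table(df: pd.DataFrame, path: str | Path, sep: str = "\t") -> Path:
    path = Path(path)
    df.to_csv(path, sep=sep, index=False)
    return path


def read_sample_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _check_columns(df, ["sample", "compartment", "condition"], "sample metadata")
    return df


def read_annotation(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _check_columns(df, ["gene", "tags_per_kb"], "gene annotation")
    return df


def read_qpcr(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, ["gene", "fraction", "replicate", "ct"], "qPCR")
    return df


def write_geometry(geom: NeuriteGeometry, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(geom.to_dict(), indent=1))
    return path


def read_geometry(path: str | Path) -> NeuriteGeometry:
    return NeuriteGeometry.from_dict(json.loads(Path(path).read_text()))
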