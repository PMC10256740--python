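"""Neurite geometry: soma centroid plus neurite polylines.

Each neurite is a polyline in µm whose first vertex is the soma end;
arclength therefore increases from soma (0) to tip (total length).
Spot positions are normalized as a fraction of the length of the
neurite they are assigned to, so fractions are bounded by 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import LineString, Point


@dataclass
class NeuriteGeometry:
    soma_centroid: tuple[float, float]
    neurites: list[np.ndarray]  # each (N, 2) vertex array, µm, soma end first

    def __post_init__(self) -> None:
        if not self.neurites:
            raise ValueError("geometry needs at least one neurite")
        cleaned = []
        for i, poly in enumerate(self.neurites):
            arr = np.asarray(poly, dtype=float)
            if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] != 2:
                raise ValueError(f"neurite {i} must be an (N>=2, 2) vertex array")
            if LineString(arr).length <= 0:
                raise ValueError(f"neurite {i} has zero length")
            cleaned.append(arr)
        self.neurites = cleaned
        self._lines = [LineString(a) for a in self.neurites]

    @property
    def n_neurites(self) -> int:
        return len(self.neurites)

    @property
    def lengths(self) -> np.ndarray:
        """Total arclength of each neurite, µm."""
        return np.array([ln.length for ln in self._lines])

    def point_at_fraction(self, neurite: int, fraction: float) -> tuple[float, float]:
        """Position at a given arclength fraction along one neurite."""
        if not 0.0 <= fraction <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")
        p = self._lines[neurite].interpolate(fraction, normalized=True)
        return (p.x, p.y)

    def project(self, x: float, y: float) -> tuple[int, float, float]:
        """Project a point onto the nearest neurite.

        Returns
        -------
        (neurite_index, fraction, distance)
            Index of the nearest polyline, arclength fraction in [0, 1]
            of the projection (soma end = 0), and the Euclidean distance
            from the point to the polyline in µm.
        """
        pt = Point(x, y)
        dists = [ln.distance(pt) for ln in self._lines]
        idx = int(np.argmin(dists))
        line = self._lines[idx]
        frac = line.project(pt) / line.length
        return idx, float(np.clip(frac, 0.0, 1.0)), float(dists[idx])

    def to_dict(self) -> dict:
        return {
            "soma_centroid": list(self.soma_centroid),
            "neurites": [a.tolist() for a in self.neurites],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NeuriteGeometry":
        return cls(
            soma_centroid=tuple(d["soma_centroid"]),
            neurites=[np.asarray(a, dtype=float) for a in d["neurites"]],
        )
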