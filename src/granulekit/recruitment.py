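"""Centrosome-recruitment scoring and masked colocalization.

The recruitment assay tethers a kinesin tail to the dynein adapter
BicD2 so that cargo binding the tail accumulates at the centrosome;
association strength is read out as

    E = log2( mean intensity inside the centrosome mask
              / mean intensity over the whole-cell mask )

where the whole-cell mask includes the centrosome pixels.  E = 0 means
no enrichment; E is invariant to multiplicative intensity scaling
(exposure/gain) but not to additive offsets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import mann_whitney


@dataclass
class CellImage:
    """One cell's intensity image with its cell and centrosome masks."""

    image: np.ndarray
    cell_mask: np.ndarray
    centrosome_mask: np.ndarray
    pixel_size: float = 1.0
    cell_id: int | str | None = None

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        self.cell_mask = np.asarray(self.cell_mask, dtype=bool)
        self.centrosome_mask = np.asarray(self.centrosome_mask, dtype=bool)
        if self.image.shape != self.cell_mask.shape != self.centrosome_mask.shape:
            raise ValueError("image and masks must share a shape")
        if not self.cell_mask.any() or not self.centrosome_mask.any():
            raise ValueError("masks must be non-empty")
        if np.any(self.centrosome_mask & ~self.cell_mask):
            raise ValueError("centrosome mask must lie inside the cell mask")


def centrosome_enrichment(image: np.ndarray, cell_mask: np.ndarray,
                          centrosome_mask: np.ndarray) -> float:
    """log2 centrosome-to-whole-cell mean intensity ratio."""
    ci = CellImage(image, cell_mask, centrosome_mask)  # validates masks
    cell_mean = float(ci.image[ci.cell_mask].mean())
    centro_mean = float(ci.image[ci.centrosome_mask].mean())
    if cell_mean <= 0:
        raise ValueError("whole-cell mean intensity must be positive")
    if centro_mean <= 0:
        raise ValueError("centrosome mean intensity must be positive")
    return float(np.log2(centro_mean / cell_mean))


def enrichment_experiment(scores: dict[str, np.ndarray]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summarize per-cell enrichment scores by group.

    Returns a summary table (median, quartiles, 10th/90th percentiles,
    n — the box/whisker conventions of recruitment figures, with 0 as
    the no-enrichment reference) and a table of pairwise two-tailed
    Mann–Whitney p-values.
    """
    if len(scores) < 2:
        raise ValueError("need at least two groups")
    rows = []
    for grp, vals in scores.items():
        vals = np.asarray(vals, dtype=float)
        if vals.size == 0:
            raise ValueError(f"group {grp!r} is empty")
        q10, q25, q50, q75, q90 = np.percentile(vals, [10, 25, 50, 75, 90])
        rows.append({"group": grp, "n": vals.size, "median": q50,
                     "q25": q25, "q75": q75, "p10": q10, "p90": q90})
    summary = pd.DataFrame(rows)

    groups = list(scores)
    prow = []
    for i, ga in enumerate(groups):
        for gb in groups[i + 1:]:
            res = mann_whitney(scores[ga], scores[gb])
            prow.append({"group_a": ga, "group_b": gb, "U": res.U,
                         "p": res.p, "method": res.method})
    return summary, pd.DataFrame(prow)


def pearson_in_mask(ch1: np.ndarray, ch2: np.ndarray,
                    mask: np.ndarray) -> float:
    """Pearson correlation of two channels over masked pixels only.

    Works for 2-D or 3-D arrays; requires ≥ 2 masked pixels and
    non-zero variance in both channels within the mask.
    """
    mask = np.asarray(mask, dtype=bool)
    a = np.asarray(ch1, dtype=float)[mask]
    b = np.asarray(ch2, dtype=float)[mask]
    if a.size < 2:
        raise ValueError("need at least 2 pixels in the mask")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance within mask; correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


def manders_in_mask(ch1: np.ndarray, ch2: np.ndarray, mask: np.ndarray,
                    t1: float = 0.0, t2: float = 0.0) -> tuple[float, float]:
    """Manders overlap coefficients (M1, M2) within a mask.

    M1 = fraction of channel-1 intensity lying over pixels where
    channel 2 exceeds t2; M2 symmetric.  Thresholds default to 0
    (a pixel counts when the other channel is strictly positive).
    """
    if t1 < 0 or t2 < 0:
        raise ValueError("thresholds must be >= 0")
    mask = np.asarray(mask, dtype=bool)
    a = np.asarray(ch1, dtype=float)[mask]
    b = np.asarray(ch2, dtype=float)[mask]
    sum_a, sum_b = a.sum(), b.sum()
    if sum_a == 0 or sum_b == 0:
        raise ValueError("zero total intensity in a channel within mask")
    m1 = float(a[b > t2].sum() / sum_a)
    m2 = float(b[a > t1].sum() / sum_b)
    return m1, m2
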