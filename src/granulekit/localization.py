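"""Subcellular mRNA localization statistics.

Covers the compartment-fractionation analysis (cyclic-loess
normalization, per-gene log2(neurite/soma) localization ratios and
their shifts between conditions, CLIP-density binning with rank-sum
tests, mis-localized gene sets and overlap enrichment), FISH
spot-distance statistics along neurites (per-cell 95th percentiles of
length-normalized distances), a centrosomal RNA fraction, ΔΔCt qPCR
membrane enrichment, and isoform fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .geometry import NeuriteGeometry
from .stats import OverlapResult, overlap_enrichment  # re-exported  # noqa: F401

DEFAULT_EXPRESSION_THRESHOLD = 1.0   # mean normalized log2 expression
DEFAULT_DELTA_THRESHOLD = 0.25       # |ΔL| cut for mis-localized sets
DEFAULT_MIN_SPOTS = 150
DEFAULT_LOESS_SPAN = 0.7
DEFAULT_LOESS_CYCLES = 3
PSEUDOCOUNT = 0.5


def normalize_cyclic_loess(counts: pd.DataFrame,
                           span: float = DEFAULT_LOESS_SPAN,
                           n_cycles: int = DEFAULT_LOESS_CYCLES) -> pd.DataFrame:
    """Cyclic-loess normalization of a count table (genes × samples).

    Counts are transformed to log2(count + 0.5); then, cycling over all
    sample pairs for ``n_cycles`` iterations, a loess curve of M (the
    per-gene difference) on A (the per-gene average) is fitted and half
    the fitted M subtracted from one sample and added to the other, so
    each pairwise MA trend is flattened while per-gene averages are
    preserved.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least two samples to normalize")
    y = np.log2(counts.to_numpy(dtype=float) + PSEUDOCOUNT)
    n = y.shape[1]
    for _ in range(n_cycles):
        for i in range(n - 1):
            for j in range(i + 1, n):
                m = y[:, i] - y[:, j]
                a = 0.5 * (y[:, i] + y[:, j])
                fit = lowess(m, a, frac=span, return_sorted=False)
                y[:, i] -= fit / 2.0
                y[:, j] += fit / 2.0
    return pd.DataFrame(y, index=counts.index, columns=counts.columns)


@dataclass
class LocalizationTable:
    """Per-gene localization ratios and shifts between conditions."""

    table: pd.DataFrame      # gene index; L_<cond> columns; dL_<cond> columns; passes_filter
    control: str
    expression_threshold: float

    @property
    def passing(self) -> pd.DataFrame:
        return self.table[self.table["passes_filter"]]


def localization_ratio(normed: pd.DataFrame, samples: pd.DataFrame,
                       control: str | None = None,
                       expression_threshold: float = DEFAULT_EXPRESSION_THRESHOLD,
                       ) -> LocalizationTable:
    """Per-gene log2(neurite/soma) per condition, and shifts vs control.

    ``normed`` is the cyclic-loess-normalized log2 expression matrix;
    ``samples`` maps each column to a compartment (soma/neurite) and
    condition.  L_c = mean neurite − mean soma log2 expression.  The
    expression filter keeps genes whose mean normalized log2 expression
    exceeds the threshold in both compartments of every condition.
    ΔL_c = L_c − L_control for each non-control condition.
    """
    required = {"sample", "compartment", "condition"}
    if not required.issubset(samples.columns):
        raise ValueError(f"sample table needs columns {sorted(required)}")
    conditions = list(dict.fromkeys(samples["condition"]))
    if control is None:
        control = conditions[0]
    if control not in conditions:
        raise ValueError(f"control condition {control!r} not in sample table")

    out = pd.DataFrame(index=normed.index)
    passes = pd.Series(True, index=normed.index)
    for cond in conditions:
        sub = samples[samples["condition"] == cond]
        for comp in ("soma", "neurite"):
            cols = sub.loc[sub["compartment"] == comp, "sample"].tolist()
            if not cols:
                raise ValueError(f"condition {cond!r} has no {comp} sample")
        soma = normed[sub.loc[sub["compartment"] == "soma", "sample"]].mean(axis=1)
        neur = normed[sub.loc[sub["compartment"] == "neurite", "sample"]].mean(axis=1)
        out[f"L_{cond}"] = neur - soma
        passes &= (soma > expression_threshold) & (neur > expression_threshold)

    for cond in conditions:
        if cond != control:
            out[f"dL_{cond}"] = out[f"L_{cond}"] - out[f"L_{control}"]
    out["passes_filter"] = passes
    return LocalizationTable(out, control, expression_threshold)


def clip_density_shift(loc: LocalizationTable, annotation: pd.DataFrame,
                       condition: str | None = None,
                       bin_edges: np.ndarray | None = None,
                       n_boot: int = 200,
                       seed: int | None = None) -> pd.DataFrame:
    """Median localization shift as a function of CLIP tag density.

    Genes passing the expression filter are binned by ``tags_per_kb``
    (bin 0 = zero density; default upper bins split positive densities
    at their median and upper quartile).  Per bin: the median ΔL, a
    bootstrap SEM of the median, and a two-tailed Wilcoxon rank-sum
    p-value against the zero-density reference bin.
    """
    if not {"gene", "tags_per_kb"}.issubset(annotation.columns):
        raise ValueError("annotation needs columns gene, tags_per_kb")
    table = loc.passing
    dl_cols = [c for c in table.columns if c.startswith("dL_")]
    if not dl_cols:
        raise ValueError("localization table has no shift (dL) columns")
    col = f"dL_{condition}" if condition is not None else dl_cols[0]
    if col not in table.columns:
        raise ValueError(f"no shift column for condition {condition!r}")

    merged = table[[col]].join(
        annotation.set_index("gene")["tags_per_kb"], how="inner").dropna()
    dens = merged["tags_per_kb"].to_numpy()
    dl = merged[col].to_numpy()

    if bin_edges is None:
        pos = dens[dens > 0]
        if pos.size == 0:
            raise ValueError("no genes with positive tag density")
        q50, q75 = np.quantile(pos, [0.5, 0.75])
        bin_edges = np.array([0.0, q50, q75, np.inf])
    labels = ["0"] + [
        f"({bin_edges[i]:.3g}, {bin_edges[i+1]:.3g}]"
        for i in range(len(bin_edges) - 1)
    ]
    which = np.zeros(len(dens), dtype=int)
    posmask = dens > 0
    which[posmask] = 1 + np.searchsorted(bin_edges[1:-1], dens[posmask],
                                         side="left")

    ref = dl[which == 0]
    if ref.size == 0:
        raise ValueError("no zero-density reference bin")
    rng = np.random.default_rng(seed)
    rows = []
    for b, lab in enumerate(labels):
        vals = dl[which == b]
        if vals.size == 0:
            rows.append({"bin": lab, "n": 0, "median_dL": np.nan,
                         "sem": np.nan, "p_vs_zero": np.nan})
            continue
        boot = np.median(
            rng.choice(vals, size=(n_boot, vals.size), replace=True), axis=1)
        if b == 0:
            p = 1.0
        else:
            p = float(stats.ranksums(vals, ref).pvalue)
        rows.append({"bin": lab, "n": int(vals.size),
                     "median_dL": float(np.median(vals)),
                     "sem": float(boot.std(ddof=1)), "p_vs_zero": p})
    return pd.DataFrame(rows)


def mislocalized_set(loc: LocalizationTable, condition: str | None = None,
                     delta_threshold: float = DEFAULT_DELTA_THRESHOLD) -> set[str]:
    """Genes shifted toward the soma: ΔL ≤ −delta_threshold among
    expression-passing genes."""
    table = loc.passing
    dl_cols = [c for c in table.columns if c.startswith("dL_")]
    col = f"dL_{condition}" if condition is not None else dl_cols[0]
    if col not in table.columns:
        raise ValueError(f"no shift column for condition {condition!r}")
    return set(table.index[table[col] <= -delta_threshold])


def spot_neurite_distance(spots: pd.DataFrame, geometry: NeuriteGeometry,
                          max_assign_um: float = 2.0) -> pd.DataFrame:
    """Normalized arclength of each spot along its nearest neurite.

    Each spot is projected onto the nearest polyline; its distance is
    the arclength from the soma end to the projection divided by that
    neurite's total length, so values lie in [0, 1].  Spots farther
    than ``max_assign_um`` from every neurite are flagged unassigned
    (NaN fraction) and excluded from downstream statistics.
    """
    rows = []
    for _, sp in spots.iterrows():
        idx, frac, dist = geometry.project(sp["x_um"], sp["y_um"])
        ok = dist <= max_assign_um
        rows.append({
            "cell_id": sp.get("cell_id", 0),
            "x_um": sp["x_um"], "y_um": sp["y_um"],
            "neurite": idx if ok else -1,
            "fraction": frac if ok else np.nan,
            "offset_um": dist,
            "assigned": ok,
        })
    return pd.DataFrame(rows)


def cell_p95(distances: pd.DataFrame,
             min_spots: int = DEFAULT_MIN_SPOTS) -> pd.DataFrame:
    """Per-cell 95th percentile of normalized spot distances.

    Cells with fewer than ``min_spots`` assigned spots are excluded.
    The percentile uses linear interpolation.  Group comparisons on the
    per-cell values use the two-tailed Mann–Whitney test
    (:func:`granulekit.dynamics.compare_groups`).
    """
    if "fraction" not in distances.columns:
        raise ValueError("expected a 'fraction' column (see spot_neurite_distance)")
    ok = distances.dropna(subset=["fraction"])
    rows = []
    for cell, sub in ok.groupby("cell_id"):
        if len(sub) < min_spots:
            continue
        rows.append({"cell_id": cell, "n_spots": len(sub),
                     "p95": float(np.percentile(sub["fraction"], 95))})
    if not rows:
        raise ValueError(
            f"no cell passes the min_spots filter ({min_spots})")
    return pd.DataFrame(rows)


def centrosomal_rna_fraction(spots: pd.DataFrame, centrosome_mask: np.ndarray,
                             cell_mask: np.ndarray,
                             pixel_size: float = 1.0) -> float:
    """Fraction of FISH spots inside the centrosome mask relative to
    all spots inside the cell mask.

    Spot coordinates (µm) are mapped to the nearest pixel.
    """
    cell = np.asarray(cell_mask, dtype=bool)
    centro = np.asarray(centrosome_mask, dtype=bool)
    if np.any(centro & ~cell):
        raise ValueError("centrosome mask must lie inside the cell mask")
    px = np.round(spots["x_um"].to_numpy() / pixel_size).astype(int)
    py = np.round(spots["y_um"].to_numpy() / pixel_size).astype(int)
    inside = (px >= 0) & (px < cell.shape[1]) & (py >= 0) & (py < cell.shape[0])
    px, py = px[inside], py[inside]
    in_cell = cell[py, px]
    n_cell = int(in_cell.sum())
    if n_cell == 0:
        raise ValueError("no spots inside the cell mask")
    n_centro = int(centro[py[in_cell], px[in_cell]].sum())
    return n_centro / n_cell


def qpcr_membrane_enrichment(table: pd.DataFrame) -> tuple[float, float]:
    """Relative membrane association of a target RNA by ΔΔCt.

    For each replicate,
    fold = 2^−[(Ct_target,mem − Ct_ref,mem) − (Ct_target,cyto − Ct_ref,cyto)];
    the reported fold is the geometric mean over replicates
    (equivalently 2^−mean ΔΔCt).  Returns (fold, percent difference
    from 1): fold 1.6 ↔ 60 % greater membrane association.
    """
    required = {"gene", "fraction", "replicate", "ct"}
    if not required.issubset(table.columns):
        raise ValueError(f"qPCR table needs columns {sorted(required)}")
    ddcts = []
    for rep, sub in table.groupby("replicate"):
        piv = sub.pivot_table(index="gene", columns="fraction", values="ct")
        cells = [("target", "membrane"), ("reference", "membrane"),
                 ("target", "cytosol"), ("reference", "cytosol")]
        missing = [c for c in cells
                   if c[0] not in piv.index or c[1] not in piv.columns
                   or pd.isna(piv.loc[c[0], c[1]])]
        if missing:
            raise ValueError(
                f"replicate {rep} is missing gene×fraction combination(s) {missing}")
        d_mem = piv.loc["target", "membrane"] - piv.loc["reference", "membrane"]
        d_cyt = piv.loc["target", "cytosol"] - piv.loc["reference", "cytosol"]
        ddcts.append(d_mem - d_cyt)
    fold = float(2.0 ** (-np.mean(ddcts)))
    return fold, (fold - 1.0) * 100.0


def isoform_fraction(tpm_alpha: float, tpm_beta: float) -> float:
    """Fraction of the α isoform among total (α + β) expression."""
    total = tpm_alpha + tpm_beta
    if total <= 0:
        raise ValueError("total expression must be positive")
    return tpm_alpha / total
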