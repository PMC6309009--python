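"""Structural predictor matrices for affiliation modelling.

Association between two animals can be driven by structural opportunity -
being sociable, being in the same place, being around at the same time -
rather than by any social preference.  This module builds the dyadic
predictor matrices that capture those confounds so the affiliation model can
regress them out:

* ``gregariousness``  - log product of the two members' summed association
  indices (each excluding the focal dyad itself);
* ``spatial_overlap`` - proportion of jointly-sampled months in which the
  pair shared at least one subarea (transition zone excluded);
* ``temporal_overlap`` - months both identified / months either identified
  (bounded Jaccard orientation);
* ``homerange_udoi``  - utilization-distribution overlap index of the two
  kernel home ranges;
* ``area_match`` / ``sex_match`` / ``period_match`` - binary same-class
  indicators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import TRANSITION, annotate_time
from .matrices import DyadMatrix

__all__ = [
    "gregariousness_predictor",
    "spatial_overlap",
    "temporal_overlap",
    "Grid",
    "UtilizationDistribution",
    "make_grid",
    "href_bandwidth",
    "kernel_ud",
    "udoi",
    "class_match",
    "build_predictor_set",
]


# ---------------------------------------------------------------------------
# association-derived and calendar predictors
# ---------------------------------------------------------------------------

def gregariousness_predictor(hwi_matrix: DyadMatrix) -> DyadMatrix:
    """G_ab = log[ (sum_{i!=b} HWI_ai) * (sum_{j!=a} HWI_bj) ].

    Dyads whose factor is non-positive (an individual with zero associations
    outside the dyad) are undefined and masked.
    """
    v = np.where(np.isnan(hwi_matrix.values), 0.0, hwi_matrix.values)
    row = v.sum(axis=1)
    fa = row[:, None] - v
    fb = row[None, :] - v
    prod = fa * fb
    bad = prod <= 0
    if bad[~np.eye(len(row), dtype=bool)].any():
        warnings.warn("dyads with zero off-dyad association sums masked",
                      stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(bad, np.nan, np.log(np.where(bad, 1.0, prod)))
    return DyadMatrix(hwi_matrix.ids, out, kind="PREDICTOR")


def _month_presence(records: pd.DataFrame, ids: list[str]) -> np.ndarray:
    recs = records if "month_index" in records.columns else annotate_time(records)
    months = np.arange(1, int(recs["month_index"].max()) + 1)
    pres = np.zeros((len(ids), len(months)), dtype=bool)
    idx = {ind: k for k, ind in enumerate(ids)}
    for ind, m in recs[["individual_id", "month_index"]].itertuples(index=False):
        k = idx.get(str(ind))
        if k is not None:
            pres[k, int(m) - 1] = True
    return pres


def _month_area_bits(records: pd.DataFrame, ids: list[str]) -> np.ndarray:
    """Bitmask of (non-transition) areas used per individual per month."""
    recs = records if "month_index" in records.columns else annotate_time(records)
    recs = recs[recs["subarea"] != TRANSITION]
    months = int(records["month_index"].max()) if "month_index" in records.columns else int(annotate_time(records)["month_index"].max())
    bits = np.zeros((len(ids), months), dtype=np.int64)
    idx = {ind: k for k, ind in enumerate(ids)}
    area_bit = {a: 1 << i for i, a in enumerate(sorted(recs["subarea"].unique()))}
    for ind, m, a in recs[["individual_id", "month_index", "subarea"]].itertuples(index=False):
        k = idx.get(str(ind))
        if k is not None:
            bits[k, int(m) - 1] |= area_bit[a]
    return bits


def spatial_overlap(records: pd.DataFrame, ids: list[str] | None = None) -> DyadMatrix:
    """Proportion of jointly-identified months sharing at least one area.

    Months are jointly identified when both members have any sighting that
    month; the shared-area test ignores transition-zone sightings.  Dyads
    with no common month are 0 by convention (never co-temporal).
    """
    if ids is None:
        ids = sorted(records["individual_id"].astype(str).unique())
    pres = _month_presence(records, ids)
    bits = _month_area_bits(records, ids)
    n = len(ids)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            common = pres[i] & pres[j]
            denom = int(common.sum())
            if denom == 0:
                out[i, j] = out[j, i] = 0.0
                continue
            share = (bits[i, common] & bits[j, common]) != 0
            out[i, j] = out[j, i] = share.sum() / denom
    return DyadMatrix(ids, out, kind="PREDICTOR")


def temporal_overlap(records: pd.DataFrame, ids: list[str] | None = None) -> DyadMatrix:
    """Months both identified over months either identified (in [0, 1])."""
    if ids is None:
        ids = sorted(records["individual_id"].astype(str).unique())
    pres = _month_presence(records, ids).astype(np.int64)
    both = pres @ pres.T
    tot = pres.sum(axis=1)
    either = tot[:, None] + tot[None, :] - both
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(either > 0, both / np.where(either > 0, either, 1), np.nan)
    return DyadMatrix(ids, out, kind="PREDICTOR")


# ---------------------------------------------------------------------------
# kernel home ranges and UDOI
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Grid:
    """Regular planar lattice of square cells (all lengths in metres)."""

    x0: float
    y0: float
    cell: float
    nx: int
    ny: int

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        cx = self.x0 + (np.arange(self.nx) + 0.5) * self.cell
        cy = self.y0 + (np.arange(self.ny) + 0.5) * self.cell
        return cx, cy

    @property
    def cell_area(self) -> float:
        return self.cell * self.cell


@dataclass
class UtilizationDistribution:
    """Kernel utilisation distribution: probability mass per grid cell."""

    individual_id: str
    grid: Grid
    mass: np.ndarray  # (ny, nx), sums to 1

    def isopleth(self, level: float) -> np.ndarray:
        """Smallest density contour holding ``level`` of the mass.

        Cells are ranked by density and accumulated until the level is
        reached; cells tied with the cutoff density are included (the contour
        is a density level set), so a uniform distribution's isopleth is its
        whole support.
        """
        flat = self.mass.ravel()
        order = np.argsort(flat)[::-1]
        cum = np.cumsum(flat[order])
        k = int(np.searchsorted(cum, level))
        cutoff = flat[order[min(k, flat.size - 1)]]
        return self.mass >= cutoff

    def to_ascii_grid(self) -> str:
        """ESRI ASCII raster of the mass surface (for GIS inspection)."""
        g = self.grid
        lines = [
            f"ncols {g.nx}",
            f"nrows {g.ny}",
            f"xllcorner {g.x0}",
            f"yllcorner {g.y0}",
            f"cellsize {g.cell}",
            "NODATA_value -9999",
        ]
        for row in self.mass[::-1]:
            lines.append(" ".join(f"{v:.6g}" for v in row))
        return "\n".join(lines) + "\n"


def make_grid(points: np.ndarray, cell: float = 100.0, pad: float = 3000.0) -> Grid:
    """Grid covering the points with a margin (shared across individuals)."""
    x, y = points[:, 0], points[:, 1]
    x0, y0 = x.min() - pad, y.min() - pad
    nx = int(np.ceil((x.max() + pad - x0) / cell))
    ny = int(np.ceil((y.max() + pad - y0) / cell))
    return Grid(float(x0), float(y0), float(cell), nx, ny)


def href_bandwidth(points: np.ndarray) -> float:
    """Reference bandwidth: sqrt((var_x + var_y)/2) * n^(-1/6)."""
    n = len(points)
    var = points.var(axis=0, ddof=1)
    return float(np.sqrt(var.mean()) * n ** (-1.0 / 6.0))


def kernel_ud(
    points: np.ndarray,
    grid: Grid,
    bandwidth: float | None = None,
    individual_id: str = "",
    min_points: int = 5,
) -> UtilizationDistribution | None:
    """Bivariate-normal kernel density of the sighting locations on the grid.

    Returns None (masked) when fewer than ``min_points`` locations exist.
    Bandwidth defaults to the per-individual reference rule.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < min_points:
        return None
    if bandwidth is None:
        bandwidth = href_bandwidth(points)
        if bandwidth <= 0:
            bandwidth = grid.cell
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    cx, cy = grid.centers()
    dx = (cx[None, :] - points[:, 0:1]) / bandwidth  # (npts, nx)
    dy = (cy[None, :] - points[:, 1:2]) / bandwidth  # (npts, ny)
    gx = np.exp(-0.5 * dx**2)
    gy = np.exp(-0.5 * dy**2)
    dens = gy.T @ gx  # (ny, nx): sum over points of product kernels
    total = dens.sum()
    if total <= 0:
        return None
    return UtilizationDistribution(individual_id, grid, dens / total)


def udoi(
    ud_a: UtilizationDistribution,
    ud_b: UtilizationDistribution,
    homerange_level: float = 0.90,
) -> float:
    """Utilization-distribution overlap index of two home ranges.

    ``UDOI = A_overlap * integral(UD_a * UD_b)`` where ``A_overlap`` is the
    intersection area of the two home ranges (default the 90% isopleths).
    Two identical uniform distributions give 1; disjoint ranges give 0;
    values above 1 indicate higher-than-uniform shared use.
    """
    if ud_a.grid != ud_b.grid:
        raise ValueError("UDOI requires a common grid")
    overlap_cells = int((ud_a.isopleth(homerange_level) & ud_b.isopleth(homerange_level)).sum())
    # A * sum(f_a f_b) dA with f = mass/cell_area reduces to:
    return float(overlap_cells * (ud_a.mass * ud_b.mass).sum())


def homerange_udoi(
    records: pd.DataFrame,
    ids: list[str] | None = None,
    cell: float = 100.0,
    bandwidth: float | None = None,
    homerange_level: float = 0.90,
    min_points: int = 5,
) -> DyadMatrix:
    """Pairwise UDOI matrix from sighting locations (shared grid)."""
    if ids is None:
        ids = sorted(records["individual_id"].astype(str).unique())
    pts_all = records[["x", "y"]].to_numpy(float)
    grid = make_grid(pts_all, cell=cell)
    uds = {}
    for ind in ids:
        pts = records.loc[records["individual_id"].astype(str) == ind, ["x", "y"]].to_numpy(float)
        uds[ind] = kernel_ud(pts, grid, bandwidth=bandwidth, individual_id=ind,
                             min_points=min_points)
    n = len(ids)
    out = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            ua, ub = uds[ids[i]], uds[ids[j]]
            if ua is None or ub is None:
                continue
            out[i, j] = out[j, i] = udoi(ua, ub, homerange_level)
    return DyadMatrix(ids, out, kind="PREDICTOR")


# ---------------------------------------------------------------------------
# class-match matrices
# ---------------------------------------------------------------------------

def class_match(
    labels: pd.Series, ids: list[str], mask_unknown: bool = False
) -> DyadMatrix:
    """Binary same-class indicator matrix.

    With ``mask_unknown`` (used for sex), dyads involving an UNKNOWN label are
    undefined rather than scored as mismatches.
    """
    lab = labels.reindex(ids)
    if lab.isna().any():
        raise ValueError("class label missing for some individuals")
    arr = lab.to_numpy()
    out = (arr[:, None] == arr[None, :]).astype(float)
    if mask_unknown:
        unk = arr == "UNKNOWN"
        out[unk, :] = np.nan
        out[:, unk] = np.nan
    return DyadMatrix(ids, out, kind="PREDICTOR")


def build_predictor_set(
    records: pd.DataFrame,
    hwi_matrix: DyadMatrix,
    classes: pd.DataFrame,
    cell: float = 100.0,
    include_homerange: bool = True,
) -> dict[str, DyadMatrix]:
    """Assemble the full named predictor collection on a common id order."""
    ids = hwi_matrix.ids
    cls = classes.set_index("individual_id")
    preds = {
        "gregariousness": gregariousness_predictor(hwi_matrix),
        "spatial_overlap": spatial_overlap(records, ids),
        "temporal_overlap": temporal_overlap(records, ids),
        "area_match": class_match(cls["area_class"], ids),
        "sex_match": class_match(cls["sex"], ids, mask_unknown=True),
        "period_match": class_match(cls["period_class"], ids),
    }
    if include_homerange:
        preds["homerange_udoi"] = homerange_udoi(records, ids, cell=cell)
    return preds
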