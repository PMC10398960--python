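"""Spatial elasticity maps and the hippocampal subregion scheme.

Fitted moduli acquired on a regular 30 μm grid over a 1,500 × 450 μm
field are assembled into an :class:`ElasticityMap`, assigned to one of
ten anatomical subregions via a label mask, and grouped into the seven
analysis groups used for statistics:

====  ==========================  ===============
label  subregion                   analysis group
====  ==========================  ===============
1      CA1 stratum oriens          CA1_SO_SR
2      CA1 stratum pyramidale      CA1_PYR
3      CA1 stratum radiatum        CA1_SO_SR
4      stratum lacunosum-molec.    SLM
5      DG molecular layer          ML
6      DG granule cell layer       DG_GCL
7      Hilus                       HILUS_CA3_SO_SR
8      CA3 stratum oriens          HILUS_CA3_SO_SR
9      CA3 stratum pyramidale      CA3_PYR
10     CA3 stratum radiatum        HILUS_CA3_SO_SR
====  ==========================  ===============

The CA1 oriens/radiatum pair is pooled because the two layers respond
almost identically to age and genotype; the CA3 oriens/radiatum are
pooled with the Hilus because their boundaries are ambiguous in slices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    DuplicatePositionError,
    LabelError,
    ParameterError,
    RenderError,
)

__all__ = [
    "AnalysisGroup",
    "LABEL_TO_GROUP",
    "GROUP_TO_LABELS",
    "ElasticityMap",
    "RegionMask",
    "assemble_map",
    "assign_regions",
    "group_regions",
    "render_map",
    "grid_shape",
]

DEFAULT_STEP_UM = 30.0
DEFAULT_EXTENT_UM = (1500.0, 450.0)


class AnalysisGroup(str, Enum):
    """The seven region groups compared statistically."""

    CA1_SO_SR = "CA1_SO_SR"
    CA1_PYR = "CA1_PYR"
    SLM = "SLM"
    ML = "ML"
    DG_GCL = "DG_GCL"
    HILUS_CA3_SO_SR = "HILUS_CA3_SO_SR"
    CA3_PYR = "CA3_PYR"


LABEL_TO_GROUP: Mapping[int, AnalysisGroup] = {
    1: AnalysisGroup.CA1_SO_SR,
    2: AnalysisGroup.CA1_PYR,
    3: AnalysisGroup.CA1_SO_SR,
    4: AnalysisGroup.SLM,
    5: AnalysisGroup.ML,
    6: AnalysisGroup.DG_GCL,
    7: AnalysisGroup.HILUS_CA3_SO_SR,
    8: AnalysisGroup.HILUS_CA3_SO_SR,
    9: AnalysisGroup.CA3_PYR,
    10: AnalysisGroup.HILUS_CA3_SO_SR,
}

GROUP_TO_LABELS: Mapping[AnalysisGroup, tuple[int, ...]] = {
    g: tuple(l for l, gg in LABEL_TO_GROUP.items() if gg is g) for g in AnalysisGroup
}


def grid_shape(
    extent: tuple[float, float] = DEFAULT_EXTENT_UM, step: float = DEFAULT_STEP_UM
) -> tuple[int, int]:
    """(ny, nx) of an inclusive-endpoint grid over ``extent`` at ``step``.

    The default 1,500 × 450 μm field at 30 μm steps gives 51 × 16 points.
    """
    if step <= 0:
        raise ParameterError("step must be positive")
    nx = int(np.floor(extent[0] / step + 1e-9)) + 1
    ny = int(np.floor(extent[1] / step + 1e-9)) + 1
    return ny, nx


@dataclass
class ElasticityMap:
    """Grid of fitted moduli (Pa); NaN marks missing cells.

    Coordinates are cell-centred: grid[j, i] sits at
    (origin_x + i·step, origin_y + j·step), x rightward, y downward.
    """

    grid: np.ndarray
    origin: tuple[float, float] = (0.0, 0.0)
    step: float = DEFAULT_STEP_UM
    extent: tuple[float, float] = DEFAULT_EXTENT_UM

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2:
            raise ParameterError("grid must be 2-D")
        if self.step <= 0:
            raise ParameterError("step must be positive")
        finite = self.grid[np.isfinite(self.grid)]
        if finite.size and np.any(finite <= 0):
            raise ParameterError("stored moduli must be positive")

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.grid).sum())


@dataclass
class RegionMask:
    """Label image aligned to a map grid; 0 = unassigned, 1-10 subregions."""

    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ParameterError("label mask must be 2-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            lab = np.asarray(self.labels)
            if not np.allclose(lab, np.round(lab)):
                raise ParameterError("mask labels must be integers")
            self.labels = lab.astype(int)
        vals = np.unique(self.labels)
        if vals.min(initial=0) < 0 or vals.max(initial=0) > 10:
            raise LabelError(f"mask labels must lie in 0..10, found {vals}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


def assemble_map(
    fits: pd.DataFrame,
    origin: tuple[float, float] = (0.0, 0.0),
    step: float = DEFAULT_STEP_UM,
    extent: tuple[float, float] = DEFAULT_EXTENT_UM,
) -> ElasticityMap:
    """Place per-curve fit results onto the acquisition grid.

    ``fits`` needs columns x_um, y_um, E_Pa, quality_flag.  Positions
    must sit on the grid within step/4; results whose quality flag is
    not ``ok`` (or whose modulus is not finite/positive) become missing
    cells, mirroring the gaps rendered in published maps.
    """
    ny, nx = grid_shape(extent, step)
    grid = np.full((ny, nx), np.nan)
    seen = np.zeros((ny, nx), dtype=bool)
    for row in fits.itertuples(index=False):
        fx = (row.x_um - origin[0]) / step
        fy = (row.y_um - origin[1]) / step
        i, j = int(round(fx)), int(round(fy))
        if abs(fx - i) > 0.25 or abs(fy - j) > 0.25:
            raise AlignmentError(
                f"position ({row.x_um}, {row.y_um}) is off-grid by more than step/4"
            )
        if not (0 <= i < nx and 0 <= j < ny):
            raise AlignmentError(
                f"position ({row.x_um}, {row.y_um}) lies outside the map extent"
            )
        if seen[j, i]:
            raise DuplicatePositionError(
                f"two fits map to grid cell ({i}, {j}) at ({row.x_um}, {row.y_um})"
            )
        seen[j, i] = True
        e = row.E_Pa
        if row.quality_flag == "ok" and np.isfinite(e) and e > 0:
            grid[j, i] = e
    return ElasticityMap(grid=grid, origin=origin, step=step, extent=extent)


def assign_regions(emap: ElasticityMap, mask: RegionMask) -> pd.DataFrame:
    """Turn non-missing map cells into labelled point records.

    Returns a frame with columns x_um, y_um, E_Pa, subregion; cells
    with label 0 (unassigned anatomy) are excluded.
    """
    if mask.shape != emap.grid.shape:
        raise AlignmentError(
            f"mask shape {mask.shape} does not match map grid {emap.grid.shape}"
        )
    jj, ii = np.nonzero(np.isfinite(emap.grid) & (mask.labels > 0))
    return pd.DataFrame(
        {
            "x_um": emap.origin[0] + ii * emap.step,
            "y_um": emap.origin[1] + jj * emap.step,
            "E_Pa": emap.grid[jj, ii],
            "subregion": mask.labels[jj, ii].astype(int),
        }
    )


def group_regions(points: pd.DataFrame) -> pd.DataFrame:
    """Add the 7-way ``analysis_group`` column from ``subregion`` labels."""
    labels = points["subregion"].to_numpy()
    bad = set(np.unique(labels)) - set(LABEL_TO_GROUP)
    if bad:
        raise LabelError(f"subregion labels outside 1..10: {sorted(bad)}")
    out = points.copy()
    out["analysis_group"] = [LABEL_TO_GROUP[int(l)].value for l in labels]
    return out


def render_map(
    emap: ElasticityMap,
    color_range: tuple[float, float] = (0.0, 800.0),
    path: str | None = None,
):
    """Render an elasticity map as a raster figure.

    Dark red encodes soft tissue and bright yellow stiff tissue
    ("hot" colormap, default 0-800 Pa).  Missing cells and moduli above
    the colour range are overplotted with an 'X' marker, matching the
    convention of flagging absent points above 800 Pa.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    lo, hi = color_range
    if not (hi > lo >= 0):
        raise ParameterError("color_range must satisfy max > min >= 0")
    if not np.isfinite(emap.grid).any():
        raise RenderError("cannot render a map with no data")

    shown = np.where(emap.grid > hi, np.nan, emap.grid)
    fig, ax = plt.subplots(figsize=(10, 3.5))
    w, h = emap.extent
    im = ax.imshow(
        shown,
        cmap="hot",
        vmin=lo,
        vmax=hi,
        origin="upper",
        extent=(
            emap.origin[0] - emap.step / 2,
            emap.origin[0] + w + emap.step / 2,
            emap.origin[1] + h + emap.step / 2,
            emap.origin[1] - emap.step / 2,
        ),
        interpolation="nearest",
    )
    marked = np.isnan(shown)
    jj, ii = np.nonzero(marked)
    ax.scatter(
        emap.origin[0] + ii * emap.step,
        emap.origin[1] + jj * emap.step,
        marker="x",
        c="0.5",
        s=12,
        linewidths=0.8,
    )
    fig.colorbar(im, ax=ax, label="Young's modulus (Pa)")
    ax.set_xlabel("x (μm)")
    ax.set_ylabel("y (μm)")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
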