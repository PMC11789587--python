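"""Assemble tile summaries into the annotated screen table and heatmaps.

Joins per-tile quantification with the gradient-calibration parameters at
each tile centre, averages replicates, builds per-DOG 2D heatmap grids, and
fuses the four DOGs into one (T, S, W) -> response point cloud.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gradient_model import DOGLayout, make_tile_grid, map_position

__all__ = [
    "RESPONSES",
    "annotate_parameters",
    "merge_replicates",
    "HeatmapGrid",
    "build_heatmap",
    "plot_heatmap",
    "fuse_parameter_space",
]

RESPONSES = ("density", "median_ctcf_asma", "median_ctcf_col1")
PARAM_COLS = ("wavelength_um", "stiffness_mpa", "wca_deg")
KEY_COLS = ("dog", "condition", "col", "row")


def annotate_parameters(
    summaries: pd.DataFrame,
    layouts: dict[str, DOGLayout],
    tile_width_um: float = 1742.0,
    tile_height_um: float = 1298.0,
) -> pd.DataFrame:
    """Attach (x_mm, y_mm, T, S, W) at each tile centre to the summary rows.

    Row count is preserved; an unknown DOG name raises ``KeyError``.
    """
    if summaries.empty:
        out = summaries.copy()
        for c in ("x_mm", "y_mm", *PARAM_COLS):
            out[c] = pd.Series(dtype=float)
        return out
    param_rows = {}
    for dog in summaries["dog"].unique():
        if dog not in layouts:
            raise KeyError(f"no layout for DOG {dog!r}")
        grid = make_tile_grid(layouts[dog], tile_width_um, tile_height_um)
        for col, row, x, y in grid.tiles():
            p = map_position(layouts[dog], x, y)
            param_rows[(dog, col, row)] = (x, y, p.wavelength_um, p.stiffness_mpa, p.wca_deg)
    vals = np.array(
        [param_rows[(r.dog, r.col, r.row)] for r in summaries.itertuples()], dtype=float
    )
    out = summaries.copy()
    for i, c in enumerate(("x_mm", "y_mm", *PARAM_COLS)):
        out[c] = vals[:, i]
    return out


def merge_replicates(table: pd.DataFrame, responses=RESPONSES) -> pd.DataFrame:
    """Arithmetic mean per response over replicates of each tile.

    Grouping key is (dog, condition, col, row).  Means are taken over the
    non-missing replicate values only; per-response replicate counts are
    recorded as ``n_reps_<response>`` and the overall replicate count as
    ``n_reps``.
    """
    keep = [c for c in table.columns if c not in responses and c != "replicate"]
    agg: dict = {r: (r, "mean") for r in responses if r in table.columns}
    first_cols = [c for c in keep if c not in KEY_COLS and c not in ("n_cells",)]
    grouped = table.groupby(list(KEY_COLS), sort=True, dropna=False)
    out = grouped.agg(**{r: v for r, v in agg.items()}).reset_index()
    out["n_reps"] = grouped.size().to_numpy()
    for r in responses:
        if r in table.columns:
            out[f"n_reps_{r}"] = grouped[r].count().to_numpy()
    firsts = grouped[first_cols].first().reset_index(drop=True)
    for c in first_cols:
        if c not in out.columns:
            out[c] = firsts[c].to_numpy()
    return out


@dataclass(frozen=True)
class HeatmapGrid:
    """Replicate-mean response on one DOG's tile grid, with axis annotations."""

    dog: str
    response: str
    values: np.ndarray  # (n_rows, n_cols), NaN where missing
    x_axis_param: str
    y_axis_param: str
    x_axis_values: np.ndarray
    y_axis_values: np.ndarray


def build_heatmap(
    merged: pd.DataFrame,
    dog: str,
    response: str,
    layouts: dict[str, DOGLayout],
    tile_width_um: float = 1742.0,
    tile_height_um: float = 1298.0,
) -> HeatmapGrid:
    """Grid of replicate-mean *response* over one DOG; missing tiles stay NaN."""
    sub = merged[merged["dog"] == dog]
    if sub.empty:
        raise ValueError(f"no rows for DOG {dog!r}")
    if response not in merged.columns:
        raise ValueError(f"response {response!r} not in table")
    layout = layouts[dog]
    grid = make_tile_grid(layout, tile_width_um, tile_height_um)
    values = np.full((grid.n_rows, grid.n_cols), np.nan)
    for r in sub.itertuples():
        values[r.row, r.col] = getattr(r, response)

    centers_x = np.array([grid.tile_center_mm(c, 0)[0] for c in range(grid.n_cols)])
    centers_y = np.array([grid.tile_center_mm(0, rw)[1] for rw in range(grid.n_rows)])
    x_kind = layout.x_axis[0].parameter_kind if layout.x_axis else "fixed"
    y_kind = layout.y_axis[0].parameter_kind if layout.y_axis else "fixed"
    x_vals = layout.x_axis[0](centers_x) if layout.x_axis else centers_x
    y_vals = layout.y_axis[0](centers_y) if layout.y_axis else centers_y
    return HeatmapGrid(dog, response, values, x_kind, y_kind, np.asarray(x_vals), np.asarray(y_vals))


def plot_heatmap(grid: HeatmapGrid, path) -> None:
    """Render a heatmap grid to an image file with parameter-unit axis ticks."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    im = ax.imshow(grid.values, origin="lower", aspect="auto", cmap="viridis")
    ax.set_xticks(range(len(grid.x_axis_values)))
    ax.set_xticklabels([f"{v:.3g}" for v in grid.x_axis_values], rotation=90, fontsize=7)
    ax.set_yticks(range(len(grid.y_axis_values)))
    ax.set_yticklabels([f"{v:.3g}" for v in grid.y_axis_values], fontsize=7)
    ax.set_xlabel(grid.x_axis_param)
    ax.set_ylabel(grid.y_axis_param)
    ax.set_title(f"{grid.dog}: {grid.response}")
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def fuse_parameter_space(merged: pd.DataFrame, responses=RESPONSES) -> pd.DataFrame:
    """Fuse all DOGs into one 3D (T, S, W) -> response point cloud.

    Plain concatenation: no deduplication across DOGs, no rescaling; each
    point keeps its source DOG as provenance.
    """
    cols = ["dog", *[c for c in ("condition", "col", "row") if c in merged.columns], *PARAM_COLS]
    cols += [r for r in responses if r in merged.columns]
    missing = [c for c in PARAM_COLS if c not in merged.columns]
    if missing:
        raise ValueError(f"table lacks parameter columns {missing}; run annotate_parameters first")
    return merged[cols].reset_index(drop=True)
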