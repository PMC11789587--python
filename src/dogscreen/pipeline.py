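"""End-to-end drivers composing generation, quantification and assembly."""

from __future__ import annotations

import pandas as pd

from .gradient_model import DOGLayout, default_layouts
from .screen_assembly import annotate_parameters, merge_replicates
from .segment_quant import SegmentationConfig, quantify_tile
from .synth_screen import Condition, OpticsConfig, ResponseModel, iterate_screen

__all__ = ["quantify_screen_in_memory", "run_synthetic_screen"]


def quantify_screen_in_memory(
    model: ResponseModel,
    layouts: dict[str, DOGLayout],
    seed: int,
    optics: OpticsConfig | None = None,
    conditions: tuple[Condition, ...] = (Condition("7d", True),),
    replicates: dict[str, int] | int = 1,
    seg_config: SegmentationConfig | None = None,
    tile_width_um: float = 1742.0,
    tile_height_um: float = 1298.0,
    keep_truth: bool = True,
) -> pd.DataFrame:
    """Render and quantify a synthetic screen tile by tile without touching disk.

    Returns the tile summary table (one row per tile x replicate x condition),
    optionally with the planted ground truth columns alongside for validation.
    """
    optics = optics or OpticsConfig()
    rows = []
    for meta, gt, img in iterate_screen(
        model, layouts, seed, conditions, replicates, optics, tile_width_um, tile_height_um
    ):
        _, summary = quantify_tile(
            img, optics.pixel_size_um, seg_config,
            dog=meta["dog"], replicate=meta["replicate"], condition=meta["condition"],
            col=meta["col"], row=meta["row"],
            tile_width_um=tile_width_um, tile_height_um=tile_height_um,
        )
        rec = summary.as_dict()
        if keep_truth:
            rec.update(
                true_n_cells=gt.n_cells,
                true_density=gt.true_density,
                true_median_ctcf_asma=gt.true_median_ctcf["asma"],
                true_median_ctcf_col1=gt.true_median_ctcf["col1"],
            )
        rows.append(rec)
    return pd.DataFrame(rows)


def run_synthetic_screen(
    seed: int,
    pixel_size_um: float = 1.0,
    model: ResponseModel | None = None,
    layouts: dict[str, DOGLayout] | None = None,
    conditions: tuple[Condition, ...] = (Condition("7d", True),),
    replicates: dict[str, int] | int = 1,
    seg_config: SegmentationConfig | None = None,
) -> pd.DataFrame:
    """Full default pipeline: simulate, quantify, annotate, merge replicates."""
    model = model or ResponseModel()
    layouts = layouts or default_layouts()
    optics = OpticsConfig(pixel_size_um=pixel_size_um)
    summaries = quantify_screen_in_memory(
        model, layouts, seed, optics, conditions, replicates, seg_config
    )
    annotated = annotate_parameters(summaries, layouts)
    return merge_replicates(annotated)
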