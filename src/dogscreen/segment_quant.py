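"""Nucleus-seeded cell segmentation and CTCF quantification for screen tiles.

Re-implements the screening contract of a CellProfiler-style pipeline: smooth
and threshold the nucleus channel, declump touching nuclei with an h-maxima-
seeded distance-transform watershed, remove large artefacts, grow cell bodies
by a seeded watershed on the summed marker channels (falling back to fixed-
radius dilation where there is no marker signal), and quantify each cell's
corrected total cell fluorescence

    CTCF = integrated density - cell area (um^2) x mean background intensity,

where integrated density is cell area (um^2) x mean per-pixel intensity and
the background is the mean over all non-cell pixels of the same tile and
channel.  Negative CTCF values are kept: clipping would bias tile medians
upward on dim tiles.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage.filters import threshold_local, threshold_otsu
from skimage.morphology import h_maxima
from skimage.segmentation import watershed

from .synth_screen import CHANNELS, MARKERS

__all__ = [
    "SegmentationConfig",
    "TileSummary",
    "segment_nuclei",
    "segment_cells",
    "remove_artifacts",
    "compute_ctcf",
    "summarize_tile",
    "quantify_tile",
    "quantify_manifest",
    "match_to_ground_truth",
]


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunable segmentation parameters, all in physical units (um / um^2)."""

    smoothing_sigma_um: float = 2.0
    threshold_method: str = "otsu"  # "otsu" | "local"
    local_block_um: float = 200.0
    min_nucleus_area_um2: float = 20.0
    max_nucleus_area_um2: float = 400.0
    artifact_max_area_um2: float = 5000.0
    declump_h_um: float = 2.0
    cell_expansion: str = "watershed"  # "watershed" | "dilation"
    dilation_radius_um: float = 16.0
    border_exclusion: bool = True

    def __post_init__(self) -> None:
        if not (self.min_nucleus_area_um2 < self.max_nucleus_area_um2 < self.artifact_max_area_um2):
            raise ValueError("need min_nucleus_area < max_nucleus_area < artifact_max_area")
        if self.smoothing_sigma_um < 0:
            raise ValueError("smoothing sigma must be >= 0")
        if self.threshold_method not in ("otsu", "local"):
            raise ValueError("threshold_method must be 'otsu' or 'local'")
        if self.cell_expansion not in ("watershed", "dilation"):
            raise ValueError("cell_expansion must be 'watershed' or 'dilation'")


def _threshold(img: np.ndarray, config: SegmentationConfig, pixel_size_um: float) -> np.ndarray:
    """Foreground mask, robust to tiles that are pure background.

    Otsu (or a local threshold) splits even a noise-only image, so the
    threshold is floored at median + 5 sigma of the (MAD-estimated) background
    noise; a tile with no signal then yields an empty mask.
    """
    if img.max() == img.min():
        return np.zeros(img.shape, dtype=bool)
    sub = img[::2, ::2]  # statistics on a subsample; thresholds are global anyway
    med = float(np.median(sub))
    mad_sigma = 1.4826 * float(np.median(np.abs(sub - med)))
    floor = med + 5.0 * mad_sigma
    if config.threshold_method == "local":
        block = int(config.local_block_um / pixel_size_um) | 1  # odd
        return (img > threshold_local(img, block_size=max(block, 3), method="gaussian")) & (
            img > floor
        )
    return img > max(threshold_otsu(sub), floor)


def segment_nuclei(
    nucleus_img: np.ndarray, pixel_size_um: float, config: SegmentationConfig | None = None
) -> np.ndarray:
    """Label nuclei in a single-channel image.

    Pipeline: Gaussian smoothing, thresholding, hole filling, h-maxima-seeded
    distance-transform watershed declumping of clumps, and size filtering to
    ``[min_nucleus_area, max_nucleus_area]``.  Declumping only touches
    connected components larger than ``max_nucleus_area``; isolated nuclei
    pass through unsplit.  An all-zero image yields an empty label map.
    """
    config = config or SegmentationConfig()
    img = np.asarray(nucleus_img, dtype=np.float32)
    sigma_px = config.smoothing_sigma_um / pixel_size_um
    smoothed = ndi.gaussian_filter(img, sigma_px) if sigma_px > 0 else img
    fg = _threshold(smoothed, config, pixel_size_um)
    if not fg.any():
        return np.zeros(img.shape, dtype=np.int32)
    fg = ndi.binary_fill_holes(fg)

    labels, n = ndi.label(fg)
    labels = labels.astype(np.int32)
    px_area = pixel_size_um**2
    max_px = config.max_nucleus_area_um2 / px_area
    counts = np.bincount(labels.ravel())
    clumps = np.flatnonzero(counts > max_px)
    clumps = clumps[clumps > 0]
    if clumps.size:
        labels = _declump(labels, clumps, config.declump_h_um, pixel_size_um)

    # size filter to [min, max] nucleus area
    counts = np.bincount(labels.ravel(), minlength=labels.max() + 1)
    min_px = config.min_nucleus_area_um2 / px_area
    bad = (counts < min_px) | (counts > max_px)
    bad[0] = False
    if bad.any():
        labels[bad[labels]] = 0
    return _relabel_sequential(labels)


def _declump(labels: np.ndarray, clump_ids: np.ndarray, h_um: float, pixel_size_um: float) -> np.ndarray:
    """Split oversized components with a watershed on their distance transform."""
    out = labels.copy()
    next_label = int(labels.max()) + 1
    slices = ndi.find_objects(labels)
    for cid in clump_ids:
        sl = slices[cid - 1]
        if sl is None:
            continue
        sub = labels[sl] == cid
        dist = ndi.distance_transform_edt(sub, sampling=pixel_size_um)
        h = max(h_um, pixel_size_um)
        maxima = h_maxima(dist, h)
        seeds, n_seeds = ndi.label(maxima)
        if n_seeds <= 1:
            continue
        split = watershed(-dist, seeds, mask=sub)
        region = out[sl]
        region[sub] = split[sub] + (next_label - 1)
        next_label += n_seeds
    return out


def _relabel_sequential(labels: np.ndarray) -> np.ndarray:
    ids = np.unique(labels)
    ids = ids[ids > 0]
    lut = np.zeros(labels.max() + 1 if labels.size else 1, dtype=np.int32)
    lut[ids] = np.arange(1, ids.size + 1, dtype=np.int32)
    return lut[labels]


def remove_artifacts(labels: np.ndarray, artifact_max_area_um2: float, pixel_size_um: float) -> np.ndarray:
    """Remove labelled objects larger than *artifact_max_area_um2*; survivors keep ids."""
    if labels.max() == 0:
        return labels
    counts = np.bincount(labels.ravel(), minlength=labels.max() + 1)
    max_px = artifact_max_area_um2 / pixel_size_um**2
    bad = counts > max_px
    bad[0] = False
    if not bad.any():
        return labels
    out = labels.copy()
    out[bad[labels]] = 0
    if out.max() == 0:
        warnings.warn(
            "artifact threshold removed every object; check artifact_max_area_um2",
            stacklevel=2,
        )
    return out


def segment_cells(
    marker_imgs,
    nuclei_labels: np.ndarray,
    pixel_size_um: float,
    config: SegmentationConfig | None = None,
) -> np.ndarray:
    """Grow one cell region per nucleus (labels preserved).

    A seeded watershed runs on the smoothed sum of the marker channels within
    a mask of thresholded marker signal union the nuclei dilated by
    ``dilation_radius_um``; where marker signal is below threshold the
    dilation alone provides the body (fallback contract).  Regions are
    disjoint and each contains its nucleus.
    """
    config = config or SegmentationConfig()
    if nuclei_labels.max() == 0:
        return nuclei_labels.copy()
    r_px = max(1, int(round(config.dilation_radius_um / pixel_size_um)))

    if config.cell_expansion == "dilation":
        dist_to_nuc, (iy, ix) = ndi.distance_transform_edt(
            nuclei_labels == 0, return_indices=True
        )
        cells = np.where(dist_to_nuc <= r_px, nuclei_labels[iy, ix], 0)
        cells[nuclei_labels > 0] = nuclei_labels[nuclei_labels > 0]
        return cells.astype(np.int32)

    marker_sum = np.zeros(nuclei_labels.shape, dtype=np.float32)
    for im in marker_imgs:
        marker_sum += np.asarray(im, dtype=np.float32)
    sigma_px = config.smoothing_sigma_um / pixel_size_um
    smoothed = ndi.gaussian_filter(marker_sum, sigma_px) if sigma_px > 0 else marker_sum

    dist_to_nuc = ndi.distance_transform_edt(nuclei_labels == 0)
    dilated = dist_to_nuc <= r_px
    fg = _threshold(smoothed, config, pixel_size_um)
    mask = fg | dilated | (nuclei_labels > 0)

    # watershed on inverted marker signal; nearest-nucleus distance breaks
    # ties in signal-free (fallback) regions
    elevation = -smoothed + np.float32(1e-3) * dist_to_nuc.astype(np.float32)
    cells = watershed(elevation, nuclei_labels, mask=mask)
    # never let a cell claim signal-free territory beyond the dilation radius;
    # inside it the dilated disk acts as a floor, so the faint blurred rim of a
    # cell body stays with the cell instead of contaminating the background
    cells[(~fg) & (dist_to_nuc > r_px)] = 0
    cells[nuclei_labels > 0] = nuclei_labels[nuclei_labels > 0]
    return cells.astype(np.int32)


def compute_ctcf(
    channel_img: np.ndarray,
    cell_labels: np.ndarray,
    pixel_size_um: float,
    background_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-cell CTCF for one channel.

    Returns a DataFrame indexed by label with columns ``area_um2``,
    ``mean_intensity``, ``integrated_density`` and ``ctcf``.  The background
    mask defaults to all non-cell pixels; an empty background is an error
    (background undefined).
    """
    img = np.asarray(channel_img, dtype=float)
    if background_mask is None:
        background_mask = cell_labels == 0
    if not background_mask.any():
        raise ValueError("background mask is empty; background intensity undefined")
    bg_mean = float(img[background_mask].mean())
    px_area = pixel_size_um**2
    n_labels = int(cell_labels.max())
    if n_labels == 0:
        return pd.DataFrame(
            columns=["area_um2", "mean_intensity", "integrated_density", "ctcf", "background_mean"]
        )
    flat = cell_labels.ravel()
    counts = np.bincount(flat, minlength=n_labels + 1)[1:]
    sums = np.bincount(flat, weights=img.ravel(), minlength=n_labels + 1)[1:]
    present = counts > 0
    labels_idx = np.arange(1, n_labels + 1)[present]
    counts = counts[present]
    sums = sums[present]
    area = counts * px_area
    mean = sums / counts
    integrated = area * mean
    ctcf = integrated - area * bg_mean
    return pd.DataFrame(
        dict(
            area_um2=area,
            mean_intensity=mean,
            integrated_density=integrated,
            ctcf=ctcf,
            background_mean=bg_mean,
        ),
        index=pd.Index(labels_idx, name="label"),
    )


@dataclass(frozen=True)
class TileSummary:
    """Per-tile quantification record."""

    dog: str
    replicate: int
    condition: str
    col: int
    row: int
    n_cells: int
    density: float  # cells mm^-2
    median_ctcf_asma: float  # nan when n_cells == 0
    median_ctcf_col1: float
    background_asma: float
    background_col1: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def summarize_tile(
    cell_records: pd.DataFrame,
    tile_width_um: float,
    tile_height_um: float,
    dog: str = "",
    replicate: int = 1,
    condition: str = "",
    col: int = 0,
    row: int = 0,
) -> TileSummary:
    """Aggregate per-cell records of one tile: density = count / area, medians of CTCF."""
    area_mm2 = tile_width_um * tile_height_um / 1e6
    n = int(len(cell_records))
    med = {}
    bg = {}
    for m in MARKERS:
        col_name = f"ctcf_{m}"
        med[m] = float(cell_records[col_name].median()) if n else float("nan")
        bg_col = f"background_{m}"
        bg[m] = float(cell_records[bg_col].iloc[0]) if n and bg_col in cell_records else float("nan")
    return TileSummary(
        dog, replicate, condition, col, row, n, n / area_mm2,
        med["asma"], med["col1"], bg["asma"], bg["col1"],
    )


def quantify_tile(
    image: np.ndarray,
    pixel_size_um: float,
    config: SegmentationConfig | None = None,
    **meta,
) -> tuple[pd.DataFrame, TileSummary]:
    """Run the full per-tile pipeline on a ``(3, H, W)`` image.

    Returns the per-cell record table (centroid, areas, per-channel intensity
    and CTCF) and the tile summary.  ``meta`` must include the tile identity
    fields of :class:`TileSummary` plus ``tile_width_um``/``tile_height_um``
    (defaulting to the pixel grid).
    """
    config = config or SegmentationConfig()
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[0] < len(CHANNELS):
        raise ValueError(f"expected a ({len(CHANNELS)}, H, W) image, got shape {image.shape}")
    h, w = image.shape[1:]
    tile_w = float(meta.pop("tile_width_um", w * pixel_size_um))
    tile_h = float(meta.pop("tile_height_um", h * pixel_size_um))
    ident = dict(
        dog=meta.pop("dog", ""), replicate=int(meta.pop("replicate", 1)),
        condition=meta.pop("condition", ""), col=int(meta.pop("col", 0)),
        row=int(meta.pop("row", 0)),
    )

    nuclei = segment_nuclei(image[0], pixel_size_um, config)
    nuclei = remove_artifacts(nuclei, config.artifact_max_area_um2, pixel_size_um)
    if config.border_exclusion and nuclei.max() > 0:
        edge_labels = np.unique(
            np.concatenate([nuclei[0, :], nuclei[-1, :], nuclei[:, 0], nuclei[:, -1]])
        )
        if edge_labels.max() > 0:
            lut = np.arange(nuclei.max() + 1, dtype=nuclei.dtype)
            lut[edge_labels] = 0
            nuclei = lut[nuclei]
    cells = segment_cells([image[1], image[2]], nuclei, pixel_size_um, config)

    records = _cell_records(image, nuclei, cells, pixel_size_um)
    summary = summarize_tile(records, tile_w, tile_h, **ident)
    return records, summary


def _cell_records(image, nuclei, cells, pixel_size_um) -> pd.DataFrame:
    px_area = pixel_size_um**2
    if cells.max() == 0:
        cols = ["label", "centroid_x_um", "centroid_y_um", "nucleus_area_um2", "cell_area_um2"]
        for m in MARKERS:
            cols += [f"mean_{m}", f"integrated_{m}", f"ctcf_{m}", f"background_{m}"]
        return pd.DataFrame(columns=cols)
    ctcf = {m: compute_ctcf(image[1 + i], cells, pixel_size_um) for i, m in enumerate(MARKERS)}
    n_max = cells.max() + 1
    flat = cells.ravel()
    counts = np.bincount(flat, minlength=n_max)
    yy, xx = np.nonzero(cells)
    labs_px = cells[yy, xx]
    sum_x = np.bincount(labs_px, weights=xx, minlength=n_max)
    sum_y = np.bincount(labs_px, weights=yy, minlength=n_max)
    nuc_counts = np.bincount(nuclei.ravel(), minlength=n_max)
    labels_idx = np.flatnonzero(counts)
    labels_idx = labels_idx[labels_idx > 0]
    df = pd.DataFrame(
        dict(
            label=labels_idx,
            centroid_x_um=(sum_x[labels_idx] / counts[labels_idx] + 0.5) * pixel_size_um,
            centroid_y_um=(sum_y[labels_idx] / counts[labels_idx] + 0.5) * pixel_size_um,
            nucleus_area_um2=nuc_counts[labels_idx] * px_area,
            cell_area_um2=counts[labels_idx] * px_area,
        )
    )
    for m in MARKERS:
        t = ctcf[m].loc[labels_idx]
        df[f"mean_{m}"] = t["mean_intensity"].to_numpy()
        df[f"integrated_{m}"] = t["integrated_density"].to_numpy()
        df[f"ctcf_{m}"] = t["ctcf"].to_numpy()
        df[f"background_{m}"] = t["background_mean"].to_numpy()
    return df


def quantify_manifest(
    manifest,
    config: SegmentationConfig | None = None,
    base_dir: str | None = None,
    pixel_size_um: float | None = None,
) -> pd.DataFrame:
    """Quantify every tile listed in a manifest CSV/DataFrame.

    The manifest needs columns dog, replicate, condition, col, row, path and
    (unless overridden) pixel_size_um and tile dimensions.  Returns the tile
    summary table.
    """
    if not isinstance(manifest, pd.DataFrame):
        base_dir = base_dir or os.path.dirname(str(manifest))
        manifest = pd.read_csv(manifest)
    summaries = []
    for _, r in manifest.iterrows():
        path = r["path"]
        if base_dir and not os.path.isabs(path):
            path = os.path.join(base_dir, path)
        img = tifffile.imread(path)
        px = pixel_size_um if pixel_size_um is not None else float(r["pixel_size_um"])
        _, summary = quantify_tile(
            img, px, config,
            dog=r["dog"], replicate=r["replicate"], condition=r["condition"],
            col=r["col"], row=r["row"],
            tile_width_um=r.get("tile_width_um", img.shape[-1] * px),
            tile_height_um=r.get("tile_height_um", img.shape[-2] * px),
        )
        summaries.append(summary.as_dict())
    return pd.DataFrame(summaries)


def match_to_ground_truth(
    pred_xy_um: np.ndarray, true_xy_um: np.ndarray, max_dist_um: float = 15.0
) -> dict:
    """Greedy nearest-neighbour matching of detected to planted cell centroids.

    Returns a dict with n_matched, precision, recall.
    """
    pred = np.atleast_2d(np.asarray(pred_xy_um, dtype=float))
    true = np.atleast_2d(np.asarray(true_xy_um, dtype=float))
    n_pred = 0 if pred.size == 0 else len(pred)
    n_true = 0 if true.size == 0 else len(true)
    if n_pred == 0 or n_true == 0:
        return dict(
            n_matched=0,
            precision=1.0 if n_pred == 0 else 0.0,
            recall=1.0 if n_true == 0 else 0.0,
        )
    tree = cKDTree(true)
    dists, idx = tree.query(pred)
    order = np.argsort(dists)
    used = np.zeros(n_true, dtype=bool)
    matched = 0
    for i in order:
        if dists[i] > max_dist_um:
            break
        j = idx[i]
        if not used[j]:
            used[j] = True
            matched += 1
        else:
            # nearest taken; try the next unused neighbour within range
            cand = tree.query_ball_point(pred[i], max_dist_um)
            for j2 in sorted(cand, key=lambda k: np.linalg.norm(true[k] - pred[i])):
                if not used[j2]:
                    used[j2] = True
                    matched += 1
                    break
    return dict(n_matched=matched, precision=matched / n_pred, recall=matched / n_true)
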