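"""Synthetic DOG screen generator with planted parameter->response functions.

Stands in for an unreleased raw-image screen: normal human dermal fibroblasts
seeded on four DOG samples, cultured 24 h or 7 d with or without TGF-beta,
stained for nucleus / alpha-SMA / COL1 and imaged tile by tile.  The planted
model follows the screen's qualitative structure: cell density and marker
expression rise logistically as the surface becomes more hydrophilic
(lower water contact angle), stiffness adds a milder positive modulation,
topography a weak one, and myofibroblast markers only switch on after 7 days
in the presence of TGF-beta.

The generator exposes three granularities:

* :func:`sample_cells` / :func:`render_tile` -- one tile's ground-truth cell
  population and its rendered 3-channel 16-bit image;
* :func:`iterate_screen` -- stream ``(metadata, GroundTruthTile, image)`` for
  a whole screen without touching disk;
* :func:`generate_screen` -- write TIFFs + manifest + ground-truth CSV;
* :func:`simulate_summary_table` -- skip rendering and summarise the sampled
  ground truth directly (for model-level experiments).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import tifffile
from scipy.ndimage import gaussian_filter

from .gradient_model import (
    DOGLayout,
    ParameterPoint,
    TileGrid,
    make_tile_grid,
    map_position,
)

__all__ = [
    "CHANNELS",
    "MARKERS",
    "Condition",
    "CONDITIONS",
    "DEFAULT_REPLICATES",
    "ResponseModel",
    "OpticsConfig",
    "CellTruth",
    "GroundTruthTile",
    "expected_density",
    "expected_ctcf",
    "sample_cells",
    "render_tile",
    "iterate_screen",
    "generate_screen",
    "simulate_summary_table",
]

CHANNELS = ("nuclei", "asma", "col1")
MARKERS = ("asma", "col1")


@dataclass(frozen=True)
class Condition:
    """Experimental condition: culture timepoint x TGF-beta supplementation."""

    timepoint: str  # "24h" | "7d"
    tgfb: bool

    def __post_init__(self) -> None:
        if self.timepoint not in ("24h", "7d"):
            raise ValueError("timepoint must be '24h' or '7d'")

    @property
    def key(self) -> str:
        return f"{self.timepoint}_tgfb_{'pos' if self.tgfb else 'neg'}"

    @classmethod
    def from_key(cls, key: str) -> "Condition":
        tp, _, sign = key.split("_")
        return cls(tp, sign == "pos")


CONDITIONS = (
    Condition("24h", False),
    Condition("24h", True),
    Condition("7d", False),
    Condition("7d", True),
)

#: Replicate structure of the screen: n=4 for 7 d TGF-beta(+), n=2 otherwise.
DEFAULT_REPLICATES = {
    "24h_tgfb_neg": 2,
    "24h_tgfb_pos": 2,
    "7d_tgfb_neg": 2,
    "7d_tgfb_pos": 4,
}


def _logistic(z):
    return 1.0 / (1.0 + np.exp(-np.asarray(z, dtype=float)))


@dataclass(frozen=True)
class ResponseModel:
    """Planted ground-truth response functions and cell-level noise model.

    Density (cells mm^-2) saturates between ``d_min`` on the hydrophobic side
    and ``d_max`` on the hydrophilic side with a logistic transition at
    ``w50_density`` (width ``tau_w_density``), modulated fractionally by
    normalised stiffness (``gamma_s``) and topography (``gamma_t``).  Tile-
    median marker CTCF spans ``m_min``..``m_max`` a.u. with its own logistic
    in wettability and a stiffness weight ``beta_s``; the condition gates
    collapse the dynamic range to the ``m_min`` baseline for TGF-beta(-) and
    24 h cultures.  Normalised stiffness/topography use the screen-wide
    calibration ranges ``stiffness_range`` / ``topography_range``.
    """

    d_min: float = 50.0
    d_max: float = 300.0
    w50_density: float = 70.0
    tau_w_density: float = 8.0
    gamma_s: float = 0.2
    gamma_t: float = 0.05
    m_min: float = 5000.0
    m_max: float = 80000.0
    w50_marker: float = 55.0
    tau_w_marker: float = 5.0
    beta_s: float = 0.3
    col1_scale: float = 0.6
    condition_gates: dict = field(
        default_factory=lambda: {
            "24h_tgfb_neg": 0.0,
            "24h_tgfb_pos": 0.0,
            "7d_tgfb_neg": 0.0,
            "7d_tgfb_pos": 1.0,
        }
    )
    cell_cv: float = 0.35
    stiffness_range: tuple[float, float] = (15.0, 120.0)
    topography_range: tuple[float, float] = (0.0, 10.0)
    min_spacing_um: float = 25.0
    nucleus_radius_um: float = 6.0
    nucleus_radius_sd_um: float = 1.0
    cell_radius_factor: float = 2.6
    nucleus_total_au: float = 20000.0

    def __post_init__(self) -> None:
        if not self.d_min < self.d_max:
            raise ValueError("d_min must be < d_max")
        if not self.m_min < self.m_max:
            raise ValueError("m_min must be < m_max")
        if self.tau_w_density <= 0 or self.tau_w_marker <= 0:
            raise ValueError("logistic widths must be > 0")
        if any(not 0.0 <= g <= 1.0 for g in self.condition_gates.values()):
            raise ValueError("condition gates must lie in [0, 1]")

    def normalized_stiffness(self, s_mpa: float) -> float:
        lo, hi = self.stiffness_range
        return float(np.clip(2.0 * (s_mpa - lo) / (hi - lo) - 1.0, -1.0, 1.0))

    def normalized_topography(self, wl_um: float) -> float:
        lo, hi = self.topography_range
        return float(np.clip(2.0 * (wl_um - lo) / (hi - lo) - 1.0, -1.0, 1.0))

    def gate(self, condition: Condition) -> float:
        return float(self.condition_gates[condition.key])


def expected_density(model: ResponseModel, p: ParameterPoint, condition: Condition | None = None) -> float:
    """Planted mean cell density (cells mm^-2) at parameter point *p*.

    Density is not gated by condition: fibroblasts adhere in all conditions,
    only marker expression is condition-dependent.
    """
    s = model.normalized_stiffness(p.stiffness_mpa)
    t = model.normalized_topography(p.wavelength_um)
    w = _logistic((model.w50_density - p.wca_deg) / model.tau_w_density)
    d = (model.d_min + (model.d_max - model.d_min) * w) * (1.0 + model.gamma_s * s) * (
        1.0 + model.gamma_t * t
    )
    return float(max(d, 0.0))


def expected_ctcf(
    model: ResponseModel, p: ParameterPoint, condition: Condition, marker: str = "asma"
) -> float:
    """Planted tile-median marker CTCF (a.u.) at parameter point *p*.

    The condition gate scales only the dynamic range, so gated conditions sit
    at the ``m_min`` baseline rather than zero.  COL1 follows the alpha-SMA
    shape scaled by ``col1_scale``.
    """
    if marker not in MARKERS:
        raise ValueError(f"unknown marker {marker!r}")
    s = model.normalized_stiffness(p.stiffness_mpa)
    w = _logistic((model.w50_marker - p.wca_deg) / model.tau_w_marker)
    stiff_mod = 1.0 - model.beta_s + model.beta_s * (s + 1.0) / 2.0
    m = model.m_min + model.gate(condition) * (model.m_max - model.m_min) * w * stiff_mod
    if marker == "col1":
        m *= model.col1_scale
    return float(m)


@dataclass(frozen=True)
class CellTruth:
    """One planted cell: geometry plus per-channel total signal (a.u. = counts x um^2)."""

    x_um: float
    y_um: float
    nucleus_radius_um: float
    cell_radius_um: float
    totals: dict  # channel -> total integrated signal above background


@dataclass(frozen=True)
class GroundTruthTile:
    """Ground truth for one tile: planted expectations and the sampled cells."""

    col: int
    row: int
    tile_width_um: float
    tile_height_um: float
    true_density: float
    true_median_ctcf: dict  # marker -> a.u.
    cells: tuple[CellTruth, ...]

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def area_mm2(self) -> float:
        return self.tile_width_um * self.tile_height_um / 1e6


class PlacementError(RuntimeError):
    pass


def _hardcore_positions(n, width, height, margin, min_spacing, rng, max_tries_per_cell=200):
    """Dart-throwing hard-core point process inside [margin, dim-margin]^2."""
    if n == 0:
        return np.empty((0, 2))
    lo_x, hi_x = margin, width - margin
    lo_y, hi_y = margin, height - margin
    if hi_x <= lo_x or hi_y <= lo_y:
        raise PlacementError("tile too small for the requested cell margin")
    pts = np.empty((n, 2))
    d2 = min_spacing**2
    placed = 0
    tries = 0
    budget = max_tries_per_cell * n
    while placed < n:
        if tries > budget:
            raise PlacementError(
                f"hard-core placement failed after {budget} attempts at n={n}; "
                "reduce min_spacing_um or the planted density"
            )
        tries += 1
        cand = np.array([rng.uniform(lo_x, hi_x), rng.uniform(lo_y, hi_y)])
        if placed:
            if np.min(np.sum((pts[:placed] - cand) ** 2, axis=1)) < d2:
                continue
        pts[placed] = cand
        placed += 1
    return pts


def sample_cells(
    model: ResponseModel,
    p: ParameterPoint,
    condition: Condition,
    rng: np.random.Generator,
    tile_width_um: float = 1742.0,
    tile_height_um: float = 1298.0,
    col: int = 0,
    row: int = 0,
) -> GroundTruthTile:
    """Draw one tile's cell population from the planted model.

    Cell count is Poisson at the planted density x tile area; positions come
    from a hard-core process (min spacing ``model.min_spacing_um``); per-cell
    marker totals are lognormal around the planted tile median with
    coefficient of variation ``model.cell_cv``.
    """
    dens = expected_density(model, p, condition)
    area_mm2 = tile_width_um * tile_height_um / 1e6
    n = int(rng.poisson(dens * area_mm2))
    medians = {m: expected_ctcf(model, p, condition, m) for m in MARKERS}

    max_cell_r = model.cell_radius_factor * (model.nucleus_radius_um + 3 * model.nucleus_radius_sd_um)
    pts = _hardcore_positions(n, tile_width_um, tile_height_um, max_cell_r, model.min_spacing_um, rng)
    nuc_r = np.clip(
        rng.normal(model.nucleus_radius_um, model.nucleus_radius_sd_um, size=n),
        3.0,
        model.nucleus_radius_um + 3 * model.nucleus_radius_sd_um,
    )
    cell_r = nuc_r * model.cell_radius_factor
    sigma = np.sqrt(np.log1p(model.cell_cv**2))
    cells = []
    for i in range(n):
        totals = {"nuclei": model.nucleus_total_au}
        z = rng.standard_normal(len(MARKERS))
        for j, m in enumerate(MARKERS):
            totals[m] = float(medians[m] * np.exp(sigma * z[j]))  # lognormal, median preserved
        cells.append(
            CellTruth(float(pts[i, 0]), float(pts[i, 1]), float(nuc_r[i]), float(cell_r[i]), totals)
        )
    return GroundTruthTile(
        col, row, tile_width_um, tile_height_um, dens, medians, tuple(cells)
    )


@dataclass(frozen=True)
class OpticsConfig:
    """Synthetic acquisition model (defaults ~10X widefield, 0.65 um/px camera)."""

    pixel_size_um: float = 0.65
    camera_offset: float = 100.0
    read_noise_sd: float = 2.0
    shot_noise: bool = True
    background: dict = field(
        default_factory=lambda: {"nuclei": 20.0, "asma": 60.0, "col1": 40.0}
    )
    bg_gradient_amplitude: float = 0.15
    psf_sigma_um: float = 1.0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be > 0")
        if self.read_noise_sd < 0 or self.psf_sigma_um < 0 or self.bg_gradient_amplitude < 0:
            raise ValueError("noise parameters must be >= 0")


def _stamp(img, x_px, y_px, radius_px, total_counts, profile):
    """Add a radial kernel of integrated mass *total_counts* centred at (x, y)."""
    h, w = img.shape
    r_ext = int(np.ceil(radius_px * 1.5)) + 1
    x0, x1 = int(np.floor(x_px)) - r_ext, int(np.floor(x_px)) + r_ext + 1
    y0, y1 = int(np.floor(y_px)) - r_ext, int(np.floor(y_px)) + r_ext + 1
    x0c, x1c, y0c, y1c = max(x0, 0), min(x1, w), max(y0, 0), min(y1, h)
    if x0c >= x1c or y0c >= y1c:
        return
    dx = np.arange(x0c, x1c, dtype=np.float32) + 0.5 - x_px
    dy = np.arange(y0c, y1c, dtype=np.float32) + 0.5 - y_px
    rr = np.sqrt(dx[None, :] ** 2 + dy[:, None] ** 2)
    k = profile(rr, radius_px)
    s = k.sum()
    if s <= 0:
        return
    img[y0c:y1c, x0c:x1c] += (total_counts / s) * k


def _gauss_profile(rr, radius_px):
    sig = radius_px / 2.0
    return np.exp(-0.5 * (rr / sig) ** 2)


def _soft_disk_profile(rr, radius_px):
    # half-maximum exactly at the planted radius
    edge = max(radius_px * 0.25, 1.0)
    return np.clip((radius_px - rr) / edge + 0.5, 0.0, 1.0)


def render_tile(
    gt: GroundTruthTile,
    optics: OpticsConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Render one tile as a ``(3, H, W)`` uint16 image.

    Nuclei are 2D Gaussian spots in channel 0; cell bodies are soft disks in
    channels 1-2 carrying each cell's planted total signal (mass-conserving,
    in counts = total_au / pixel_area so that downstream CTCF in a.u. is
    calibration-invariant).  Background + a smooth gradient + PSF blur +
    shot/read noise + camera offset are then applied and the result clipped
    to 16 bits.
    """
    px = optics.pixel_size_um
    px_area = px * px
    h = max(1, int(round(gt.tile_height_um / px)))
    w = max(1, int(round(gt.tile_width_um / px)))
    planes = {ch: np.zeros((h, w), dtype=np.float32) for ch in CHANNELS}
    for c in gt.cells:
        x_px, y_px = c.x_um / px, c.y_um / px
        _stamp(
            planes["nuclei"], x_px, y_px, c.nucleus_radius_um / px,
            c.totals["nuclei"] / px_area, _gauss_profile,
        )
        for m in MARKERS:
            _stamp(
                planes[m], x_px, y_px, c.cell_radius_um / px,
                c.totals[m] / px_area, _soft_disk_profile,
            )

    out = np.empty((len(CHANNELS), h, w), dtype=np.uint16)
    sigma_px = optics.psf_sigma_um / px
    # one smooth illumination gradient per tile, shared across channels
    gx, gy = rng.uniform(-1.0, 1.0, size=2)
    yy = np.linspace(-0.5, 0.5, h, dtype=np.float32)[:, None]
    xx = np.linspace(-0.5, 0.5, w, dtype=np.float32)[None, :]
    grad = gx * xx + gy * yy
    read_var = optics.read_noise_sd**2
    for i, ch in enumerate(CHANNELS):
        img = planes[ch]
        bg = optics.background.get(ch, 0.0)
        img = img + np.float32(bg) * (np.float32(1.0) + np.float32(optics.bg_gradient_amplitude) * grad)
        if sigma_px > 0:
            img = gaussian_filter(img, sigma_px, mode="reflect")
        lam = np.clip(img, 0.0, None)
        if optics.shot_noise:
            # Poisson shot noise; the bright regime (>= 50 photons) uses the
            # Gaussian approximation, folding the read noise into one draw
            img = rng.normal(lam, np.sqrt(lam + read_var)).astype(np.float32)
            small = lam < 12.0
            if small.any():
                img[small] = rng.poisson(lam[small]) + (
                    rng.normal(0.0, optics.read_noise_sd, int(small.sum()))
                    if optics.read_noise_sd > 0
                    else 0.0
                )
        elif optics.read_noise_sd > 0:
            img = lam + rng.normal(0.0, optics.read_noise_sd, size=lam.shape).astype(np.float32)
        else:
            img = lam
        img = img + np.float32(optics.camera_offset)
        out[i] = np.clip(np.round(img), 0, 65535).astype(np.uint16)
    return out


# ---------------------------------------------------------------------------
# Whole-screen drivers
# ---------------------------------------------------------------------------


def _tile_seed_seq(seed: int, dog: str, replicate: int, condition: Condition, col: int, row: int):
    """Deterministic per-tile seed derivation, independent of iteration order."""
    key = f"{dog}|{replicate}|{condition.key}|{col}|{row}"
    digest = np.frombuffer(key.encode(), dtype=np.uint8)
    return np.random.SeedSequence([seed, *digest.tolist()])


def iterate_screen(
    model: ResponseModel,
    layouts: dict[str, DOGLayout],
    seed: int,
    conditions: tuple[Condition, ...] = (Condition("7d", True),),
    replicates: dict[str, int] | int = 1,
    optics: OpticsConfig | None = None,
    tile_width_um: float = 1742.0,
    tile_height_um: float = 1298.0,
    render: bool = True,
):
    """Stream ``(meta, ground_truth, image)`` for every tile of a screen.

    ``meta`` is a dict with dog / replicate / condition / col / row / tile
    centre / planted parameters.  ``image`` is ``None`` when ``render`` is
    False.  Two RNG streams (population, optics) are split from the per-tile
    seed, so the same population can be re-rendered under different noise.
    """
    optics = optics or OpticsConfig()
    for dog, layout in layouts.items():
        grid = make_tile_grid(layout, tile_width_um, tile_height_um)
        for condition in conditions:
            n_rep = replicates if isinstance(replicates, int) else replicates.get(condition.key, 1)
            for rep in range(1, n_rep + 1):
                for col, row_i, x_mm, y_mm in grid.tiles():
                    p = map_position(layout, x_mm, y_mm)
                    ss = _tile_seed_seq(seed, dog, rep, condition, col, row_i)
                    pop_ss, opt_ss = ss.spawn(2)
                    gt = sample_cells(
                        model, p, condition, np.random.default_rng(pop_ss),
                        tile_width_um, tile_height_um, col, row_i,
                    )
                    img = render_tile(gt, optics, np.random.default_rng(opt_ss)) if render else None
                    meta = dict(
                        dog=dog, replicate=rep, condition=condition.key,
                        col=col, row=row_i, x_mm=x_mm, y_mm=y_mm,
                        wavelength_um=p.wavelength_um, stiffness_mpa=p.stiffness_mpa,
                        wca_deg=p.wca_deg,
                        tile_width_um=tile_width_um, tile_height_um=tile_height_um,
                    )
                    yield meta, gt, img


def _ground_truth_row(meta: dict, gt: GroundTruthTile) -> dict:
    row = dict(meta)
    row.update(
        n_cells=gt.n_cells,
        true_density=gt.true_density,
        true_median_ctcf_asma=gt.true_median_ctcf["asma"],
        true_median_ctcf_col1=gt.true_median_ctcf["col1"],
    )
    return row


def generate_screen(
    model: ResponseModel,
    layouts: dict[str, DOGLayout],
    out_dir,
    seed: int,
    conditions: tuple[Condition, ...] = (Condition("7d", True),),
    replicates: dict[str, int] | int | None = None,
    optics: OpticsConfig | None = None,
    tile_width_um: float = 1742.0,
    tile_height_um: float = 1298.0,
    overwrite: bool = False,
) -> pd.DataFrame:
    """Write a full synthetic screen to *out_dir* and return the manifest.

    One multi-channel TIFF per tile per DOG per replicate per condition, plus
    ``manifest.csv`` (dog, replicate, condition, col, row, path), and
    ``ground_truth.csv`` with planted parameters and responses per tile.
    """
    out_dir = str(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    manifest_path = os.path.join(out_dir, "manifest.csv")
    if os.path.exists(manifest_path) and not overwrite:
        raise FileExistsError(f"{manifest_path} exists; pass overwrite=True to replace it")
    if replicates is None:
        replicates = DEFAULT_REPLICATES
    manifest_rows, truth_rows = [], []
    for meta, gt, img in iterate_screen(
        model, layouts, seed, conditions, replicates, optics, tile_width_um, tile_height_um
    ):
        safe_dog = meta["dog"].replace("|", "x")
        fname = (
            f"{safe_dog}_{meta['condition']}_rep{meta['replicate']}_"
            f"c{meta['col']:02d}_r{meta['row']:02d}.tif"
        )
        path = os.path.join(out_dir, fname)
        tifffile.imwrite(path, img, photometric="minisblack")
        manifest_rows.append(
            dict(
                dog=meta["dog"], replicate=meta["replicate"], condition=meta["condition"],
                col=meta["col"], row=meta["row"], path=fname,
                tile_width_um=tile_width_um, tile_height_um=tile_height_um,
                pixel_size_um=(optics or OpticsConfig()).pixel_size_um,
            )
        )
        truth_rows.append(_ground_truth_row(meta, gt))
    manifest = pd.DataFrame(manifest_rows)
    manifest.to_csv(manifest_path, index=False)
    pd.DataFrame(truth_rows).to_csv(os.path.join(out_dir, "ground_truth.csv"), index=False)
    return manifest


def simulate_summary_table(
    model: ResponseModel,
    layouts: dict[str, DOGLayout],
    seed: int,
    conditions: tuple[Condition, ...] = (Condition("7d", True),),
    replicates: dict[str, int] | int = 1,
    tile_width_um: float = 1742.0,
    tile_height_um: float = 1298.0,
) -> pd.DataFrame:
    """Per-tile summaries computed from sampled ground truth, skipping imaging.

    Density is the realised count / area and marker medians are medians of the
    sampled per-cell totals, i.e. what a perfect segmentation would measure.
    Useful for model-level experiments (hit ranking, RF/PLS) at scale.
    """
    rows = []
    for meta, gt, _ in iterate_screen(
        model, layouts, seed, conditions, replicates, None, tile_width_um, tile_height_um,
        render=False,
    ):
        rec = dict(meta)
        rec["n_cells"] = gt.n_cells
        rec["density"] = gt.n_cells / gt.area_mm2
        for m in MARKERS:
            vals = [c.totals[m] for c in gt.cells]
            rec[f"median_ctcf_{m}"] = float(np.median(vals)) if vals else np.nan
        rec["true_density"] = gt.true_density
        rec["true_median_ctcf_asma"] = gt.true_median_ctcf["asma"]
        rec["true_median_ctcf_col1"] = gt.true_median_ctcf["col1"]
        rows.append(rec)
    return pd.DataFrame(rows)
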