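"""Surface-gradient calibration model for double-orthogonal gradient (DOG) samples.

A DOG sample is a 20x20 mm substrate carrying two physicochemical gradients at
90 degrees to each other -- wrinkled topography (T, wavelength in um), surface
stiffness (S, DMT modulus in MPa), and wettability (W, water contact angle in
degrees) -- with the remaining parameter held constant.  This module turns a
handful of calibration measurements per gradient axis into a continuous map
from any physical position on a sample to its ``(T, S, W)`` parameter triple,
and lays the imaging tile grid over the sample.

Conventions: the origin sits at the sample corner where all gradients are at
their "closed-mask" end; x increases rightward and y upward, in mm.  Tile
indices ``(col, row)`` run row-major from the origin and each tile is assigned
the parameters of its centre.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.interpolate import PchipInterpolator

__all__ = [
    "PARAMETER_KINDS",
    "PARAMETER_UNITS",
    "CalibrationTable",
    "DOGLayout",
    "ParameterPoint",
    "TileGrid",
    "interpolate_parameter",
    "map_position",
    "make_tile_grid",
    "default_calibrations",
    "default_layouts",
    "read_calibration_csv",
    "write_calibration_csv",
    "load_layouts",
    "dump_layouts",
]

PARAMETER_KINDS = (
    "topography_wavelength",
    "topography_amplitude",
    "stiffness",
    "wettability",
)

PARAMETER_UNITS = {
    "topography_wavelength": "um",
    "topography_amplitude": "um",
    "stiffness": "MPa",
    "wettability": "deg",
}

#: The three parameters modelled downstream; amplitude is carried but not modelled.
MODELLED_KINDS = ("topography_wavelength", "stiffness", "wettability")


class GradientConfigError(ValueError):
    """Raised for inconsistent calibration tables or layouts."""


@dataclass(frozen=True)
class CalibrationTable:
    """Position-indexed measurements of one surface parameter along a gradient axis.

    Parameters
    ----------
    parameter_kind
        One of :data:`PARAMETER_KINDS`.
    positions_mm, mean_values, sd_values, n_meas
        Per-knot measurement summaries; positions must be strictly increasing.
    axis_length_mm
        Extent of the gradient axis (default 20 mm).
    """

    parameter_kind: str
    positions_mm: np.ndarray
    mean_values: np.ndarray
    sd_values: np.ndarray
    n_meas: np.ndarray
    axis_length_mm: float = 20.0

    def __post_init__(self) -> None:
        for name in ("positions_mm", "mean_values", "sd_values", "n_meas"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.parameter_kind not in PARAMETER_KINDS:
            raise GradientConfigError(f"unknown parameter kind {self.parameter_kind!r}")
        if self.positions_mm.ndim != 1 or self.positions_mm.size < 2:
            raise GradientConfigError(
                f"{self.parameter_kind}: need >= 2 calibration points, "
                f"got {self.positions_mm.size}"
            )
        if not np.all(np.diff(self.positions_mm) > 0):
            raise GradientConfigError(f"{self.parameter_kind}: positions must be strictly increasing")
        if self.mean_values.shape != self.positions_mm.shape:
            raise GradientConfigError(f"{self.parameter_kind}: positions/values length mismatch")
        if np.any(self.sd_values < 0):
            raise GradientConfigError(f"{self.parameter_kind}: sd_value must be >= 0")
        if self.parameter_kind == "wettability" and (
            np.any(self.mean_values < 0) or np.any(self.mean_values > 180)
        ):
            raise GradientConfigError("wettability: contact angles must lie in [0, 180] deg")
        object.__setattr__(self, "_interp", PchipInterpolator(self.positions_mm, self.mean_values))

    @property
    def value_range(self) -> tuple[float, float]:
        """(min, max) over the calibration knots."""
        return float(self.mean_values.min()), float(self.mean_values.max())

    def __call__(self, position_mm):
        return interpolate_parameter(self, position_mm)


def interpolate_parameter(table: CalibrationTable, position_mm):
    """Evaluate the monotone piecewise-cubic interpolant of *table* at *position_mm*.

    A PCHIP (shape-preserving cubic) interpolant is used: it is exact at every
    calibration knot and monotone wherever the knots are, which matches the
    physics of the plasma-treatment gradients (no overshoot between sparse
    knots).  Positions outside the knot range are clamped to the end knots,
    because stitched-image edges can overhang the characterized region.
    """
    pos = np.clip(np.asarray(position_mm, dtype=float), table.positions_mm[0], table.positions_mm[-1])
    out = table._interp(pos)
    if np.isscalar(position_mm) or np.ndim(position_mm) == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class ParameterPoint:
    """A (topography, stiffness, wettability) triple at one physical position."""

    wavelength_um: float
    stiffness_mpa: float
    wca_deg: float
    amplitude_um: float | None = None

    def __post_init__(self) -> None:
        if self.wavelength_um < 0:
            raise ValueError("wavelength_um must be >= 0 (0 encodes flat)")
        if self.stiffness_mpa <= 0:
            raise ValueError("stiffness_mpa must be > 0")
        if not 0.0 <= self.wca_deg <= 180.0:
            raise ValueError("wca_deg must lie in [0, 180]")


_KIND_TO_FIELD = {
    "topography_wavelength": "wavelength_um",
    "topography_amplitude": "amplitude_um",
    "stiffness": "stiffness_mpa",
    "wettability": "wca_deg",
}


@dataclass(frozen=True)
class DOGLayout:
    """Geometry of one DOG sample: which parameter varies along each axis.

    One axis may carry two co-varying parameters (the S|W axis of the T-S|W
    sample, produced by a single plasma treatment that changes stiffness and
    wettability together).  Parameters on neither axis are constants in
    ``fixed_params``.
    """

    name: str
    x_axis: tuple[CalibrationTable, ...]
    y_axis: tuple[CalibrationTable, ...]
    fixed_params: dict[str, float] = field(default_factory=dict)
    extent_mm: tuple[float, float] = (20.0, 20.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "x_axis", tuple(self.x_axis))
        object.__setattr__(self, "y_axis", tuple(self.y_axis))
        seen: list[str] = [t.parameter_kind for t in self.x_axis + self.y_axis]
        seen += list(self.fixed_params)
        for kind in MODELLED_KINDS:
            if seen.count(kind) != 1:
                raise GradientConfigError(
                    f"layout {self.name!r}: parameter {kind!r} must appear exactly once "
                    f"across axes and fixed_params (found {seen.count(kind)})"
                )
        for kind in self.fixed_params:
            if kind not in PARAMETER_KINDS:
                raise GradientConfigError(f"layout {self.name!r}: unknown fixed parameter {kind!r}")

    def axis_tables(self) -> dict[str, tuple[str, CalibrationTable]]:
        """Map parameter kind -> (axis name, calibration table)."""
        out: dict[str, tuple[str, CalibrationTable]] = {}
        for t in self.x_axis:
            out[t.parameter_kind] = ("x", t)
        for t in self.y_axis:
            out[t.parameter_kind] = ("y", t)
        return out

    def parameter_range(self, kind: str) -> tuple[float, float]:
        """Range of *kind* over this layout (knot range, or the fixed value twice)."""
        tables = self.axis_tables()
        if kind in tables:
            return tables[kind][1].value_range
        if kind in self.fixed_params:
            v = float(self.fixed_params[kind])
            return (v, v)
        raise GradientConfigError(f"layout {self.name!r}: parameter {kind!r} not present")


def map_position(layout: DOGLayout, x_mm: float, y_mm: float) -> ParameterPoint:
    """Parameters presented by layout at physical position ``(x_mm, y_mm)``.

    Each parameter is filled from its axis interpolant (clamped at the knots)
    or from the layout's fixed value; deterministic and total over the extent.
    """
    values: dict[str, float] = {}
    for table in layout.x_axis:
        values[table.parameter_kind] = interpolate_parameter(table, x_mm)
    for table in layout.y_axis:
        values[table.parameter_kind] = interpolate_parameter(table, y_mm)
    for kind, v in layout.fixed_params.items():
        values[kind] = float(v)
    try:
        kwargs = {_KIND_TO_FIELD[k]: v for k, v in values.items()}
        return ParameterPoint(**kwargs)
    except TypeError as exc:  # pragma: no cover - guarded by layout invariant
        raise GradientConfigError(f"layout {layout.name!r}: incomplete parameter set") from exc


@dataclass(frozen=True)
class TileGrid:
    """Imaging tile grid laid over a sample, row-major from the origin corner."""

    tile_width_um: float = 1742.0
    tile_height_um: float = 1298.0
    n_cols: int = 11
    n_rows: int = 15

    def tile_center_mm(self, col: int, row: int) -> tuple[float, float]:
        return (
            (col + 0.5) * self.tile_width_um / 1000.0,
            (row + 0.5) * self.tile_height_um / 1000.0,
        )

    def tiles(self):
        """Yield ``(col, row, x_mm, y_mm)`` for every tile centre."""
        for row in range(self.n_rows):
            for col in range(self.n_cols):
                x, y = self.tile_center_mm(col, row)
                yield col, row, x, y

    @property
    def n_tiles(self) -> int:
        return self.n_cols * self.n_rows

    @property
    def tile_area_mm2(self) -> float:
        return self.tile_width_um * self.tile_height_um / 1e6


def make_tile_grid(
    layout: DOGLayout,
    tile_width_um: float = 1742.0,
    tile_height_um: float = 1298.0,
) -> TileGrid:
    """Tile the layout extent, keeping every tile whose centre lies inside it.

    A 20x20 mm sample with 1742x1298 um tiles yields an 11x15 grid.  A tile
    larger than the extent degenerates to a 1x1 grid.
    """
    if tile_width_um <= 0 or tile_height_um <= 0:
        raise ValueError("tile dimensions must be positive")
    ext_x_um = layout.extent_mm[0] * 1000.0
    ext_y_um = layout.extent_mm[1] * 1000.0
    # centre of tile i is (i + 0.5) * w; keep it iff it falls inside the extent
    n_cols = max(1, math.floor(ext_x_um / tile_width_um + 0.5))
    n_rows = max(1, math.floor(ext_y_um / tile_height_um + 0.5))
    return TileGrid(tile_width_um, tile_height_um, n_cols, n_rows)


# ---------------------------------------------------------------------------
# Default calibrations and layouts
#
# The profiles below are placeholders spanning the characterized ranges of the
# screening platform: wrinkle wavelength 0-10 um (11 AFM points), DMT modulus
# 15-120 MPa (5 nanomechanical-mapping points), water contact angle 110-20 deg
# (5 sessile-drop points).  The masked plasma-dose profile saturates at both
# ends of the mask, so the default profiles are gently sigmoidal in position.
# ---------------------------------------------------------------------------


def _sigmoid_profile(lo: float, hi: float, n: int, length: float, steep: float = 3.5):
    pos = np.linspace(0.0, length, n)
    z = (pos - length / 2.0) / (length / (2.0 * steep))
    f = 1.0 / (1.0 + np.exp(-z))
    f = (f - f[0]) / (f[-1] - f[0])
    return pos, lo + (hi - lo) * f


def default_calibrations(axis_length_mm: float = 20.0) -> dict[str, CalibrationTable]:
    """Built-in calibration tables for the four gradient axes."""
    tables: dict[str, CalibrationTable] = {}
    pos, wl = _sigmoid_profile(0.0, 10.0, 11, axis_length_mm, steep=2.5)
    tables["topography_wavelength"] = CalibrationTable(
        "topography_wavelength", pos, wl, 0.05 * np.maximum(wl, 0.2), np.full(11, 3), axis_length_mm
    )
    pos, amp = _sigmoid_profile(0.0, 1.5, 11, axis_length_mm, steep=2.5)
    tables["topography_amplitude"] = CalibrationTable(
        "topography_amplitude", pos, amp, 0.05 * np.maximum(amp, 0.05), np.full(11, 3), axis_length_mm
    )
    pos, s = _sigmoid_profile(15.0, 120.0, 5, axis_length_mm, steep=2.5)
    tables["stiffness"] = CalibrationTable(
        "stiffness", pos, s, 0.08 * s, np.full(5, 3), axis_length_mm
    )
    # the wettability dose-response of the masked plasma is sharper than the
    # stiffness one, so the two default profiles are deliberately distinct
    pos, w = _sigmoid_profile(110.0, 20.0, 5, axis_length_mm, steep=4.5)
    tables["wettability"] = CalibrationTable(
        "wettability", pos, w, np.full(5, 3.0), np.full(5, 3), axis_length_mm
    )
    return tables


#: Fixed-parameter defaults: T-S is fully oxidised (hydrophilic), T-W keeps the
#: base imprint stiffness, S-W is on flat PDMS.
DEFAULT_FIXED = {
    "T-S": {"wettability": 22.0},
    "T-W": {"stiffness": 15.0},
    "T-S|W": {},
    "S-W": {"topography_wavelength": 0.0, "topography_amplitude": 0.0},
}

DOG_NAMES = ("T-S", "T-W", "T-S|W", "S-W")


def default_layouts(axis_length_mm: float = 20.0) -> dict[str, DOGLayout]:
    """The four standard DOG layouts with the default calibrations."""
    cal = default_calibrations(axis_length_mm)
    topo = (cal["topography_wavelength"], cal["topography_amplitude"])
    ext = (axis_length_mm, axis_length_mm)
    return {
        "T-S": DOGLayout("T-S", topo, (cal["stiffness"],), dict(DEFAULT_FIXED["T-S"]), ext),
        "T-W": DOGLayout("T-W", topo, (cal["wettability"],), dict(DEFAULT_FIXED["T-W"]), ext),
        "T-S|W": DOGLayout(
            "T-S|W", topo, (cal["stiffness"], cal["wettability"]), dict(DEFAULT_FIXED["T-S|W"]), ext
        ),
        "S-W": DOGLayout(
            "S-W", (cal["stiffness"],), (cal["wettability"],), dict(DEFAULT_FIXED["S-W"]), ext
        ),
    }


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

_CAL_COLUMNS = ["parameter_kind", "position_mm", "mean_value", "sd_value", "n_meas"]


def read_calibration_csv(path, axis_length_mm: float = 20.0) -> dict[str, CalibrationTable]:
    """Read calibration tables from a long-format CSV.

    Expected columns: parameter_kind, position_mm, mean_value, sd_value, n_meas.
    """
    df = pd.read_csv(path)
    missing = [c for c in _CAL_COLUMNS if c not in df.columns]
    if missing:
        raise GradientConfigError(f"calibration CSV missing columns {missing}")
    out = {}
    for kind, grp in df.groupby("parameter_kind", sort=False):
        grp = grp.sort_values("position_mm")
        out[str(kind)] = CalibrationTable(
            str(kind),
            grp["position_mm"].to_numpy(),
            grp["mean_value"].to_numpy(),
            grp["sd_value"].to_numpy(),
            grp["n_meas"].to_numpy(),
            axis_length_mm,
        )
    return out


def write_calibration_csv(tables: dict[str, CalibrationTable], path) -> None:
    rows = []
    for kind, t in tables.items():
        for p, m, s, n in zip(t.positions_mm, t.mean_values, t.sd_values, t.n_meas):
            rows.append(dict(parameter_kind=kind, position_mm=p, mean_value=m, sd_value=s, n_meas=int(n)))
    pd.DataFrame(rows, columns=_CAL_COLUMNS).to_csv(path, index=False)


def load_layouts(path) -> dict[str, DOGLayout]:
    """Load DOG layouts from a YAML config.

    Schema::

        axis_length_mm: 20
        calibrations:             # optional; defaults used when omitted
          stiffness: {positions_mm: [...], mean_values: [...], sd_values: [...], n_meas: [...]}
        layouts:
          S-W:
            x: [stiffness]
            y: [wettability]
            fixed: {topography_wavelength: 0.0}
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    axis_length = float(cfg.get("axis_length_mm", 20.0))
    cal = default_calibrations(axis_length)
    for kind, entry in (cfg.get("calibrations") or {}).items():
        cal[kind] = CalibrationTable(
            kind,
            entry["positions_mm"],
            entry["mean_values"],
            entry.get("sd_values", np.zeros(len(entry["positions_mm"]))),
            entry.get("n_meas", np.ones(len(entry["positions_mm"]))),
            axis_length,
        )
    layouts = {}
    for name, entry in cfg["layouts"].items():
        layouts[name] = DOGLayout(
            name,
            tuple(cal[k] for k in entry.get("x", [])),
            tuple(cal[k] for k in entry.get("y", [])),
            {k: float(v) for k, v in (entry.get("fixed") or {}).items()},
            (axis_length, axis_length),
        )
    return layouts


def dump_layouts(layouts: dict[str, DOGLayout], path) -> None:
    """Write layouts (and their calibrations) to the YAML schema of :func:`load_layouts`."""
    cal: dict[str, CalibrationTable] = {}
    layouts_cfg = {}
    any_len = 20.0
    for name, lay in layouts.items():
        any_len = lay.extent_mm[0]
        for t in lay.x_axis + lay.y_axis:
            cal[t.parameter_kind] = t
        layouts_cfg[name] = {
            "x": [t.parameter_kind for t in lay.x_axis],
            "y": [t.parameter_kind for t in lay.y_axis],
            "fixed": {k: float(v) for k, v in lay.fixed_params.items()},
        }
    cfg = {
        "axis_length_mm": float(any_len),
        "calibrations": {
            k: {
                "positions_mm": t.positions_mm.tolist(),
                "mean_values": t.mean_values.tolist(),
                "sd_values": t.sd_values.tolist(),
                "n_meas": t.n_meas.astype(int).tolist(),
            }
            for k, t in cal.items()
        },
        "layouts": layouts_cfg,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
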