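"""Abiotic site covariates from a DEM: elevation, slope/aspect, heat load
index, and maximum terrain relief within a footprint.

The heat load index (HLI) summarises the thermal favourability of a
site's slope/aspect/latitude combination by folding aspect about the
northeast-southwest axis so that southwest-facing slopes (which receive
afternoon sun) score highest. The equation coefficients follow McCune &
Keon's published regressions and live in ``HLI_EQUATIONS`` with a citation
string rather than being buried in code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import Ellipse

__all__ = [
    "DemGrid",
    "SiteCovariates",
    "HLI_EQUATIONS",
    "slope_aspect",
    "heat_load_index",
    "footprint_relief",
    "elevation_at",
    "site_covariates",
]

#: McCune & Keon (2002, J. Veg. Sci. 13:603-606) regression coefficients,
#: keyed by trigonometric term (L latitude, S slope, A folded aspect, all
#: in radians). eq1/eq2 return exp(linear predictor); eq3 is a direct
#: (non-log) fit whose cos(A) term carries no sin(L) factor. eq1 is the
#: default (broadest slope/latitude applicability).
HLI_EQUATIONS = {
    "eq1": {
        "coefficients": {
            "intercept": -1.467,
            "cosL_cosS": 1.582,
            "cosA_sinS_sinL": -1.500,
            "sinL_sinS": -0.262,
            "sinA_sinS": 0.607,
        },
        "log_scale": True,
        "citation": "McCune & Keon 2002, J Veg Sci 13:603-606, eq. 1",
    },
    "eq2": {
        "coefficients": {
            "intercept": -1.236,
            "cosL_cosS": 1.350,
            "cosA_sinS_sinL": -1.376,
            "sinL_sinS": -0.331,
            "sinA_sinS": 0.375,
        },
        "log_scale": True,
        "citation": "McCune & Keon 2002, J Veg Sci 13:603-606, eq. 2",
    },
    "eq3": {
        "coefficients": {
            "intercept": 0.339,
            "cosL_cosS": 0.808,
            "sinL_sinS": -0.196,
            "cosA_sinS": -0.482,
        },
        "log_scale": False,
        "citation": "McCune & Keon 2002, J Veg Sci 13:603-606, eq. 3",
    },
}


@dataclass
class DemGrid:
    """Regular elevation grid; row 0 is the northernmost row.

    ``origin`` is the (x, y) of the grid's south-west corner.
    """

    origin: tuple[float, float]
    cell_size: float
    elevation: np.ndarray

    def __post_init__(self) -> None:
        self.elevation = np.asarray(self.elevation, dtype=float)
        if self.elevation.ndim != 2:
            raise ValueError("elevation must be a 2-D array")
        if not np.all(np.isfinite(self.elevation)):
            raise ValueError("elevations must be finite")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.elevation.shape

    def cell_center_coords(self):
        """x (per column) and y (per row, matching row order) centre coords."""
        nrows, ncols = self.shape
        xs = self.origin[0] + (np.arange(ncols) + 0.5) * self.cell_size
        ys = self.origin[1] + (nrows - np.arange(nrows) - 0.5) * self.cell_size
        return xs, ys

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        nrows, _ = self.shape
        col = int(math.floor((x - self.origin[0]) / self.cell_size))
        row_from_south = int(math.floor((y - self.origin[1]) / self.cell_size))
        row = nrows - 1 - row_from_south
        if not (0 <= row < nrows and 0 <= col < self.shape[1]):
            raise ValueError(f"point ({x}, {y}) outside DEM extent")
        return row, col


@dataclass
class SiteCovariates:
    elev: float
    hli: float
    slope_deg: float
    aspect_deg: float
    latitude_deg: float


def slope_aspect(dem: DemGrid, point: tuple[float, float]) -> tuple[float, float]:
    """Horn 3x3 finite-difference slope and aspect at ``point``.

    Aspect is the compass bearing, clockwise from north, toward which the
    terrain rises (the bearing of steepest ascent); a plane rising due
    south therefore has aspect 180. Flat cells return aspect 0.
    """
    row, col = dem.index_of(*point)
    nrows, ncols = dem.shape
    if not (1 <= row < nrows - 1 and 1 <= col < ncols - 1):
        raise ValueError("point lacks a full 3x3 DEM neighbourhood")
    z = dem.elevation[row - 1 : row + 2, col - 1 : col + 2]
    # Horn's weights; rows run north->south, columns west->east
    dz_dx = ((z[0, 2] + 2 * z[1, 2] + z[2, 2]) - (z[0, 0] + 2 * z[1, 0] + z[2, 0])) / (
        8 * dem.cell_size
    )
    dz_dy = ((z[0, 0] + 2 * z[0, 1] + z[0, 2]) - (z[2, 0] + 2 * z[2, 1] + z[2, 2])) / (
        8 * dem.cell_size
    )
    slope = math.degrees(math.atan(math.hypot(dz_dx, dz_dy)))
    if dz_dx == 0 and dz_dy == 0:
        aspect = 0.0
    else:
        aspect = math.degrees(math.atan2(dz_dx, dz_dy)) % 360.0
    return slope, aspect


def heat_load_index(
    slope_deg: float,
    aspect_deg: float,
    latitude_deg: float,
    equation: str = "eq1",
) -> float:
    """Heat load index from slope, aspect and latitude.

    Aspect is folded about the NE-SW axis, A_f = |180 - |aspect - 225||,
    which maps southwest to the fold maximum and northeast to the minimum,
    so at fixed slope and latitude HLI peaks on southwest aspects. At zero
    slope the aspect terms vanish.
    """
    if not 0.0 <= latitude_deg <= 60.0:
        raise ValueError("latitude must be within [0, 60] degrees")
    spec = HLI_EQUATIONS[equation]
    aspect_deg = aspect_deg % 360.0
    folded = abs(180.0 - abs(aspect_deg - 225.0))
    L = math.radians(latitude_deg)
    S = math.radians(slope_deg)
    A = math.radians(folded)
    terms = {
        "intercept": 1.0,
        "cosL_cosS": math.cos(L) * math.cos(S),
        "cosA_sinS_sinL": math.cos(A) * math.sin(S) * math.sin(L),
        "sinL_sinS": math.sin(L) * math.sin(S),
        "sinA_sinS": math.sin(A) * math.sin(S),
        "cosA_sinS": math.cos(A) * math.sin(S),
    }
    lin = sum(c * terms[name] for name, c in spec["coefficients"].items())
    return math.exp(lin) if spec["log_scale"] else lin


def footprint_relief(dem: DemGrid, ellipse: Ellipse) -> float:
    """Max minus min elevation over DEM cells whose centres fall inside."""
    xs, ys = dem.cell_center_coords()
    xx, yy = np.meshgrid(xs, ys)
    inside = ellipse.contains(xx, yy)
    if inside.sum() < 2:
        raise ValueError("footprint covers fewer than 2 DEM cell centres")
    vals = dem.elevation[inside]
    return float(vals.max() - vals.min())


def elevation_at(dem: DemGrid, x: float, y: float) -> float:
    """Bilinear interpolation of the DEM at a point."""
    nrows, ncols = dem.shape
    fx = (x - dem.origin[0]) / dem.cell_size - 0.5
    fy_south = (y - dem.origin[1]) / dem.cell_size - 0.5
    c0 = int(math.floor(fx))
    r0s = int(math.floor(fy_south))
    if not (0 <= c0 < ncols - 1 and 0 <= r0s < nrows - 1):
        raise ValueError(f"point ({x}, {y}) outside interpolable DEM extent")
    tx = fx - c0
    ty = fy_south - r0s
    # convert south-based rows to array rows (row 0 = north)
    r_lo = nrows - 1 - r0s
    r_hi = nrows - 1 - (r0s + 1)
    z00 = dem.elevation[r_lo, c0]
    z10 = dem.elevation[r_lo, c0 + 1]
    z01 = dem.elevation[r_hi, c0]
    z11 = dem.elevation[r_hi, c0 + 1]
    return float(
        z00 * (1 - tx) * (1 - ty)
        + z10 * tx * (1 - ty)
        + z01 * (1 - tx) * ty
        + z11 * tx * ty
    )


def site_covariates(
    dem: DemGrid,
    point: tuple[float, float],
    latitude_deg: float,
    equation: str = "eq1",
) -> SiteCovariates:
    """Elevation, slope/aspect, and HLI for one site centre."""
    slope, aspect = slope_aspect(dem, point)
    return SiteCovariates(
        elev=elevation_at(dem, *point),
        hli=heat_load_index(slope, aspect, latitude_deg, equation=equation),
        slope_deg=slope,
        aspect_deg=aspect,
        latitude_deg=latitude_deg,
    )
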