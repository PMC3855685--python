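"""Structural metrics from height-normalized discrete-return point clouds.

Metrics are computed per 20 m grid cell from points above a 1 m vegetation
cutoff, then aggregated within an elliptical footprint by replicating each
20 m cell to 1 m resolution and averaging the 1 m cells whose centres fall
inside the ellipse (matching how gridded metrics are extracted around a
survey site in practice).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .geometry import Ellipse
from .synthetic import PointCloud

__all__ = [
    "CloudMetrics",
    "MetricGrid",
    "cell_metrics",
    "grid_metrics",
    "mode_metrics",
    "extract_footprint",
    "METRIC_NAMES",
]

METRIC_NAMES = (
    "p_lower", "p_mid", "p_upper", "vdr", "density", "hmax", "hmedian", "hsd",
    "hmean", "crr", "hirq", "hmode", "hmrange", "hskew", "hkurt", "hvar",
    "hmad", "fhd",
)


@dataclass
class CloudMetrics:
    """Per-cell (or footprint-aggregated) point-cloud canopy metrics."""

    p_lower: float
    p_mid: float
    p_upper: float
    vdr: float
    density: float
    hmax: float
    hmedian: float
    hsd: float
    hmean: float
    crr: float
    hirq: float
    hmode: float
    hmrange: float
    hskew: float
    hkurt: float
    hvar: float
    hmad: float
    fhd: float
    n_points: int = 0
    n_veg: int = 0
    bare: bool = False

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in METRIC_NAMES], dtype=float)


def mode_metrics(heights: np.ndarray, bin_width: float = 1.0) -> tuple[float, float]:
    """Dominant-mode height and mode range from a 1 m binned count profile.

    Modes are strict local maxima of the count profile (a flat plateau
    counts once, at its lowest bin); hmode is the bin-centre height of the
    highest-count mode (count ties break toward the lower bin), hmrange the
    height difference between the highest- and lowest-elevation modes.
    """
    heights = np.asarray(heights, dtype=float)
    if heights.size == 0:
        raise ValueError("mode_metrics needs at least one height")
    top = int(math.floor(heights.max() / bin_width))
    counts = np.zeros(top + 1)
    idx = np.floor(heights / bin_width).astype(int)
    np.add.at(counts, idx, 1.0)

    padded = np.concatenate([[-np.inf], counts, [-np.inf]])
    modes = []
    b = 0
    nb = counts.size
    while b < nb:
        # extent of the plateau starting at b
        e = b
        while e + 1 < nb and counts[e + 1] == counts[b]:
            e += 1
        if counts[b] > 0 and padded[b] < counts[b] and padded[e + 2] < counts[b]:
            modes.append(b)
        b = e + 1
    if not modes:  # profile monotone: fall back to the maximum-count bin
        modes = [int(np.argmax(counts))]
    centers = (np.asarray(modes) + 0.5) * bin_width
    dominant = centers[int(np.argmax(counts[modes]))]
    return float(dominant), float(centers.max() - centers.min())


def cell_metrics(z: np.ndarray, veg_cutoff: float = 1.0) -> CloudMetrics:
    """Metrics for the points of one cell; vegetation = z > veg_cutoff.

    Stratum fractions use left-open/right-closed intervals (1, 3], (3, 10],
    (10, inf) consistent with the vegetation cutoff, and are fractions of
    all returns (so p_lower + p_mid + p_upper = density). Height statistics
    are over vegetation points only; crr = (mean - min)/(max - min);
    kurtosis is reported as excess kurtosis; fhd is the Shannon index of
    vegetation point counts in 1 m bins.
    """
    z = np.asarray(z, dtype=float)
    n = z.size
    if n == 0:
        raise ValueError("cell has no points")
    veg = z[z > veg_cutoff]
    nv = veg.size
    if nv == 0:
        zero = dict.fromkeys(METRIC_NAMES, 0.0)
        return CloudMetrics(**zero, n_points=n, n_veg=0, bare=True)

    p_lower = float(((z > veg_cutoff) & (z <= 3.0)).sum() / n)
    p_mid = float(((z > 3.0) & (z <= 10.0)).sum() / n)
    p_upper = float((z > 10.0).sum() / n)
    density = nv / n

    hmax = float(veg.max())
    hmin = float(veg.min())
    hmean = float(veg.mean())
    hmedian = float(np.median(veg))
    hsd = float(veg.std(ddof=1)) if nv > 1 else 0.0
    hvar = hsd**2
    hmad = float(np.median(np.abs(veg - hmedian)))
    hirq = float(np.subtract(*np.percentile(veg, [75, 25])))
    if hsd == 0.0:  # constant heights: moments degenerate
        hskew = hkurt = 0.0
    else:
        hskew = float(stats.skew(veg)) if nv > 2 else 0.0
        hkurt = float(stats.kurtosis(veg, fisher=True)) if nv > 3 else 0.0
    crr = (hmean - hmin) / (hmax - hmin) if hmax > hmin else 0.5
    vdr = (hmax - hmedian) / hmax if hmax > 0 else 0.0

    counts = np.bincount(np.floor(veg).astype(int))
    q = counts[counts > 0] / nv
    fhd = float(-np.sum(q * np.log(q)))
    hmode, hmrange = mode_metrics(veg)

    return CloudMetrics(
        p_lower=p_lower, p_mid=p_mid, p_upper=p_upper, vdr=vdr, density=density,
        hmax=hmax, hmedian=hmedian, hsd=hsd, hmean=hmean, crr=crr, hirq=hirq,
        hmode=hmode, hmrange=hmrange, hskew=hskew, hkurt=hkurt, hvar=hvar,
        hmad=hmad, fhd=fhd, n_points=n, n_veg=nv, bare=False,
    )


@dataclass
class MetricGrid:
    """Per-cell metrics on a regular grid aligned to ``origin``.

    ``cells`` maps (row, col) -> CloudMetrics with row/col counted from the
    grid origin (south-west corner), i.e. row increases northward.
    """

    origin: tuple[float, float]
    cell_size: float
    cells: dict[tuple[int, int], CloudMetrics]


def grid_metrics(
    pc: PointCloud, cell: float = 20.0, veg_cutoff: float = 1.0,
    origin: tuple[float, float] | None = None,
) -> MetricGrid:
    """Compute CloudMetrics in ``cell`` m grid cells over the cloud extent.

    The grid is aligned to ``origin`` (default: multiples of the cell size
    covering the cloud, so grids over translated copies of a cloud line up
    when the translation is a multiple of the cell size).
    """
    if len(pc) == 0:
        raise ValueError("empty point cloud")
    if origin is None:
        origin = (
            math.floor(pc.x.min() / cell) * cell,
            math.floor(pc.y.min() / cell) * cell,
        )
    col = np.floor((pc.x - origin[0]) / cell).astype(int)
    row = np.floor((pc.y - origin[1]) / cell).astype(int)
    cells: dict[tuple[int, int], CloudMetrics] = {}
    order = np.lexsort((col, row))
    keys = np.stack([row[order], col[order]], axis=1)
    boundaries = np.nonzero(np.any(np.diff(keys, axis=0) != 0, axis=1))[0] + 1
    for chunk in np.split(order, boundaries):
        r, c = int(row[chunk[0]]), int(col[chunk[0]])
        cells[(r, c)] = cell_metrics(pc.z_agl[chunk], veg_cutoff=veg_cutoff)
    return MetricGrid(origin=origin, cell_size=cell, cells=cells)


def extract_footprint(
    grid: MetricGrid, ellipse: Ellipse, fine: float = 1.0,
) -> CloudMetrics:
    """Average grid metrics over an elliptical footprint.

    Each coarse cell is notionally replicated to ``fine`` (1 m) resolution;
    the mean is over fine cells whose centres fall inside the ellipse.
    Cells without data (no points) are skipped.
    """
    ox, oy = grid.origin
    pad = ellipse.semimajor
    xs = np.arange(
        math.floor((ellipse.center_x - pad - ox) / fine) * fine + ox + fine / 2,
        ellipse.center_x + pad + fine, fine,
    )
    ys = np.arange(
        math.floor((ellipse.center_y - pad - oy) / fine) * fine + oy + fine / 2,
        ellipse.center_y + pad + fine, fine,
    )
    xx, yy = np.meshgrid(xs, ys)
    inside = ellipse.contains(xx, yy)
    if not np.any(inside):
        raise ValueError("footprint contains no fine-grid cell centres")

    rows = np.floor((yy[inside] - oy) / grid.cell_size).astype(int)
    cols = np.floor((xx[inside] - ox) / grid.cell_size).astype(int)
    acc = np.zeros(len(METRIC_NAMES))
    count = 0
    n_points = n_veg = 0
    for r, c in zip(rows, cols):
        cm = grid.cells.get((int(r), int(c)))
        if cm is None:
            continue
        acc += cm.as_vector()
        n_points += cm.n_points
        n_veg += cm.n_veg
        count += 1
    if count == 0:
        raise ValueError("footprint overlaps no computed grid cells")
    mean = acc / count
    vals = dict(zip(METRIC_NAMES, mean))
    return CloudMetrics(**vals, n_points=n_points, n_veg=n_veg, bare=n_veg == 0)
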