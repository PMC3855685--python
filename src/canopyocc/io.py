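"""File formats and run configuration.

All tabular formats are comma-separated UTF-8 with '.' decimals and empty
fields for missing values; every writer emits a header and every reader
validates it. Formats:

* waveform ASCII — blocks introduced by a metadata header line
  ``#site_id,center_x,center_y,semimajor_m,eccentricity,azimuth_deg``
  followed by ``height_m,amplitude`` rows at uniform spacing;
* point clouds — XYZ CSV with columns x,y,z_agl;
* DEM — ESRI ASCII grid (ncols/nrows/xllcorner/yllcorner/cellsize header);
* detection histories — one row per site: site_id, y1..yJ, then per-visit
  covariate columns named ``<cov>_<visit>``; missing visits are blank;
* model tables — model, coefficient columns, df, logLik, AICc, delta,
  weight (the layout of the packaged reference tables).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geometry import Ellipse
from .synthetic import PointCloud
from .terrain import DemGrid
from .waveform import Waveform

log = logging.getLogger("canopyocc")

__all__ = [
    "RunConfig",
    "load_config",
    "read_waveform_file",
    "write_waveform_file",
    "read_point_cloud",
    "write_point_cloud",
    "read_esri_ascii",
    "write_esri_ascii",
    "read_detection_csv",
    "write_detection_csv",
    "write_model_table",
    "read_model_table",
    "write_run_report",
]


@dataclass
class RunConfig:
    """Effective pipeline configuration; every field is echoed into the
    run report so a run is reproducible from its report alone."""

    noise_multiplier: float = 4.0
    filter_sigma_m: float = 0.60
    filter_width_is_fwhm: bool = False
    max_peaks: int = 6
    delta_max: float = 6.0
    veg_cutoff_m: float = 1.0
    cell_size_m: float = 20.0
    averaging_mode: str = "conditional"
    hli_equation: str = "eq1"
    ci_threshold: float = 30.0
    vdp_threshold: float = 0.5
    n_sites: int = 80
    n_visits: int = 2
    seed: int = 0

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path) -> RunConfig:
    """Read a YAML config; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


# ---------------------------------------------------------------------------
# waveform ASCII

_WF_HEADER = "#site_id,center_x,center_y,semimajor_m,eccentricity,azimuth_deg"


def write_waveform_file(path, waveforms: list[Waveform]) -> None:
    lines = []
    for w in waveforms:
        e = w.ellipse
        lines.append(
            f"#{w.site_id},{e.center_x!r},{e.center_y!r},{e.semimajor!r},"
            f"{e.eccentricity!r},{e.azimuth_deg!r}"
        )
        lines.append("height_m,amplitude")
        for h, a in zip(w.bin_heights, w.amplitudes):
            lines.append(f"{float(h)!r},{float(a)!r}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_waveform_file(path) -> list[Waveform]:
    """Parse a waveform ASCII file; malformed rows report line numbers."""
    text = Path(path).read_text(encoding="utf-8")
    waveforms: list[Waveform] = []
    meta = None
    heights: list[float] = []
    amps: list[float] = []
    start_line = 0

    def flush(line_no):
        nonlocal meta, heights, amps
        if meta is None:
            return
        if len(heights) < 2:
            raise ValueError(
                f"{path}: waveform block starting at line {start_line} has "
                f"fewer than 2 bins"
            )
        h = np.asarray(heights)
        d = np.diff(h)
        if not np.allclose(d, d[0], rtol=0, atol=1e-6):
            bad = int(np.argmax(~np.isclose(d, d[0], rtol=0, atol=1e-6)))
            raise ValueError(
                f"{path}: non-uniform bin spacing first at line "
                f"{start_line + 2 + bad + 1}"
            )
        site_id, cx, cy, a, e, az = meta
        waveforms.append(
            Waveform(
                bin_heights=h,
                amplitudes=np.asarray(amps),
                ellipse=Ellipse(float(cx), float(cy), float(a), float(e), float(az)),
                site_id=site_id,
            )
        )
        meta, heights, amps = None, [], []

    for i, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            flush(i)
            parts = line[1:].split(",")
            if len(parts) != 6:
                raise ValueError(
                    f"{path}: line {i}: metadata header needs 6 fields "
                    f"({_WF_HEADER})"
                )
            meta = parts
            start_line = i
            continue
        if line == "height_m,amplitude":
            continue
        if meta is None:
            raise ValueError(f"{path}: line {i}: data row before any header")
        parts = line.split(",")
        if len(parts) != 2:
            raise ValueError(f"{path}: line {i}: expected 'height_m,amplitude'")
        try:
            heights.append(float(parts[0]))
            amps.append(float(parts[1]))
        except ValueError:
            raise ValueError(f"{path}: line {i}: non-numeric row {line!r}") from None
    flush(None)
    if not waveforms:
        log.warning("%s: no waveforms found", path)
    return waveforms


# ---------------------------------------------------------------------------
# point clouds / DEM

def write_point_cloud(path, pc: PointCloud) -> None:
    pd.DataFrame({"x": pc.x, "y": pc.y, "z_agl": pc.z_agl}).to_csv(path, index=False)


def read_point_cloud(path) -> PointCloud:
    df = pd.read_csv(path)
    required = ["x", "y", "z_agl"]
    if list(df.columns[:3]) != required:
        raise ValueError(f"{path}: expected columns {required}, got {list(df.columns)}")
    return PointCloud(x=df["x"].to_numpy(), y=df["y"].to_numpy(),
                      z_agl=df["z_agl"].to_numpy())


def write_esri_ascii(path, dem: DemGrid, nodata: float = -9999.0) -> None:
    nrows, ncols = dem.shape
    header = (
        f"ncols {ncols}\nnrows {nrows}\n"
        f"xllcorner {dem.origin[0]!r}\nyllcorner {dem.origin[1]!r}\n"
        f"cellsize {dem.cell_size!r}\nNODATA_value {nodata!r}\n"
    )
    body = "\n".join(" ".join(repr(float(v)) for v in row) for row in dem.elevation)
    Path(path).write_text(header + body + "\n", encoding="utf-8")


def read_esri_ascii(path) -> DemGrid:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    header: dict[str, float] = {}
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
        ):
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: missing ESRI ASCII header field {key!r}")
    data = np.loadtxt(lines[i:], dtype=float)
    data = np.atleast_2d(data)
    if data.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(
            f"{path}: grid shape {data.shape} does not match header "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )
    if "nodata_value" in header:
        data = np.where(data == header["nodata_value"], np.nan, data)
        if np.isnan(data).any():
            raise ValueError(f"{path}: NODATA cells are not supported")
    return DemGrid(
        origin=(header["xllcorner"], header["yllcorner"]),
        cell_size=header["cellsize"],
        elevation=data,
    )


# ---------------------------------------------------------------------------
# detection histories

def write_detection_csv(path, data) -> None:
    n, J = data.y.shape
    out = {"site_id": data.site_ids or [f"s{i:03d}" for i in range(n)]}
    for j in range(J):
        col = data.y[:, j]
        out[f"y{j + 1}"] = ["" if np.isnan(v) else int(v) for v in col]
    for name, arr in data.visit_covariates.items():
        for j in range(J):
            out[f"{name}_{j + 1}"] = arr[:, j]
    df = pd.DataFrame(out)
    df = pd.concat([df, data.site_covariates.reset_index(drop=True)], axis=1)
    df.to_csv(path, index=False)


def read_detection_csv(path):
    from .occupancy import DetectionData

    df = pd.read_csv(path)
    if "site_id" not in df.columns:
        raise ValueError(f"{path}: missing 'site_id' column")
    ycols = sorted(
        (c for c in df.columns if c.startswith("y") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    if not ycols:
        raise ValueError(f"{path}: no y1..yJ detection columns found")
    J = len(ycols)
    y = df[ycols].to_numpy(dtype=float)
    visit: dict[str, np.ndarray] = {}
    site_cols = []
    for c in df.columns:
        if c == "site_id" or c in ycols:
            continue
        stem, _, idx = c.rpartition("_")
        if stem and idx.isdigit() and 1 <= int(idx) <= J:
            visit.setdefault(stem, {})[int(idx)] = df[c].to_numpy(dtype=float)
        else:
            site_cols.append(c)
    visit_covs = {}
    for name, cols in visit.items():
        if sorted(cols) != list(range(1, J + 1)):
            raise ValueError(f"{path}: visit covariate {name!r} missing visits")
        visit_covs[name] = np.column_stack([cols[j] for j in range(1, J + 1)])
    return DetectionData(
        y=y,
        site_covariates=df[site_cols].astype(float),
        visit_covariates=visit_covs,
        site_ids=df["site_id"].astype(str).tolist(),
    )


# ---------------------------------------------------------------------------
# model tables / run report

_MODEL_TABLE_FIXED = ("model", "df", "logLik", "AICc", "delta", "weight")


def write_model_table(path, mset) -> None:
    mset.table.to_csv(path, index=False)


def read_model_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("model", "AICc") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: model table missing columns {missing}")
    df["model"] = df["model"].astype(str)
    return df


def write_run_report(path, config: RunConfig, sections: dict) -> None:
    """Provenance report: package versions, full effective config, and
    per-stage counts/summaries."""
    import canopyocc

    lines = ["# canopyocc run report", ""]
    lines.append(f"canopyocc version: {canopyocc.__version__}")
    lines.append(f"numpy version: {np.__version__}")
    lines.append(f"pandas version: {pd.__version__}")
    lines += ["", "## configuration (effective, defaults included)", ""]
    for k, v in config.as_dict().items():
        lines.append(f"{k} = {v}")
    for title, content in sections.items():
        lines += ["", f"## {title}", ""]
        if isinstance(content, dict):
            lines += [f"{k} = {v}" for k, v in content.items()]
        else:
            lines.append(str(content))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
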