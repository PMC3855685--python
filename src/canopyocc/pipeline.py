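"""End-to-end synthetic study: terrain -> canopies -> LiDAR -> metrics ->
occupancy modelling -> selection/averaging -> cross-validation.

The pipeline emulates the design of a two-platform LiDAR occupancy study:
survey sites on a regular grid (>= 340 m spacing) over synthetic montane
terrain, one large-footprint waveform and one ~12 pt/m^2 point cloud per
site, canopy metrics extracted per footprint, detection histories drawn
from a logit-linear occupancy/detection truth on the standardized measured
covariates, then the full inferential chain with known ground truth.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from . import selection, terrain, validation
from . import waveform as wf
from .geometry import Ellipse
from .occupancy import DetectionData, ModelSpec, fit, standardize_covariates
from .synthetic import (
    SimConfig,
    TerrainSpec,
    TruthRecord,
    make_random_dem,
    sample_canopy_specs,
    simulate_detection_data,
    simulate_point_cloud,
    simulate_waveform,
)
from .pointcloud import extract_footprint, grid_metrics

log = logging.getLogger("canopyocc")

#: site covariates entering the candidate models (point-cloud and terrain
#: derived, mirroring a typical airborne-LiDAR covariate set)
MODEL_COVARIATES = ["elev", "hli", "fhd", "p_mid", "hmrange"]

#: true standardized-scale coefficients used by the synthetic study:
#: (intercept, elev, hli, fhd, p_mid, hmrange) for occupancy and
#: (intercept, julian_day, wind, sky) for detection. Moderate effects and
#: a ~0.45 baseline occupancy / ~0.65 per-visit detection.
TRUE_BETA_PSI = np.array([-0.2, 0.3, 0.25, 0.9, -0.4, 0.6])
TRUE_BETA_P = np.array([0.6, 0.0, -0.35, 0.0])

SITE_SPACING_M = 340.0


@dataclass
class PipelineResult:
    config: cio.RunConfig
    site_table: pd.DataFrame  # raw measured covariates + waveform metrics
    data: DetectionData  # standardized covariates
    truth: TruthRecord
    retained_covariates: list[str]
    belsley: list
    model_set: selection.ModelSet
    averaged: selection.AveragedEstimates
    rvi: pd.Series
    diagnostics: selection.FitDiagnostics
    global_fit: object
    roc: validation.LoocvReport


def _site_layout(n_sites: int):
    """Site centres on a square grid at the survey spacing."""
    side = int(math.ceil(math.sqrt(n_sites)))
    margin = 2.0 * SITE_SPACING_M
    pts = [
        (margin + c * SITE_SPACING_M, margin + r * SITE_SPACING_M)
        for r in range(side)
        for c in range(side)
    ]
    return pts[:n_sites], margin + (side - 1) * SITE_SPACING_M + margin


def run_pipeline(config: cio.RunConfig, out_dir=None) -> PipelineResult:
    """Run the full synthetic study under ``config``; optionally write all
    stage outputs and a provenance report under ``out_dir``."""
    rng_root = np.random.SeedSequence(config.seed)
    site_seeds = rng_root.spawn(config.n_sites)
    n = config.n_sites

    centers, extent = _site_layout(n)
    ncells = int(math.ceil(extent / 10.0)) + 4
    dem = make_random_dem(shape=(ncells, ncells), cell_size=10.0,
                          seed=config.seed + 1_000_003)

    specs = sample_canopy_specs(n, seed=config.seed + 7)
    rows = []
    waveforms = []
    latitude = 46.5
    for i, (spec, (cx, cy)) in enumerate(zip(specs, centers)):
        seed_i = int(site_seeds[i].generate_state(1)[0] % (2**31))
        slope, aspect = terrain.slope_aspect(dem, (cx, cy))
        footprint = Ellipse(cx, cy, 32.0, 0.45, float(aspect))
        cfg = SimConfig(
            noise_sd=0.2,
            noise_mean=0.5,
            footprint=footprint,
            terrain=TerrainSpec(slope_deg=slope, aspect_deg=aspect,
                                latitude_deg=latitude),
            seed=seed_i,
        )
        relief = terrain.footprint_relief(dem, footprint)

        w_raw = simulate_waveform(spec, cfg, site_id=f"s{i:03d}")
        waveforms.append(w_raw)
        w = wf.denoise(w_raw, k=config.noise_multiplier)
        w = wf.smooth(w, sigma_m=config.filter_sigma_m,
                      as_fwhm=config.filter_width_is_fwhm)
        peaks = wf.decompose(w, max_peaks=config.max_peaks)
        ground = wf.identify_ground(peaks)
        wm = wf.waveform_metrics(w, peaks, ground, relief=relief)

        pc = simulate_point_cloud(spec, cfg)
        grid = grid_metrics(pc, cell=config.cell_size_m,
                            veg_cutoff=config.veg_cutoff_m)
        cm = extract_footprint(grid, footprint)

        sc = terrain.site_covariates(dem, (cx, cy), latitude,
                                     equation=config.hli_equation)
        row = {
            "site_id": f"s{i:03d}", "x": cx, "y": cy,
            "elev": sc.elev, "hli": sc.hli, "slope_deg": slope,
            "relief": relief,
        }
        row.update({k: v for k, v in cm.as_dict().items()
                    if k not in ("n_points", "n_veg", "bare")})
        row.update({f"wf_{k}": v for k, v in wm.as_dict().items()})
        rows.append(row)
    site_table = pd.DataFrame(rows)

    # collinearity screen over the standardized candidate covariates
    # (screening raw columns would mostly flag shared location/scale)
    X = site_table[MODEL_COVARIATES].astype(float)
    X_std, _, _ = standardize_covariates(X)
    retained, belsley_diag = selection.belsley_screen(
        X_std, ci_threshold=config.ci_threshold, vdp_threshold=config.vdp_threshold
    )
    if retained != MODEL_COVARIATES:
        log.info("collinearity screen dropped %s",
                 sorted(set(MODEL_COVARIATES) - set(retained)))
    data, truth = simulate_detection_data(
        X_std, TRUE_BETA_PSI, TRUE_BETA_P,
        n_visits=config.n_visits, seed=config.seed + 11,
    )
    data.site_ids = site_table["site_id"].tolist()
    data.site_covariates = data.site_covariates[
        [c for c in data.site_covariates.columns if c in retained]
    ]

    # all-subsets candidate fits (wind is the candidate detection covariate)
    specs_all = selection.enumerate_models(retained, ["wind"])
    fits = selection.fit_candidates(specs_all, data, seed=config.seed)
    mset = selection.rank_and_weight(fits, delta_max=config.delta_max)
    averaged = selection.model_average(mset, mode=config.averaging_mode)
    importance = selection.rvi(mset)

    global_spec = ModelSpec(psi_terms=tuple(retained), p_terms=("wind",))
    global_fit = fit(global_spec, data, seed=config.seed)
    diagnostics = selection.overdispersion(global_fit, data)

    top_spec = next(
        m.spec for m in (mset.fits or fits)
        if m.spec.name == mset.table.iloc[0]["model"]
    )
    roc = validation.loocv_auc(top_spec, data, seed=config.seed)

    result = PipelineResult(
        config=config, site_table=site_table, data=data, truth=truth,
        retained_covariates=retained, belsley=belsley_diag, model_set=mset,
        averaged=averaged, rvi=importance, diagnostics=diagnostics,
        global_fit=global_fit, roc=roc,
    )
    if out_dir is not None:
        _write_outputs(result, waveforms, dem, Path(out_dir))
    return result


def _write_outputs(res: PipelineResult, waveforms, dem, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    cio.write_waveform_file(out / "waveforms.txt", waveforms)
    cio.write_esri_ascii(out / "dem.asc", dem)
    res.site_table.to_csv(out / "site_metrics.csv", index=False)
    cio.write_detection_csv(out / "detections.csv", res.data)
    cio.write_model_table(out / "model_table.csv", res.model_set)
    res.averaged.estimates.to_csv(out / "model_averaged.csv")
    res.rvi.to_frame().to_csv(out / "rvi.csv")
    d, r = res.diagnostics, res.roc
    cio.write_run_report(
        out / "run_report.txt",
        res.config,
        {
            "stage counts": {
                "sites": len(res.site_table),
                "waveforms": len(waveforms),
                "candidate models": len(res.model_set.table),
                "retained models": int(res.model_set.table["retained"].sum()),
                "loocv refit failures": r.n_failed_refits,
            },
            "screening": {
                "retained covariates": ", ".join(res.retained_covariates),
            },
            "fit diagnostics": {
                "deviance": round(d.deviance, 2), "rdof": d.rdof,
                "c_hat": round(d.c_hat, 3), "assessment": d.assessment,
                "saturated model": d.saturated_definition,
            },
            "validation": {
                "apparent AUC": round(r.apparent.auc, 3),
                "loocv AUC": round(r.loocv.auc, 3),
                "cutoff": round(r.apparent.cutoff, 3),
            },
            "truth": {
                "true occupancy rate": round(float(res.truth.z.mean()), 3),
                "naive occupancy": round(res.data.naive_occupancy, 3),
            },
        },
    )
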