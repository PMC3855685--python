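# canopyocc

Canopy vertical-structure metrics from LiDAR, and single-season occupancy
modelling of forest birds with imperfect detection.

`canopyocc` is aimed at quantitative ecologists who relate remotely sensed
forest structure to where a species breeds. It implements the full chain
used in landscape-scale woodpecker habitat studies that combine
large-footprint satellite waveform LiDAR with small-footprint airborne
discrete-return LiDAR:

* **Waveform processing** — noise estimation from the leading/trailing
  bins, denoising at `noise_mean + 4·noise_sd`, Gaussian smoothing (60 cm),
  decomposition into at most six Gaussian components, ground identification
  (the larger-amplitude of the two lowest components), and canopy metrics:
  stratum energy fractions (p.lower in 0–3 m, p.mid in 3–10 m), vegetation
  density, terrain-relief-corrected canopy height, height of median energy
  (HOME), foliage height diversity FHD = −Σ q_b ln q_b over 1 m bins,
  vertical distribution ratio VDR = (can.height − HOME)/can.height, and
  energy-weighted height moments.
* **Point-cloud metrics** — per 20 m cell from height-normalized clouds
  (vegetation = returns above 1 m): height order/moment statistics, canopy
  relief ratio (mean − min)/(max − min), dominant-mode height and mode
  range, FHD; aggregated over ~65 m elliptical footprints at 1 m
  resolution.
* **Terrain covariates** — Horn slope/aspect, McCune–Keon heat load index
  (aspect folded about the NE–SW axis), elevation, and maximum terrain
  relief within a footprint, from an ESRI ASCII DEM.
* **Occupancy model** — the zero-inflated detection-history likelihood
  L_i = ψ_i Π_j p_ij^y_ij (1−p_ij)^(1−y_ij) + (1−ψ_i)·I(Σ_j y_ij = 0),
  with logit links on site (ψ) and visit (p) covariates, quasi-Newton
  maximisation with analytic gradients, Wald standard errors from the
  observed information, and AICc = −2logL + 2K + 2K(K+1)/(n−K−1).
* **Model selection** — Belsley condition-index/VDP collinearity
  screening, all-subsets enumeration (detection-only models excluded),
  ΔAICc ≤ 6 candidate sets with renormalized Akaike weights, full and
  conditional model averaging with unconditional standard errors, relative
  variable importance (RVI), and an overdispersion check
  ĉ = deviance/(n − p).
* **Validation** — k-means (k = 2) probability cutoffs, rank-based AUC,
  and leave-one-out cross-validation.
* **Synthetic data** — multi-stratum conifer canopies generating
  waveforms (Gaussian components + noise, 0.15 m bins, ~64 m elliptical
  footprints, terrain-slope broadening), ~12 pt/m² point clouds, synthetic
  terrain, and two-visit detection histories with known ground truth, so
  every stage is testable without field data.

## Worked example

Run the full synthetic study (80 sites, two visits, all-subsets selection
over five screened covariates plus a wind detection covariate):

```bash
canopyocc --seed 1 --out-dir demo run-all
```

prints

```
80 sites; top model psi(elev+hli+fhd+p_mid) p(1); LOOCV AUC=0.722; c_hat=1.20; outputs in demo
```

meaning: of the 63 candidate models the AICc-best combines elevation, heat
load, foliage height diversity and mid-storey density; the model predicts
held-out breeding sites clearly better than chance (AUC 0.72); and the
global model shows no overdispersion (ĉ ≈ 1, so the AICc framework is
adequate without quasi-likelihood correction). `demo/` contains the
waveform file, DEM, site metrics, detection histories, the ranked model
table with deltas and weights, model-averaged coefficients, RVI, and a
provenance report echoing the full configuration.

The same machinery recomputes a published candidate-set table shipped with
the package:

```python
from canopyocc.reference import load_reference_table
from canopyocc.selection import rank_and_weight, model_average, rvi

table, n_sites = load_reference_table("airborne")
ms = rank_and_weight(table, delta_max=6.0)
print(round(ms.table.iloc[0]["weight"], 3))   # 0.443
print(round(rvi(ms)["fhd"], 2))               # 0.95
print(round(model_average(ms, "conditional")["elev"], 1))  # 69.6
```

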