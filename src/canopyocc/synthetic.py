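"""Synthetic canopies, waveforms, point clouds, terrain, and surveys.

The generator emulates the data a combined satellite-waveform / airborne
discrete-return LiDAR occupancy study would collect over mixed-conifer
forest: multi-stratum canopies (shrub layer + one or more tree strata +
ground) produce (a) large-footprint waveforms as sums of Gaussian energy
components with additive detector noise, and (b) small-footprint point
clouds at ~12 points m^-2; two-visit detection histories are drawn from a
logit-linear occupancy/detection model with Julian-day and weather
covariates. Every simulator is deterministic given its seed, and the truth
(stratum energies, occupancy states, coefficients) is returned so that
downstream estimators can be checked against it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .geometry import Ellipse
from .waveform import Waveform

__all__ = [
    "TOTAL_ENERGY",
    "Stratum",
    "CanopySpec",
    "TerrainSpec",
    "SimConfig",
    "PointCloud",
    "TruthRecord",
    "simulate_waveform",
    "simulate_point_cloud",
    "simulate_detection_data",
    "make_plane_dem",
    "sample_canopy_specs",
]

#: total pre-noise waveform energy (arbitrary amplitude units x metres)
TOTAL_ENERGY = 100.0


@dataclass(frozen=True)
class Stratum:
    """One vegetation layer: Gaussian energy component in height."""

    center: float  # m above ground
    width_sd: float  # m
    relative_energy: float  # fraction of total return energy


@dataclass(frozen=True)
class CanopySpec:
    """Vertical canopy composition: vegetation strata plus a ground return."""

    strata: tuple[Stratum, ...]
    ground_energy_fraction: float
    max_height: float = 45.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "strata", tuple(self.strata))
        if not self.strata and self.ground_energy_fraction == 0:
            raise ValueError("canopy with no strata and no ground energy: no signal")
        if not 0.0 <= self.ground_energy_fraction <= 1.0:
            raise ValueError("ground_energy_fraction must be in [0, 1]")
        total = self.ground_energy_fraction + sum(s.relative_energy for s in self.strata)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"energy fractions must sum to 1, got {total}")
        for s in self.strata:
            if not 0.0 <= s.center <= self.max_height:
                raise ValueError(f"stratum centre {s.center} outside [0, max_height]")
            if not s.width_sd > 0:
                raise ValueError("stratum width_sd must be > 0")
            if s.relative_energy < 0:
                raise ValueError("relative_energy must be >= 0")


@dataclass(frozen=True)
class TerrainSpec:
    slope_deg: float = 0.0
    aspect_deg: float = 0.0
    latitude_deg: float = 46.5  # northern-Idaho mixed conifer

    def __post_init__(self) -> None:
        if not 0.0 <= self.slope_deg < 90.0:
            raise ValueError("slope_deg must be in [0, 90)")


@dataclass(frozen=True)
class SimConfig:
    """Acquisition parameters shared by the simulators.

    bin_size 0.15 m matches the waveform instrument's vertical resolution;
    footprints default to ~64 m diameter ellipses; point_density 12 m^-2
    matches the airborne survey density. pulse_sigma is the transmitted
    pulse width expressed as a Gaussian sd in height units.
    """

    bin_size: float = 0.15
    noise_sd: float = 0.0
    noise_mean: float = 0.0
    pulse_sigma: float = 0.35
    footprint: Ellipse = field(
        default_factory=lambda: Ellipse(0.0, 0.0, 32.0, 0.0, 0.0)
    )
    point_density: float = 12.0
    terrain: TerrainSpec = field(default_factory=TerrainSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.bin_size > 0:
            raise ValueError("bin_size must be > 0")
        if not self.point_density > 0:
            raise ValueError("point_density must be > 0")
        if self.noise_sd < 0 or self.pulse_sigma < 0:
            raise ValueError("noise_sd and pulse_sigma must be >= 0")

    @property
    def footprint_relief(self) -> float:
        """Max terrain relief across the footprint: slope times major-axis span."""
        return 2.0 * self.footprint.semimajor * math.tan(
            math.radians(self.terrain.slope_deg)
        )


@dataclass
class PointCloud:
    """Height-normalized discrete returns (planar x, y; z above ground)."""

    x: np.ndarray
    y: np.ndarray
    z_agl: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z_agl = np.asarray(self.z_agl, dtype=float)
        if not (self.x.shape == self.y.shape == self.z_agl.shape):
            raise ValueError("x, y, z_agl must have equal length")
        if self.z_agl.size and (
            not np.all(np.isfinite(self.z_agl)) or np.any(self.z_agl < -1e-9)
        ):
            raise ValueError("z_agl must be finite and >= 0")

    def __len__(self) -> int:
        return self.x.size


@dataclass
class TruthRecord:
    """Ground truth retained for parameter-recovery checks."""

    psi: np.ndarray
    p: np.ndarray  # n x J detection probabilities
    z: np.ndarray  # latent occupancy states
    beta_psi: np.ndarray
    beta_p: np.ndarray


def _component_table(spec: CanopySpec, cfg: SimConfig):
    """(center, sigma, energy) per Gaussian component, slope-broadened.

    Terrain slope stretches each component by (footprint relief) / 4,
    added in quadrature with the intrinsic width and pulse width.
    """
    slope_spread = cfg.footprint_relief / 4.0
    comps = []
    if spec.ground_energy_fraction > 0:
        sigma = math.sqrt(cfg.pulse_sigma**2 + slope_spread**2)
        comps.append((0.0, max(sigma, 1e-6), spec.ground_energy_fraction * TOTAL_ENERGY))
    for s in spec.strata:
        if s.relative_energy <= 0:
            continue
        sigma = math.sqrt(s.width_sd**2 + cfg.pulse_sigma**2 + slope_spread**2)
        comps.append((s.center, sigma, s.relative_energy * TOTAL_ENERGY))
    return comps


def simulate_waveform(spec: CanopySpec, cfg: SimConfig, site_id: str = "") -> Waveform:
    """Noisy return-energy profile for one footprint.

    The noise-free profile is the exact per-bin integral of the component
    Gaussians (so total pre-noise energy equals TOTAL_ENERGY to machine
    precision); i.i.d. Gaussian noise of sd cfg.noise_sd about
    cfg.noise_mean is then added and the result floored at zero.
    """
    comps = _component_table(spec, cfg)
    if not comps:
        raise ValueError("canopy spec produces no signal")
    max_sigma = max(s for _, s, _ in comps)
    pad = max(10.0, 9.0 * max_sigma)
    # align bin centres on multiples of bin_size so height 0 is a centre
    n_below = int(math.ceil(pad / cfg.bin_size))
    lo = -(n_below + 0.5) * cfg.bin_size
    n_bins = int(math.ceil((spec.max_height + pad - lo) / cfg.bin_size))
    centers = lo + (np.arange(n_bins) + 0.5) * cfg.bin_size

    energy = np.zeros(n_bins)
    lower = centers - cfg.bin_size / 2.0
    upper = centers + cfg.bin_size / 2.0
    for c, s, e in comps:
        energy += e * (stats.norm.cdf(upper, c, s) - stats.norm.cdf(lower, c, s))
    amp = energy / cfg.bin_size

    rng = np.random.default_rng(cfg.seed)
    if cfg.noise_sd > 0 or cfg.noise_mean != 0:
        amp = amp + cfg.noise_mean + rng.normal(0.0, cfg.noise_sd, n_bins)
        amp = np.maximum(amp, 0.0)
    return Waveform(
        bin_heights=centers,
        amplitudes=amp,
        ellipse=cfg.footprint,
        site_id=site_id,
        noise_mean=cfg.noise_mean,
        noise_sd=cfg.noise_sd,
    )


def simulate_point_cloud(spec: CanopySpec, cfg: SimConfig) -> PointCloud:
    """Discrete-return cloud over the footprint.

    Point count is Poisson(density x footprint area); heights follow the
    canopy mixture (ground points at z = 0, stratum points truncated-normal
    within [0, max_height]); x, y are uniform within the footprint ellipse.
    """
    comps = _component_table(spec, cfg)
    if not comps:
        raise ValueError("canopy spec produces no signal")
    rng = np.random.default_rng(cfg.seed)
    n = int(rng.poisson(cfg.point_density * cfg.footprint.area))
    x, y = cfg.footprint.sample_uniform(n, rng)

    weights = np.array([e for _, _, e in comps])
    weights = weights / weights.sum()
    which = rng.choice(len(comps), size=n, p=weights)
    z = np.zeros(n)
    for i, (c, s, _) in enumerate(comps):
        m = which == i
        if c == 0.0:
            continue  # ground returns stay at 0
        a, b = (0.0 - c) / s, (spec.max_height - c) / s
        z[m] = stats.truncnorm.rvs(a, b, loc=c, scale=s, size=m.sum(), random_state=rng)
    return PointCloud(x=x, y=y, z_agl=z)


def simulate_detection_data(
    site_covs: pd.DataFrame,
    beta_psi: np.ndarray,
    beta_p: np.ndarray,
    n_visits: int = 2,
    seed: int = 0,
    visit_cov_names: tuple[str, ...] = ("julian_day", "wind", "sky"),
):
    """Two-level detection/nondetection histories with known truth.

    z_i ~ Bernoulli(expit(x_i' beta_psi)) with x_i = (1, site covariates);
    y_ij | z_i = 1 ~ Bernoulli(expit(v_ij' beta_p)) with v_ij = (1, visit
    covariates); y_ij = 0 where z_i = 0. Visit covariates: julian_day
    standardized continuous, wind/sky ordinal scores 0-3 drawn uniformly.

    Returns (DetectionData, TruthRecord).
    """
    from .occupancy import DetectionData  # deferred: avoid module cycle

    if n_visits < 2:
        raise ValueError("n_visits must be >= 2")
    beta_psi = np.asarray(beta_psi, dtype=float)
    beta_p = np.asarray(beta_p, dtype=float)
    n = len(site_covs)
    X = np.column_stack([np.ones(n), site_covs.to_numpy(dtype=float)])
    if X.shape[1] != beta_psi.size:
        raise ValueError(
            f"beta_psi has {beta_psi.size} entries but design has {X.shape[1]} columns"
        )
    if beta_p.size != 1 + len(visit_cov_names):
        raise ValueError(
            f"beta_p has {beta_p.size} entries but expects {1 + len(visit_cov_names)}"
        )

    rng = np.random.default_rng(seed)
    visit_covs = {}
    for name in visit_cov_names:
        if name == "julian_day":
            jd = rng.uniform(140.0, 185.0, size=(n, n_visits))
            visit_covs[name] = (jd - jd.mean()) / jd.std()
        else:
            visit_covs[name] = rng.integers(0, 4, size=(n, n_visits)).astype(float)

    psi = expit(X @ beta_psi)
    z = rng.binomial(1, psi)
    V = np.stack(
        [np.ones((n, n_visits))] + [visit_covs[m] for m in visit_cov_names], axis=-1
    )
    p = expit(V @ beta_p)
    y = rng.binomial(1, p) * z[:, None]

    data = DetectionData(
        y=y.astype(float),
        site_covariates=site_covs.copy(),
        visit_covariates=visit_covs,
    )
    truth = TruthRecord(psi=psi, p=p, z=z, beta_psi=beta_psi, beta_p=beta_p)
    return data, truth


def make_plane_dem(
    shape=(64, 64),
    cell_size: float = 10.0,
    origin=(0.0, 0.0),
    base: float = 1000.0,
    slope_deg: float = 0.0,
    aspect_deg: float = 0.0,
):
    """Planar DEM rising toward ``aspect_deg`` at ``slope_deg``.

    Returns a terrain_metrics.DemGrid. Useful both as a fixture and to
    provide elevation/relief covariates for synthetic sites.
    """
    from .terrain import DemGrid  # deferred: avoid module cycle

    nrows, ncols = shape
    g = math.tan(math.radians(slope_deg))
    az = math.radians(aspect_deg)
    gx, gy = g * math.sin(az), g * math.cos(az)  # gradient of ascent
    xs = origin[0] + (np.arange(ncols) + 0.5) * cell_size
    ys = origin[1] + (np.arange(nrows) + 0.5) * cell_size
    xx, yy = np.meshgrid(xs, ys)
    zz = base + gx * (xx - xs.mean()) + gy * (yy - ys.mean())
    # DemGrid stores row 0 = northernmost
    return DemGrid(origin=origin, cell_size=cell_size, elevation=zz[::-1, :])


def make_random_dem(
    shape=(200, 200),
    cell_size: float = 10.0,
    origin=(0.0, 0.0),
    base: float = 1000.0,
    seed: int = 0,
    n_waves: int = 4,
):
    """Smooth synthetic terrain: a gentle regional trend plus random
    long-wavelength sinusoidal undulations (montane slopes of a few
    degrees, relief of order 100 m across a few km)."""
    from .terrain import DemGrid  # deferred: avoid module cycle

    rng = np.random.default_rng(seed)
    nrows, ncols = shape
    xs = origin[0] + (np.arange(ncols) + 0.5) * cell_size
    ys = origin[1] + (np.arange(nrows) + 0.5) * cell_size
    xx, yy = np.meshgrid(xs, ys)
    zz = base + 0.02 * (xx - xs.mean()) + 0.01 * (yy - ys.mean())
    for _ in range(n_waves):
        amp = rng.uniform(10.0, 35.0)
        wavelength = rng.uniform(500.0, 2000.0)
        az = rng.uniform(0.0, 2.0 * math.pi)
        phase = rng.uniform(0.0, 2.0 * math.pi)
        zz = zz + amp * np.sin(
            2.0 * math.pi * (xx * math.sin(az) + yy * math.cos(az)) / wavelength
            + phase
        )
    return DemGrid(origin=origin, cell_size=cell_size, elevation=zz[::-1, :])


def sample_canopy_specs(n: int, seed: int = 0) -> list[CanopySpec]:
    """Draw n random mixed-conifer canopy compositions.

    Each site gets a shrub stratum (1-4 m), a main canopy stratum
    (12-35 m), and with probability 0.5 a sub-canopy stratum; energy is
    split between ground (5-30 %) and the strata. The ranges loosely
    emulate montane mixed-conifer stands with canopy heights around
    30 m and high canopy density.
    """
    rng = np.random.default_rng(seed)
    specs = []
    for _ in range(n):
        ground = rng.uniform(0.05, 0.30)
        shrub_frac = rng.uniform(0.05, 0.35) * (1 - ground)
        strata = [Stratum(rng.uniform(1.0, 4.0), rng.uniform(0.5, 1.5), shrub_frac)]
        rest = 1.0 - ground - shrub_frac
        if rng.random() < 0.5:
            sub = rng.uniform(0.2, 0.5) * rest
            strata.append(
                Stratum(rng.uniform(6.0, 12.0), rng.uniform(1.0, 3.0), sub)
            )
            rest -= sub
        strata.append(Stratum(rng.uniform(12.0, 35.0), rng.uniform(2.0, 5.0), rest))
        specs.append(CanopySpec(strata=tuple(strata), ground_energy_fraction=ground))
    return specs
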