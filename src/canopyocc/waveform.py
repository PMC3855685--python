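"""Large-footprint waveform processing and canopy metrics.

A waveform is the vertical profile of returned laser energy within one
~64 m footprint, binned at 0.15 m. The processing chain mirrors standard
practice for satellite waveform altimetry over forest:

1. noise estimation from the leading/trailing bins,
2. denoising at ``noise_mean + 4 * noise_sd``,
3. Gaussian smoothing (60 cm standard deviation by default),
4. decomposition into at most six Gaussian components,
5. ground identification as the larger-amplitude of the two lowest
   components,
6. canopy metrics (energy fractions by stratum, canopy height with a
   terrain-relief correction, height of median energy, foliage height
   diversity, vertical distribution ratio, energy-weighted height moments).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, signal

from .geometry import Ellipse

__all__ = [
    "SPEED_OF_LIGHT",
    "Waveform",
    "GaussianPeak",
    "WaveformMetrics",
    "time_to_height",
    "estimate_noise",
    "denoise",
    "smooth",
    "decompose",
    "identify_ground",
    "signal_extent",
    "canopy_height",
    "waveform_metrics",
    "qc_flags",
]

SPEED_OF_LIGHT = 299_792_458.0  # m s^-1

#: number of leading/trailing bins assumed signal-free when estimating noise
NOISE_WINDOW_BINS = 50


def time_to_height(t):
    """Convert two-way travel time (s) to one-way distance (m).

    D = 0.5 * t * c with c the vacuum speed of light.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("travel time must be non-negative")
    out = 0.5 * t * SPEED_OF_LIGHT
    return float(out) if out.ndim == 0 else out


@dataclass
class Waveform:
    """Binned return-energy profile for one footprint.

    bin_heights are ascending and uniformly spaced; amplitudes are energy
    per bin. noise_mean / noise_sd may be pre-filled by the simulator or
    estimated from the leading and trailing bins.
    """

    bin_heights: np.ndarray
    amplitudes: np.ndarray
    ellipse: Ellipse
    site_id: str = ""
    noise_mean: float | None = None
    noise_sd: float | None = None
    qc_flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bin_heights = np.asarray(self.bin_heights, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.bin_heights.shape != self.amplitudes.shape:
            raise ValueError("bin_heights and amplitudes must have equal length")
        if self.bin_heights.size < 2:
            raise ValueError("waveform needs at least 2 bins")
        d = np.diff(self.bin_heights)
        if np.any(d <= 0):
            raise ValueError("bin_heights must be strictly ascending")
        if not np.allclose(d, d[0], rtol=0, atol=1e-6):
            raise ValueError("bin spacing must be uniform")
        if not np.all(np.isfinite(self.amplitudes)):
            raise ValueError("amplitudes must be finite")

    @property
    def bin_size(self) -> float:
        return float(self.bin_heights[1] - self.bin_heights[0])

    @property
    def total_energy(self) -> float:
        """Integral of the profile (amplitude sum times bin size)."""
        return float(self.amplitudes.sum() * self.bin_size)


@dataclass(frozen=True)
class GaussianPeak:
    """One fitted Gaussian component of a decomposed waveform."""

    center: float  # m
    sigma: float  # m
    amplitude: float  # peak value, energy-per-bin units

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")
        if not self.amplitude > 0:
            raise ValueError("amplitude must be > 0")

    @property
    def area(self) -> float:
        return self.amplitude * self.sigma * math.sqrt(2.0 * math.pi)

    def evaluate(self, h):
        h = np.asarray(h, dtype=float)
        return self.amplitude * np.exp(-0.5 * ((h - self.center) / self.sigma) ** 2)


def estimate_noise(w: Waveform, n_bins: int = NOISE_WINDOW_BINS) -> tuple[float, float]:
    """Noise mean and sd from the n_bins lowest plus n_bins highest bins."""
    if 2 * n_bins > w.bin_heights.size:
        raise ValueError("waveform too short for the requested noise window")
    tails = np.concatenate([w.amplitudes[:n_bins], w.amplitudes[-n_bins:]])
    return float(tails.mean()), float(tails.std(ddof=1))


def denoise(
    w: Waveform,
    k: float = 4.0,
    noise_mean: float | None = None,
    noise_sd: float | None = None,
) -> Waveform:
    """Zero out bins at or below ``noise_mean + k * noise_sd``.

    Surviving bins are reduced by the noise mean and floored at zero. If no
    bin survives the waveform is returned zeroed with the ``low_snr`` flag
    set; downstream metric functions refuse such waveforms.
    """
    if noise_mean is None or noise_sd is None:
        if w.noise_mean is not None and w.noise_sd is not None:
            est_mean, est_sd = w.noise_mean, w.noise_sd
        else:
            est_mean, est_sd = estimate_noise(w)
        noise_mean = est_mean if noise_mean is None else noise_mean
        noise_sd = est_sd if noise_sd is None else noise_sd
    threshold = noise_mean + k * noise_sd
    amp = np.where(
        w.amplitudes > threshold, np.maximum(w.amplitudes - noise_mean, 0.0), 0.0
    )
    flags = dict(w.qc_flags)
    if not np.any(amp > 0):
        flags["low_snr"] = True
    return replace(
        w, amplitudes=amp, noise_mean=noise_mean, noise_sd=noise_sd, qc_flags=flags
    )


def smooth(w: Waveform, sigma_m: float = 0.60, as_fwhm: bool = False) -> Waveform:
    """Convolve with a unit-area Gaussian kernel of sd ``sigma_m`` metres.

    ``as_fwhm=True`` interprets ``sigma_m`` as full width at half maximum
    instead. Zero-padded convolution: total energy is conserved as long as
    the signal sits well inside the binned range.
    """
    if sigma_m <= 0:
        raise ValueError("filter width must be > 0")
    if as_fwhm:
        sigma_m = sigma_m / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    sigma_bins = sigma_m / w.bin_size
    # small tolerance so float jitter in the bin spacing cannot flip the
    # kernel half-width by one bin
    half = max(1, int(math.ceil(6.0 * sigma_bins - 1e-9)))
    x = np.arange(-half, half + 1, dtype=float)
    kernel = np.exp(-0.5 * (x / sigma_bins) ** 2)
    kernel /= kernel.sum()
    amp = np.convolve(w.amplitudes, kernel, mode="same")
    return replace(w, amplitudes=amp)


def _gaussian_mixture(h, params):
    """Sum of Gaussians; params = flat [amp, center, sigma] * n."""
    out = np.zeros_like(h)
    for a, c, s in params.reshape(-1, 3):
        out += a * np.exp(-0.5 * ((h - c) / s) ** 2)
    return out


def decompose(w: Waveform, max_peaks: int = 6) -> list[GaussianPeak]:
    """Fit at most ``max_peaks`` Gaussian components to a smoothed waveform.

    Components are initialised at the profile's local maxima (largest
    amplitude first) and refined jointly by bounded nonlinear least
    squares. Returned sorted by centre height ascending. The fit is only
    accepted if it does not worsen the residual of the initialisation.
    """
    h = w.bin_heights
    amp = w.amplitudes
    if not np.any(amp > 0):
        raise ValueError(f"waveform {w.site_id!r}: no surviving signal to decompose")

    idx, _ = signal.find_peaks(amp, height=amp.max() * 1e-6)
    if idx.size == 0:
        idx = np.array([int(np.argmax(amp))])
    # largest peaks first, capped
    idx = idx[np.argsort(amp[idx])[::-1]][:max_peaks]

    sigma0 = max(0.6, 2.0 * w.bin_size)
    p0, lo, hi = [], [], []
    span = h[-1] - h[0]
    for i in idx:
        p0 += [amp[i], h[i], sigma0]
        lo += [1e-12, h[0] - span, 1e-3]
        hi += [np.inf, h[-1] + span, span]
    p0 = np.asarray(p0)

    def resid(p):
        return _gaussian_mixture(h, p) - amp

    rss0 = float(np.sum(resid(p0) ** 2))
    best_p, best_rss = p0, rss0
    try:
        sol = optimize.least_squares(
            resid, p0, bounds=(np.asarray(lo), np.asarray(hi)), max_nfev=2000
        )
        rss = float(np.sum(sol.fun**2))
        if sol.success and rss <= rss0 + 1e-12:
            best_p, best_rss = sol.x, rss
    except Exception as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"decomposition failed for waveform {w.site_id!r}") from exc

    peaks = [
        GaussianPeak(center=float(c), sigma=float(s), amplitude=float(a))
        for a, c, s in best_p.reshape(-1, 3)
        if a > 1e-12
    ]
    if not peaks:
        raise RuntimeError(f"decomposition returned no peaks for {w.site_id!r}")
    return sorted(peaks, key=lambda p: p.center)


def identify_ground(peaks: list[GaussianPeak]) -> GaussianPeak:
    """Ground = the larger-amplitude of the two lowest components.

    Amplitude ties break toward the lower peak. A single component is
    returned as the ground.
    """
    if not peaks:
        raise ValueError("cannot identify ground in an empty peak list")
    lowest = sorted(peaks, key=lambda p: p.center)[:2]
    if len(lowest) == 1:
        return lowest[0]
    return lowest[0] if lowest[0].amplitude >= lowest[1].amplitude else lowest[1]


def signal_extent(w: Waveform) -> tuple[float, float]:
    """(signal_begin, signal_end): highest and lowest surviving bin heights."""
    nz = np.nonzero(w.amplitudes > 0)[0]
    if nz.size == 0:
        raise ValueError(f"waveform {w.site_id!r}: no surviving signal")
    return float(w.bin_heights[nz[-1]]), float(w.bin_heights[nz[0]])


def canopy_height(w: Waveform, relief: float = 0.0) -> float:
    """Waveform signal extent minus the footprint terrain relief, floored at 0.

    The relief correction removes the apparent canopy-height inflation that
    terrain slope induces by stretching the waveform.
    """
    if relief < 0:
        raise ValueError("relief must be >= 0")
    begin, end = signal_extent(w)
    return max(0.0, (begin - end) - relief)


@dataclass
class WaveformMetrics:
    """Canopy metrics for one waveform footprint (heights above ground, m)."""

    p_lower: float  # vegetation energy fraction in [0, 3) m
    p_mid: float  # vegetation energy fraction in [3, 10) m
    can_height: float
    veg_density: float  # vegetation / total energy
    home: float  # height of median (total) energy
    home_veg: float  # vegetation-energy variant, reported alongside
    fhd: float
    vdr: float | None
    ht_mean: float
    ht_var: float
    ht_cv: float
    ht_med: float
    ht_mad: float
    signal_begin: float
    signal_end: float
    bare: bool = False

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v, w_ = values[order], weights[order]
    cw = np.cumsum(w_)
    return float(np.interp(0.5 * cw[-1], cw, v))


def waveform_metrics(
    w: Waveform,
    peaks: list[GaussianPeak],
    ground: GaussianPeak,
    relief: float = 0.0,
) -> WaveformMetrics:
    """Canopy metrics from a denoised+smoothed waveform and its decomposition.

    Heights are re-expressed relative to the ground-component centre. The
    vegetation profile is the smoothed amplitude minus the fitted ground
    Gaussian, floored at zero and restricted to heights above ground.
    """
    if w.qc_flags.get("low_snr"):
        raise ValueError(f"waveform {w.site_id!r} flagged low_snr; refusing metrics")
    begin, end = signal_extent(w)
    ch = canopy_height(w, relief)
    bin_size = w.bin_size
    h_rel = w.bin_heights - ground.center
    total_energy = w.total_energy
    if total_energy <= 0:
        raise ValueError(f"waveform {w.site_id!r} has no energy")

    veg_amp = np.maximum(w.amplitudes - ground.evaluate(w.bin_heights), 0.0)
    veg_amp = np.where(h_rel > 0, veg_amp, 0.0)
    veg_energy = float(veg_amp.sum() * bin_size)

    # height of median energy: cumulative total energy from the signal end
    cum = np.cumsum(w.amplitudes) * bin_size
    home = float(np.interp(0.5 * total_energy, cum, h_rel))
    home = max(0.0, home)

    if veg_energy <= 0:
        return WaveformMetrics(
            p_lower=0.0, p_mid=0.0, can_height=ch, veg_density=0.0, home=home,
            home_veg=0.0, fhd=0.0, vdr=None, ht_mean=0.0, ht_var=0.0, ht_cv=0.0,
            ht_med=0.0, ht_mad=0.0, signal_begin=begin, signal_end=end, bare=True,
        )

    veg_e = veg_amp * bin_size
    p_lower = float(veg_e[(h_rel >= 0) & (h_rel < 3)].sum() / total_energy)
    p_mid = float(veg_e[(h_rel >= 3) & (h_rel < 10)].sum() / total_energy)
    veg_density = veg_energy / total_energy

    cum_veg = np.cumsum(veg_amp) * bin_size
    home_veg = max(0.0, float(np.interp(0.5 * veg_energy, cum_veg, h_rel)))

    # foliage height diversity over half-open 1 m bins above ground
    bins = np.floor(h_rel).astype(int)
    mask = veg_e > 0
    q = {}
    for b, e in zip(bins[mask], veg_e[mask]):
        q[b] = q.get(b, 0.0) + e
    qv = np.array(list(q.values())) / veg_energy
    fhd = float(-np.sum(qv * np.log(qv)))

    vdr = None if ch <= 0 else (ch - home) / ch

    hw = h_rel[mask]
    ew = veg_e[mask]
    ht_mean = float(np.average(hw, weights=ew))
    ht_var = float(np.average((hw - ht_mean) ** 2, weights=ew))
    ht_cv = math.sqrt(ht_var) / ht_mean if ht_mean > 0 else 0.0
    ht_med = _weighted_median(hw, ew)
    ht_mad = _weighted_median(np.abs(hw - ht_med), ew)

    return WaveformMetrics(
        p_lower=p_lower, p_mid=p_mid, can_height=ch, veg_density=veg_density,
        home=home, home_veg=home_veg, fhd=fhd, vdr=vdr, ht_mean=ht_mean,
        ht_var=ht_var, ht_cv=ht_cv, ht_med=ht_med, ht_mad=ht_mad,
        signal_begin=begin, signal_end=end, bare=False,
    )


def qc_flags(
    w: Waveform,
    ceiling: float,
    k: float = 4.0,
    consecutive: int = 3,
) -> dict:
    """Simple quality flags on a raw waveform.

    saturated: at least ``consecutive`` consecutive bins at or above
    ``ceiling``; low_snr: no bin exceeds ``noise_mean + k * noise_sd``.
    """
    if w.noise_mean is not None and w.noise_sd is not None:
        mean, sd = w.noise_mean, w.noise_sd
    else:
        mean, sd = estimate_noise(w)
    at_ceiling = w.amplitudes >= ceiling
    run = 0
    saturated = False
    for flag in at_ceiling:
        run = run + 1 if flag else 0
        if run >= consecutive:
            saturated = True
            break
    low_snr = bool(w.amplitudes.max() < mean + k * sd)
    return {"saturated": saturated, "low_snr": low_snr}
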