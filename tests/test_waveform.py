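"""Waveform processing: denoising, smoothing, Gaussian decomposition,
ground identification, and canopy metrics, checked against analytic
profiles and the simulator's known truth."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.signal import find_peaks

from canopyocc.geometry import Ellipse
from canopyocc.synthetic import CanopySpec, SimConfig, Stratum, simulate_waveform
from canopyocc.waveform import (
    GaussianPeak,
    Waveform,
    canopy_height,
    decompose,
    denoise,
    estimate_noise,
    identify_ground,
    qc_flags,
    signal_extent,
    smooth,
    time_to_height,
    waveform_metrics,
)

ELL = Ellipse(0.0, 0.0, 32.0)


def make_waveform(heights, amplitudes, **kw):
    return Waveform(np.asarray(heights), np.asarray(amplitudes), ELL, **kw)


def flat_waveform(n=500, value=0.0, bin_size=0.15):
    h = (np.arange(n) + 0.5) * bin_size - 10.0
    return make_waveform(h, np.full(n, value))


class TestTimeToHeight:
    @pytest.mark.parametrize(
        "t,expected",
        [(0.0, 0.0), (1e-9, 0.149896229), (4e-9, 0.599584916)],
    )
    def test_half_travel_time_times_c(self, t, expected):
        assert time_to_height(t) == pytest.approx(expected, abs=1e-9)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            time_to_height(-1e-9)


class TestDenoise:
    def test_pure_noise_survival_matches_normal_tail(self):
        # bins above mean + 4 sd should survive at ~the N(0,1) upper tail
        rng = np.random.default_rng(123)
        n = 1_000_000
        sigma = 2.0
        h = (np.arange(n) + 0.5) * 0.15
        w = make_waveform(h, np.maximum(rng.normal(10.0, sigma, n), 0.0))
        d = denoise(w, k=4, noise_mean=10.0, noise_sd=sigma)
        frac = np.count_nonzero(d.amplitudes) / n
        tail = stats.norm.sf(4.0)  # 3.167e-5
        assert 0.5 * tail < frac < 1.5 * tail

    def test_zero_noise_only_subtracts_mean(self):
        w = flat_waveform(value=5.0)
        d = denoise(w, noise_mean=2.0, noise_sd=0.0)
        assert np.allclose(d.amplitudes, 3.0)

    def test_strong_peak_survives(self):
        w = flat_waveform(value=1.0)
        amp = w.amplitudes.copy()
        amp[250] = 10.0  # 10 sigma above the noise
        w = make_waveform(w.bin_heights, amp)
        d = denoise(w, noise_mean=1.0, noise_sd=1.0)
        assert d.amplitudes[250] == pytest.approx(9.0)
        assert np.count_nonzero(d.amplitudes) == 1

    def test_all_zeroed_sets_low_snr_flag(self):
        w = flat_waveform(value=1.0)
        d = denoise(w, noise_mean=1.0, noise_sd=1.0)
        assert d.qc_flags["low_snr"]
        with pytest.raises(ValueError, match="low_snr"):
            waveform_metrics(d, [GaussianPeak(0, 1, 1)], GaussianPeak(0, 1, 1))

    def test_noise_estimated_from_leading_trailing_bins(self):
        rng = np.random.default_rng(5)
        w = flat_waveform(n=400)
        amp = rng.normal(3.0, 0.5, 400)
        amp[180:220] += 50.0  # signal in the middle
        w = make_waveform(w.bin_heights, amp)
        mean, sd = estimate_noise(w)
        assert mean == pytest.approx(3.0, abs=0.2)
        assert sd == pytest.approx(0.5, abs=0.15)


class TestSmooth:
    def test_impulse_becomes_gaussian_kernel(self):
        w = flat_waveform(n=401)
        amp = w.amplitudes.copy()
        amp[200] = 1.0
        w = make_waveform(w.bin_heights, amp)
        s = smooth(w, sigma_m=0.6)
        h0 = w.bin_heights[200]
        expected = np.exp(-0.5 * ((w.bin_heights - h0) / 0.6) ** 2)
        expected /= expected.sum()
        # kernel truncated at 6 sigma -> agreement to the truncation tail
        assert np.allclose(s.amplitudes, expected, atol=1e-8)

    def test_energy_conserved(self, two_strata_spec):
        w = simulate_waveform(two_strata_spec, SimConfig(seed=0))
        s = smooth(w, sigma_m=0.6)
        assert s.total_energy == pytest.approx(w.total_energy, rel=1e-9)

    def test_close_impulses_merge_to_one_maximum(self):
        w = flat_waveform(n=401)
        amp = w.amplitudes.copy()
        amp[200] = 1.0
        amp[202] = 1.0  # 0.3 m apart at 0.15 m bins
        s = smooth(make_waveform(w.bin_heights, amp), sigma_m=0.6)
        idx, _ = find_peaks(s.amplitudes)
        assert len(idx) == 1

    def test_fwhm_interpretation_is_narrower(self):
        w = simulate_waveform(
            CanopySpec(strata=(), ground_energy_fraction=1.0), SimConfig(seed=0)
        )
        s_sd = smooth(w, sigma_m=0.6)
        s_fwhm = smooth(w, sigma_m=0.6, as_fwhm=True)
        assert s_fwhm.amplitudes.max() > s_sd.amplitudes.max()

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            smooth(flat_waveform(), sigma_m=0.0)


class TestDecompose:
    def test_single_gaussian_self_fit(self):
        w = flat_waveform(n=500)
        amp = 5.0 * np.exp(-0.5 * ((w.bin_heights - 10.0) / 2.0) ** 2)
        peaks = decompose(make_waveform(w.bin_heights, amp))
        assert len(peaks) == 1
        assert peaks[0].center == pytest.approx(10.0, abs=0.01)
        assert peaks[0].sigma == pytest.approx(2.0, abs=0.01)

    def test_two_gaussians_recovered(self):
        w = flat_waveform(n=500)
        h = w.bin_heights
        amp = 4.0 * np.exp(-0.5 * (h / 1.0) ** 2) + 2.0 * np.exp(
            -0.5 * ((h - 20.0) / 3.0) ** 2
        )
        peaks = decompose(make_waveform(h, amp))
        assert len(peaks) == 2
        assert peaks[0].center == pytest.approx(0.0, abs=0.05)
        assert peaks[1].center == pytest.approx(20.0, abs=0.05)

    def test_component_cap(self):
        # 8 well-separated strata but at most 6 components returned
        strata = tuple(Stratum(4.0 + 5.0 * i, 0.6, 0.11) for i in range(8))
        spec = CanopySpec(strata=strata, ground_energy_fraction=0.12)
        w = simulate_waveform(spec, SimConfig(seed=0))
        peaks = decompose(w, max_peaks=6)
        assert len(peaks) == 6

    def test_peaks_sorted_by_height(self, two_strata_spec):
        w = simulate_waveform(two_strata_spec, SimConfig(seed=0))
        centers = [p.center for p in decompose(w)]
        assert centers == sorted(centers)

    def test_empty_signal_rejected(self):
        with pytest.raises(ValueError, match="no surviving signal"):
            decompose(flat_waveform(value=0.0))


class TestIdentifyGround:
    def test_larger_of_two_lowest_wins(self):
        peaks = [GaussianPeak(0, 1, 0.8), GaussianPeak(4, 1, 0.3),
                 GaussianPeak(25, 1, 0.5)]
        assert identify_ground(peaks).center == 0
        peaks = [GaussianPeak(0, 1, 0.2), GaussianPeak(3, 1, 0.9),
                 GaussianPeak(25, 1, 0.5)]
        assert identify_ground(peaks).center == 3

    def test_single_peak_returned(self):
        p = GaussianPeak(5, 1, 1)
        assert identify_ground([p]) is p

    def test_amplitude_tie_breaks_low(self):
        peaks = [GaussianPeak(0, 1, 0.5), GaussianPeak(3, 1, 0.5)]
        assert identify_ground(peaks).center == 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            identify_ground([])


class TestCanopyHeight:
    def _extent_waveform(self, lo, hi):
        h = np.arange(-30.0, 60.0, 0.15)
        amp = np.where((h >= lo - 1e-9) & (h <= hi + 1e-9), 1.0, 0.0)
        return make_waveform(h, amp)

    def test_flat_terrain(self):
        assert canopy_height(self._extent_waveform(0, 40), 0.0) == pytest.approx(
            40.0, abs=0.15
        )

    def test_relief_subtracted(self):
        assert canopy_height(self._extent_waveform(0, 40), 6.0) == pytest.approx(
            34.0, abs=0.15
        )

    def test_floored_at_zero(self):
        assert canopy_height(self._extent_waveform(0, 3), 6.0) == 0.0

    def test_negative_relief_rejected(self):
        with pytest.raises(ValueError):
            canopy_height(self._extent_waveform(0, 40), -1.0)


class TestWaveformMetrics:
    def test_uniform_vegetation_reaches_shannon_maximum(self):
        # equal energy in exactly 20 one-metre bins above ground
        h = np.arange(-5.0, 25.0, 0.1) + 0.05
        amp = np.where((h > 0) & (h < 20), 1.0, 0.0)
        w = make_waveform(h, amp)
        ground = GaussianPeak(0.0, 0.3, 1e-9)
        m = waveform_metrics(w, [ground], ground)
        assert m.fhd == pytest.approx(math.log(20), abs=1e-9)

    def test_symmetric_stratum_home_at_center(self):
        h = np.arange(-10.0, 30.0, 0.15)
        amp = np.exp(-0.5 * ((h - 10.0) / 2.0) ** 2)
        w = make_waveform(h, amp)
        ground = GaussianPeak(0.0, 0.3, 1e-12)
        m = waveform_metrics(w, [ground], ground)
        assert m.home == pytest.approx(10.0, abs=0.15)
        assert m.ht_mean == pytest.approx(10.0, abs=0.15)
        assert m.ht_med == pytest.approx(10.0, abs=0.15)

    def test_vdr_formula_and_band_partition(self, separable_spec):
        w = simulate_waveform(separable_spec, SimConfig(seed=3))
        s = smooth(denoise(w, noise_mean=0.0, noise_sd=0.0))
        peaks = decompose(s)
        ground = identify_ground(peaks)
        m = waveform_metrics(s, peaks, ground, relief=2.0)
        assert m.vdr == pytest.approx((m.can_height - m.home) / m.can_height)
        # p_lower + p_mid + energy above 10 m == veg_density exactly
        h_rel = s.bin_heights - ground.center
        veg = np.maximum(s.amplitudes - ground.evaluate(s.bin_heights), 0.0)
        veg = np.where(h_rel > 0, veg, 0.0)
        upper = veg[h_rel >= 10].sum() * s.bin_size / s.total_energy
        assert m.p_lower + m.p_mid + upper == pytest.approx(m.veg_density, abs=1e-12)

    def test_bare_ground_flagged(self):
        h = np.arange(-10.0, 30.0, 0.15)
        amp = 5.0 * np.exp(-0.5 * (h / 0.4) ** 2)
        w = make_waveform(h, amp)
        ground = GaussianPeak(0.0, 0.4, 5.0)
        m = waveform_metrics(w, [ground], ground)
        assert m.bare and m.fhd == 0.0 and m.vdr is None

    @given(scale=st.floats(0.1, 100.0))
    @settings(max_examples=20, deadline=None)
    def test_fhd_invariant_under_amplitude_scaling(self, scale):
        h = np.arange(-10.0, 30.0, 0.15)
        rng = np.random.default_rng(0)
        amp = rng.uniform(0, 1, h.size) * np.exp(-0.5 * ((h - 8) / 5.0) ** 2)
        ground = GaussianPeak(0.0, 0.3, 1e-12)
        m1 = waveform_metrics(make_waveform(h, amp), [ground], ground)
        m2 = waveform_metrics(make_waveform(h, amp * scale), [ground], ground)
        assert m2.fhd == pytest.approx(m1.fhd, rel=1e-9)
        # and bounded by log of the number of occupied 1 m bins
        occupied = len({int(x) for x in np.floor(h[(h > 0) & (amp > 0)])})
        assert m1.fhd <= math.log(occupied) + 1e-12

    def test_processing_commutes_with_height_translation(self, two_strata_spec):
        w = simulate_waveform(two_strata_spec, SimConfig(noise_sd=0.2,
                                                         noise_mean=1.0, seed=8))
        shifted = make_waveform(w.bin_heights + 100.0, w.amplitudes,
                                noise_mean=w.noise_mean, noise_sd=w.noise_sd)
        a = smooth(denoise(w))
        b = smooth(denoise(shifted))
        assert np.allclose(a.amplitudes, b.amplitudes, atol=1e-7)
        assert signal_extent(b)[0] - signal_extent(a)[0] == pytest.approx(100.0)


class TestRoundTrip:
    def test_noise_free_strata_recovered_within_bin_error(self, separable_spec):
        """Simulated stratum energies pass through the full metric chain."""
        cfg = SimConfig(seed=3)
        w = simulate_waveform(separable_spec, cfg)
        s = smooth(denoise(w, noise_mean=0.0, noise_sd=0.0), sigma_m=0.6)
        peaks = decompose(s)
        ground = identify_ground(peaks)
        m = waveform_metrics(s, peaks, ground)

        # analytic oracle: band energies of the smoothed mixture
        def band(lo, hi):
            total = 0.0
            for stn in separable_spec.strata:
                sig = math.sqrt(stn.width_sd**2 + cfg.pulse_sigma**2 + 0.6**2)
                total += stn.relative_energy * (
                    stats.norm.cdf(hi, stn.center, sig)
                    - stats.norm.cdf(lo, stn.center, sig)
                )
            return total

        # one-bin energy error bound at the band boundaries
        def amp_at(h):
            return sum(
                stn.relative_energy
                * stats.norm.pdf(
                    h, stn.center,
                    math.sqrt(stn.width_sd**2 + cfg.pulse_sigma**2 + 0.6**2),
                )
                for stn in separable_spec.strata
            )

        tol_low = cfg.bin_size * (amp_at(0) + amp_at(3)) + 1e-3
        tol_mid = cfg.bin_size * (amp_at(3) + amp_at(10)) + 1e-3
        assert m.p_lower == pytest.approx(band(0, 3), abs=tol_low)
        assert m.p_mid == pytest.approx(band(3, 10), abs=tol_mid)
        assert m.veg_density == pytest.approx(band(0, np.inf), abs=0.01)

        be = np.array([band(b, b + 1) for b in range(45)])
        q = be[be > 1e-12] / be.sum()
        fhd_analytic = float(-np.sum(q * np.log(q)))
        assert m.fhd == pytest.approx(fhd_analytic, abs=0.02)


class TestQcFlags:
    def test_clipped_waveform_flagged_saturated(self):
        w = flat_waveform(value=1.0)
        amp = w.amplitudes.copy()
        amp[200:205] = 100.0
        flags = qc_flags(make_waveform(w.bin_heights, amp), ceiling=100.0)
        assert flags["saturated"]

    def test_clean_signal_unflagged(self, two_strata_spec):
        w = simulate_waveform(
            two_strata_spec, SimConfig(noise_sd=0.1, noise_mean=0.5, seed=2))
        flags = qc_flags(w, ceiling=1e6)
        assert not flags["saturated"] and not flags["low_snr"]

    def test_pure_noise_flagged_low_snr(self):
        rng = np.random.default_rng(3)
        w = flat_waveform(n=1000)
        w = make_waveform(w.bin_heights, np.maximum(rng.normal(5, 0.5, 1000), 0))
        flags = qc_flags(w, ceiling=1e6)
        assert flags["low_snr"]
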