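"""Peak fitting, Bragg and Scherrer conversions, and map-level recovery."""

import numpy as np
import pytest

from periscat.frames import DetectorFrame
from periscat.geometry import two_theta_from_q, wavelength_nm
from periscat.reduction import RadialProfile, azimuthal_integrate
from periscat.simulate import (GroundTruthField, ScanGrid, SimulationConfig,
                               simulate_scan_grid, simulate_xrd_frame)
from periscat.xrd import (PeakFitResult, UltrastructureConfig, bragg_d_spacing,
                          fit_002_peak, map_ultrastructure, scherrer_size)

WL15 = wavelength_nm(15.0)


def gaussian_profile(center=18.265, fwhm=0.60, amp=1000.0, base=50.0,
                     slope=0.0, n=400, rng_sigma=0.0, seed=0):
    q = np.linspace(center - 2.5, center + 2.5, n)
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    y = amp * np.exp(-0.5 * ((q - center) / sigma) ** 2) + base + slope * q
    if rng_sigma > 0:
        model = np.maximum(y, 0)
        y = np.random.default_rng(seed).poisson(model).astype(float)
        return RadialProfile(q=q, intensity=y, sigma=np.sqrt(model))
    return RadialProfile(q=q, intensity=y)


class TestPeakFit:
    def test_identity_on_noise_free_gaussian(self):
        prof = gaussian_profile()
        fit = fit_002_peak(prof, (16.5, 20.0))
        assert fit.converged
        assert fit.center_q == pytest.approx(18.265, rel=1e-6)
        assert fit.fwhm_q == pytest.approx(0.60, rel=1e-6)
        assert fit.r_squared > 0.999999

    def test_linear_background_does_not_shift_center(self):
        fit = fit_002_peak(gaussian_profile(slope=40.0), (16.5, 20.0))
        assert fit.center_q == pytest.approx(18.265, rel=1e-4)
        assert fit.background["slope"] == pytest.approx(40.0, rel=1e-3)

    def test_poisson_center_coverage(self):
        """Center within 3 sigma of truth in >= 99% of 500 noisy replicates."""
        hits = 0
        for seed in range(500):
            prof = gaussian_profile(amp=1.0e4, base=200.0, rng_sigma=1.0,
                                    seed=seed)
            fit = fit_002_peak(prof, (16.5, 20.0))
            if fit.converged and abs(fit.center_q - 18.265) \
                    <= 3.0 * fit.center_sigma_q:
                hits += 1
        assert hits >= 495

    def test_window_outside_profile_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            fit_002_peak(gaussian_profile(), (40.0, 50.0))

    def test_too_few_bins_flags_not_raises(self):
        prof = gaussian_profile(n=200)
        out = fit_002_peak(prof, (18.25, 18.28))
        assert not out.converged


class TestBragg:
    def fit(self, center=18.265, center_sigma=0.0):
        return PeakFitResult(center_q=center, center_sigma_q=center_sigma,
                             fwhm_q=0.2, fwhm_sigma_q=0.0, amplitude=1.0,
                             background={}, r_squared=1.0, converged=True)

    def test_hand_value(self):
        d, _ = bragg_d_spacing(self.fit(), WL15)
        assert d == pytest.approx(0.3440, abs=1e-4)

    def test_order_doubles_d(self):
        d1, _ = bragg_d_spacing(self.fit(), WL15, order=1)
        d2, _ = bragg_d_spacing(self.fit(), WL15, order=2)
        assert d2 == pytest.approx(2.0 * d1, rel=1e-12)

    def test_zero_center_sigma_gives_zero_d_sigma(self):
        _, s = bragg_d_spacing(self.fit(center_sigma=0.0), WL15)
        assert s == 0.0

    def test_nonconverged_rejected(self):
        bad = self.fit()
        bad.converged = False
        with pytest.raises(ValueError):
            bragg_d_spacing(bad, WL15)


class TestScherrer:
    def fit_with_beta(self, beta_2theta, center=18.265):
        """Build a fit whose exact 2-theta FWHM equals beta_2theta."""
        tt = two_theta_from_q(center, WL15)
        q_lo = 4.0 * np.pi / WL15 * np.sin((tt - beta_2theta / 2.0) / 2.0)
        q_hi = 4.0 * np.pi / WL15 * np.sin((tt + beta_2theta / 2.0) / 2.0)
        return PeakFitResult(center_q=center, center_sigma_q=0.0,
                             fwhm_q=q_hi - q_lo, fwhm_sigma_q=0.0,
                             amplitude=1.0, background={}, r_squared=1.0,
                             converged=True)

    def test_hand_value_30nm(self):
        # K=1, lambda=0.082656 nm, theta=0.12043 rad, beta=0.0027753 rad
        tau, _ = scherrer_size(self.fit_with_beta(0.0027753), WL15, K=1.0)
        assert tau == pytest.approx(30.0, abs=0.01)

    def test_doubling_beta_halves_tau(self):
        t1, _ = scherrer_size(self.fit_with_beta(0.002), WL15)
        t2, _ = scherrer_size(self.fit_with_beta(0.004), WL15)
        assert t2 == pytest.approx(t1 / 2.0, rel=1e-4)

    def test_small_angle_limit(self):
        """At theta -> 0 the size tends to K lambda / beta."""
        beta = 0.002
        fit = self.fit_with_beta(beta, center=0.5)  # tiny scattering angle
        tau, _ = scherrer_size(fit, WL15)
        assert tau == pytest.approx(WL15 / beta, rel=1e-3)

    def test_instrumental_correction_never_shrinks_tau(self):
        fit = self.fit_with_beta(0.0030)
        raw, _ = scherrer_size(fit, WL15)
        corr, _ = scherrer_size(fit, WL15, instrumental_fwhm_2theta=0.001)
        assert corr > raw

    def test_instrumental_broadening_too_large_rejected(self):
        with pytest.raises(ValueError, match="instrumental"):
            scherrer_size(self.fit_with_beta(0.002), WL15,
                          instrumental_fwhm_2theta=0.003)

    def test_bad_shape_factor_rejected(self):
        with pytest.raises(ValueError):
            scherrer_size(self.fit_with_beta(0.002), WL15, K=2.0)


def test_round_trip_d_and_tau(xrd_config):
    """Simulate -> integrate -> fit -> Bragg/Scherrer to < 0.1% noise-free."""
    frame = simulate_xrd_frame(xrd_config, 0.344, 30.0)
    prof = azimuthal_integrate(frame, xrd_config.geometry(), n_bins=3000)
    cfg = UltrastructureConfig()
    fit = fit_002_peak(prof, cfg.fit_window(xrd_config.wavelength))
    d, _ = bragg_d_spacing(fit, xrd_config.wavelength)
    tau, _ = scherrer_size(fit, xrd_config.wavelength)
    assert d == pytest.approx(0.344, rel=1e-3)
    assert tau == pytest.approx(30.0, rel=1e-3)


def test_d_invariant_under_intensity_rescale(xrd_config):
    frame = simulate_xrd_frame(xrd_config, 0.344, 30.0)
    prof = azimuthal_integrate(frame, xrd_config.geometry(), n_bins=2000)
    scaled = RadialProfile(q=prof.q, intensity=prof.intensity * 37.0,
                           sigma=prof.sigma, n_pixels=prof.n_pixels)
    w = UltrastructureConfig().fit_window(xrd_config.wavelength)
    d1, _ = bragg_d_spacing(fit_002_peak(prof, w), xrd_config.wavelength)
    d2, _ = bragg_d_spacing(fit_002_peak(scaled, w), xrd_config.wavelength)
    assert d2 == pytest.approx(d1, rel=1e-9)


def test_larger_tau_gives_smaller_fwhm(xrd_config):
    """Strict monotonicity of fitted width against crystallite size."""
    widths = []
    w = UltrastructureConfig().fit_window(xrd_config.wavelength)
    for tau in (20.0, 30.0, 45.0):
        frame = simulate_xrd_frame(xrd_config, 0.344, tau)
        prof = azimuthal_integrate(frame, xrd_config.geometry(), n_bins=2500)
        widths.append(fit_002_peak(prof, w).fwhm_q)
    assert widths[0] > widths[1] > widths[2]


class TestMap:
    def test_constant_grid_recovery(self, xrd_config):
        field = GroundTruthField(d_spacing_at_interface_nm=0.344,
                                 d_spacing_gradient_nm_per_mm=0.0,
                                 crystallite_size_nm=30.0)
        sim = simulate_scan_grid(field, ScanGrid(0.1, 0.05, 0.05), xrd_config)
        rec = map_ultrastructure(sim.frames, xrd_config.geometry())
        assert rec["qc_pass"].all()
        assert rec["d_spacing_nm"].mean() == pytest.approx(0.344, rel=1e-3)
        assert rec["crystallite_nm"].mean() == pytest.approx(30.0, rel=2e-3)

    def test_gradient_grid_recovery(self, xrd_config):
        field = GroundTruthField(d_spacing_at_interface_nm=0.342,
                                 d_spacing_gradient_nm_per_mm=0.002)
        sim = simulate_scan_grid(field, ScanGrid(0.8, 0.1, 0.1), xrd_config)
        rec = map_ultrastructure(sim.frames, xrd_config.geometry())
        merged = rec.merge(sim.truth, on=["x_mm", "y_mm"])
        rel = np.abs(merged["d_spacing_nm"] - merged["d_nm"]) / merged["d_nm"]
        assert rel.max() < 1e-3  # noise-free: essentially exact per point

    def test_all_masked_frame_flagged_not_fatal(self, xrd_config):
        good = simulate_xrd_frame(xrd_config, 0.344, 30.0,
                                  metadata={"x_mm": 0.0, "y_mm": 0.0})
        dead = DetectorFrame(counts=good.counts,
                             mask=np.ones(good.shape, dtype=bool),
                             metadata={"x_mm": 0.1, "y_mm": 0.0})
        rec = map_ultrastructure([good, dead], xrd_config.geometry())
        assert len(rec) == 2
        assert rec.loc[0, "qc_pass"]
        assert not rec.loc[1, "qc_pass"]
        assert "integration_error" in rec.loc[1, "flags"]
        assert np.isnan(rec.loc[1, "d_spacing_nm"])
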