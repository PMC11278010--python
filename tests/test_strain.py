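"""Ellipse fitting of Debye rings, strain maps and tip-distance profiles."""

import numpy as np
import pandas as pd
import pytest

from periscat.reduction import apply_mask
from periscat.simulate import (GroundTruthField, simulate_indentation_series,
                               simulate_xrd_frame, strain_ratio_field)
from periscat.strain import (extract_ring_points, fit_ellipse,
                             fit_strain_decay, load_force_displacement,
                             propagate_ratio_sigma, secant_stiffness,
                             strain_map, strain_map_series,
                             strain_vs_tip_distance)


def ellipse_points(a, b, theta=0.0, n=36, noise=0.0, seed=0):
    phi = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    r = a * b / np.sqrt((a * np.cos(phi)) ** 2 + (b * np.sin(phi)) ** 2)
    if noise:
        r = r + noise * np.random.default_rng(seed).standard_normal(n)
    # phi measured from the major axis; rotate by theta
    x = r * np.cos(phi + theta)
    y = r * np.sin(phi + theta)
    return np.column_stack([x, y])


class TestFitEllipse:
    def test_circle_identity(self):
        fit = fit_ellipse(ellipse_points(18.0, 18.0))
        assert fit.converged
        assert fit.epsilon_relative == pytest.approx(1.0, abs=1e-6)

    def test_analytic_axis_ratio(self):
        fit = fit_ellipse(ellipse_points(18.20, 18.30))
        assert fit.epsilon_relative == pytest.approx(0.994536, abs=1e-6)

    def test_oracle_axes_recovery(self):
        """Exact-ellipse points: both axes recovered to < 0.01%."""
        fit = fit_ellipse(ellipse_points(17.9, 18.4, theta=0.9))
        assert fit.semi_minor == pytest.approx(17.9, rel=1e-4)
        assert fit.semi_major == pytest.approx(18.4, rel=1e-4)
        assert fit.orientation == pytest.approx(0.9, abs=1e-4)

    def test_rotation_invariance(self):
        base = fit_ellipse(ellipse_points(18.0, 18.3, theta=0.0))
        for theta in (0.3, 1.1, 2.5):
            rot = fit_ellipse(ellipse_points(18.0, 18.3, theta=theta))
            assert rot.epsilon_relative == pytest.approx(
                base.epsilon_relative, abs=1e-6)
            assert rot.orientation == pytest.approx(theta % np.pi, abs=1e-6)

    def test_propagation_hand_value(self):
        # a = b = 1, sigma_a = sigma_b = 0.01 -> sigma_eps = 0.01414
        assert propagate_ratio_sigma(1.0, 1.0, 0.01, 0.01) == pytest.approx(
            0.01414, abs=1e-5)

    def test_propagation_matches_monte_carlo(self):
        """Propagated ratio sigma matches the MC spread within 5%."""
        rng = np.random.default_rng(11)
        a0, b0, sa, sb = 18.0, 18.2, 0.02, 0.03
        draws = rng.normal(a0, sa, 200_000) / rng.normal(b0, sb, 200_000)
        assert propagate_ratio_sigma(a0, b0, sa, sb) == pytest.approx(
            draws.std(), rel=0.05)

    def test_reported_sigma_matches_point_noise(self):
        """Residual-based epsilon sigma tracks the true spread over seeds."""
        eps, sig = [], []
        for seed in range(60):
            fit = fit_ellipse(ellipse_points(18.0, 18.2, n=36, noise=0.01,
                                             seed=seed))
            eps.append(fit.epsilon_relative)
            sig.append(fit.epsilon_sigma)
        assert np.mean(sig) == pytest.approx(np.std(eps), rel=0.35)

    def test_degenerate_points_rejected(self):
        line = np.column_stack([np.linspace(0, 1, 10), np.linspace(0, 2, 10)])
        with pytest.raises(ValueError, match="collinear"):
            fit_ellipse(line)
        with pytest.raises(ValueError):
            fit_ellipse(ellipse_points(18.0, 18.0)[:4])


class TestExtractRingPoints:
    def test_circular_ring_radii_uniform(self, strain_config):
        frame = simulate_xrd_frame(strain_config, 0.3425, 35.0)
        pts, detail = extract_ring_points(frame, strain_config.geometry(),
                                          n_sectors=24)
        radii = np.hypot(pts[:, 0], pts[:, 1])
        q0 = 2.0 * np.pi / 0.3425
        assert np.max(np.abs(radii - q0) / q0) < 1e-4

    def test_masked_wedge_drops_sectors_only(self, strain_config):
        frame = simulate_xrd_frame(strain_config, 0.3425, 35.0)
        geom = strain_config.geometry()
        az = geom.azimuth_map(frame.shape)
        masked = apply_mask(frame, (az >= 0.0) & (az < 90.0))
        full_pts, full_detail = extract_ring_points(frame, geom, n_sectors=24,
                                                    correct_sector_smearing=False)
        part_pts, part_detail = extract_ring_points(masked, geom, n_sectors=24,
                                                    correct_sector_smearing=False)
        assert (part_detail["azimuth_deg"] > 90.0).all()
        kept = full_detail["azimuth_deg"].isin(part_detail["azimuth_deg"])
        assert np.allclose(full_detail.loc[kept, "q_peak"],
                           part_detail["q_peak"], rtol=1e-9)

    def test_elliptical_radii_follow_parametric_ellipse(self, strain_config):
        """Sector radii track r(phi) of the generating ellipse to < 0.05%."""
        ratio = 0.99
        frame = simulate_xrd_frame(strain_config, 0.3425, 35.0,
                                   strain_ratio=ratio)
        pts, detail = extract_ring_points(frame, strain_config.geometry(),
                                          n_sectors=36)
        q0 = 2.0 * np.pi / 0.3425
        a, b = q0 * np.sqrt(ratio), q0 / np.sqrt(ratio)
        phi = np.radians(detail["azimuth_deg"].to_numpy())
        r_true = a * b / np.sqrt((a * np.cos(phi)) ** 2 + (b * np.sin(phi)) ** 2)
        r_meas = np.hypot(pts[:, 0], pts[:, 1])
        assert np.max(np.abs(r_meas - r_true) / r_true) < 5e-4

    def test_underdetermined_ring_rejected(self, strain_config):
        frame = simulate_xrd_frame(strain_config, 0.3425, 35.0)
        geom = strain_config.geometry()
        az = geom.azimuth_map(frame.shape)
        nearly_all = apply_mask(frame, az < 300.0)
        with pytest.raises(ValueError, match="under-determined"):
            extract_ring_points(nearly_all, geom, n_sectors=12)


class TestStrainRecovery:
    def test_noise_free_ratio_recovery(self, strain_config):
        """Fitted a/b equals the simulated distortion to < 0.05%."""
        for ratio in (1.0, 0.995, 0.99):
            frame = simulate_xrd_frame(strain_config, 0.3425, 35.0,
                                       strain_ratio=ratio)
            pts, _ = extract_ring_points(frame, strain_config.geometry(),
                                         n_sectors=36)
            fit = fit_ellipse(pts)
            assert fit.epsilon_relative == pytest.approx(ratio, rel=5e-4)

    def test_zero_force_map_is_unstrained(self, strain_config):
        field = GroundTruthField()
        series = simulate_indentation_series(field, [0.0], strain_config,
                                             extent_um=8.0, spacing_um=4.0)
        df = strain_map(series.frames_by_force[0.0], strain_config.geometry(),
                        n_sectors=24)
        assert df["converged"].all()
        assert np.allclose(df["epsilon"], 1.0, atol=1e-4)

    def test_series_determinism(self, strain_config_noisy):
        field = GroundTruthField(strain_ratio_at_tip={150.0: 0.99})
        geom = strain_config_noisy.geometry()
        maps = []
        for _ in range(2):
            series = simulate_indentation_series(field, [150.0],
                                                 strain_config_noisy,
                                                 extent_um=8.0, spacing_um=4.0)
            df = strain_map_series(series.frames_by_force, geom, n_sectors=24)
            maps.append(df)
        pd.testing.assert_frame_equal(maps[0], maps[1])

    def test_missing_force_rejected(self, strain_config):
        frame = simulate_xrd_frame(strain_config, 0.3425, 35.0)
        with pytest.raises(ValueError, match="force"):
            strain_map_series({float("nan"): [frame]},
                              strain_config.geometry())


class TestTipDistanceProfile:
    def strain_df(self, eps_fn, spacing=5.0, n=15, sigma=1e-4):
        xs = spacing * np.arange(n)
        gy, gx = np.meshgrid(xs, xs, indexing="ij")
        tip = (xs[-1] / 2.0, xs[-1] / 2.0)
        r = np.hypot(gx - tip[0], gy - tip[1]).ravel()
        return pd.DataFrame({"x_um": gx.ravel(), "y_um": gy.ravel(),
                             "epsilon": eps_fn(r),
                             "epsilon_sigma": sigma}), tip

    def test_uniform_strain_flat_profile(self):
        df, tip = self.strain_df(lambda r: np.full_like(r, 0.995))
        prof = strain_vs_tip_distance(df, tip, bin_width_um=10.0)
        assert np.allclose(prof["mean_epsilon"], 0.995)
        assert np.allclose(prof["mean_deviation"], 0.005)

    def test_exponential_decay_matches_kernel(self):
        """Noise-free decay field: binned profile tracks the kernel."""
        L, A = 25.0, 0.01
        df, tip = self.strain_df(lambda r: 1.0 - A * np.exp(-r / L))
        prof = strain_vs_tip_distance(df, tip, bin_width_um=5.0)
        # compare at the per-bin mean distances within half-bin error
        expected = A * np.exp(-prof["tip_distance_um"] / L)
        assert np.allclose(prof["mean_deviation"], expected,
                           atol=A * 5.0 / (2.0 * L))

    def test_decay_length_recovery(self):
        L = 25.0
        df, tip = self.strain_df(lambda r: 1.0 - 0.01 * np.exp(-r / L),
                                 spacing=2.0, n=36)
        prof = strain_vs_tip_distance(df, tip, bin_width_um=4.0)
        amp, length = fit_strain_decay(prof)
        assert length == pytest.approx(L, rel=0.10)

    def test_simulated_field_kernel_value(self):
        field = GroundTruthField(strain_ratio_at_tip={200.0: 0.99},
                                 strain_decay_um=25.0)
        assert strain_ratio_field(field, 200.0, 50.0) == pytest.approx(
            1.0 - 0.01 * np.exp(-2.0))


class TestForceDisplacement:
    def test_loader_skips_and_dedupes(self, tmp_path):
        log = tmp_path / "fd.csv"
        log.write_text(
            "time_s,force_mn,displacement_um\n"
            "0.0,0.0,0.0\n"
            "1.0,100.0,1.0\n"
            "junk,row,here\n"
            "1.0,100.0,1.0\n"
            "2.0,200.0,2.0\n")
        fd, report = load_force_displacement(log)
        assert report["n_skipped_rows"] == 1
        assert report["n_deduplicated"] == 1
        assert len(fd) == 3

    def test_linear_log_secant_stiffness(self, tmp_path):
        k = 85.0
        x = np.linspace(0.0, 10.0, 30)
        log = tmp_path / "fd.csv"
        pd.DataFrame({"time_s": np.arange(30.0), "force_mn": k * x,
                      "displacement_um": x}).to_csv(log, index=False)
        fd, _ = load_force_displacement(log)
        assert secant_stiffness(fd, 100.0, 600.0) == pytest.approx(k, rel=1e-9)

    def test_simulator_law_round_trips(self, strain_config, tmp_path):
        field = GroundTruthField()
        series = simulate_indentation_series(field, [0.0, 100.0, 400.0],
                                             strain_config, extent_um=8.0,
                                             spacing_um=8.0)
        fd = series.force_displacement.copy()
        fd.insert(0, "time_s", np.arange(len(fd), dtype=float))
        path = tmp_path / "fd.csv"
        fd.to_csv(path, index=False)
        back, report = load_force_displacement(path)
        assert report == {"n_skipped_rows": 0, "n_deduplicated": 0}
        assert np.allclose(back["displacement_um"], fd["displacement_um"])

    def test_non_monotone_time_rejected(self, tmp_path):
        log = tmp_path / "fd.csv"
        log.write_text("time_s,force_mn,displacement_um\n"
                       "1.0,0.0,0.0\n0.5,1.0,1.0\n")
        with pytest.raises(ValueError, match="monotone"):
            load_force_displacement(log)
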