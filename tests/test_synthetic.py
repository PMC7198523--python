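"""Generative checks: analytic projections, Brownian statistics, determinism."""

import numpy as np
import pandas as pd
import pytest

from npcroute.geometry import NPCGeometry, PhotonModel, RouteModel
from npcroute.synthetic import (
    render_spot_stack,
    simulate_dual_channel,
    simulate_membrane_populations,
    simulate_route_localizations,
    simulate_trajectories,
)


class TestRouteLocalizations:
    def test_noiseless_ring_projection_follows_arcsine_law(self):
        # projecting a uniform circle of radius R onto one axis gives
        # f(x) = 1/(pi*sqrt(R^2 - x^2)); compare binned counts to the CDF
        # F(x) = (2/pi)*asin(x/R) of the folded |x|
        R, n = 40.0, 10**6
        table = simulate_route_localizations(
            [RouteModel(mean_radius=R)], n, noise=0.0, seed=42
        )
        edges = np.linspace(0.0, R, 21)
        counts, _ = np.histogram(np.abs(table["x_nm"]), bins=edges)
        probs = np.diff((2.0 / np.pi) * np.arcsin(edges / R))
        expected = n * probs
        chi2 = np.sum((counts - expected) ** 2 / expected)
        assert chi2 / len(counts) < 2.0

    def test_mixture_weights_split_counts(self):
        routes = [
            RouteModel(mean_radius=25.0, weight=0.5),
            RouteModel(mean_radius=41.0, weight=0.5),
        ]
        n = 20000
        table = simulate_route_localizations(routes, n, noise=0.0, seed=1)
        n_central = int((table["route"] == 0).sum())
        assert abs(n_central - n / 2) < 3.0 * np.sqrt(n * 0.25)

    def test_observed_radial_spread_matches_mc_oracle(self):
        # independent brute-force oracle for the same observation model:
        # noise on the projected x only, z unobserved
        R, sd, n = 40.0, 10.0, 10**4
        table = simulate_route_localizations(
            [RouteModel(mean_radius=R)], n, noise=sd, seed=2
        )
        r_obs = np.hypot(table["x_nm"], table["true_z"])
        rng = np.random.default_rng(999)
        theta = rng.uniform(0, 2 * np.pi, 200000)
        r_oracle = np.hypot(R * np.cos(theta) + rng.normal(0, sd, theta.size),
                            R * np.sin(theta))
        assert np.isclose(np.std(r_obs - R), np.std(r_oracle - R), rtol=0.05)

    def test_ground_truth_retained_one_to_one(self):
        table = simulate_route_localizations(
            [RouteModel(mean_radius=41.0)], 500, noise=5.0, seed=3
        )
        assert len(table) == 500
        assert table[["true_x", "true_y", "true_z"]].notna().all().all()
        np.testing.assert_allclose(
            np.hypot(table["true_x"], table["true_z"]), 41.0
        )

    def test_seed_determinism(self):
        a = simulate_route_localizations([RouteModel(41.0)], 100, noise=5.0, seed=7)
        b = simulate_route_localizations([RouteModel(41.0)], 100, noise=5.0, seed=7)
        pd.testing.assert_frame_equal(a, b)

    @pytest.mark.parametrize(
        "routes, n, noise",
        [
            ([], 10, 0.0),
            ([RouteModel(41.0)], 0, 0.0),
            ([RouteModel(41.0)], 10, -1.0),
        ],
    )
    def test_invalid_inputs_rejected(self, routes, n, noise):
        with pytest.raises(ValueError):
            simulate_route_localizations(routes, n, noise=noise, seed=0)

    def test_photon_model_noise_uses_precision_formula(self):
        from npcroute.localization import precision_moving

        model = PhotonModel(N=2000, D=1.0)
        table = simulate_route_localizations(
            [RouteModel(mean_radius=41.0)], 20000, noise=model, seed=8
        )
        err = table["x_nm"] - table["true_x"]
        sigma = precision_moving(model).sigma
        assert np.isclose(err.std(), sigma, rtol=0.05)


class TestTrajectories:
    def test_zero_diffusion_is_static(self):
        tracks = simulate_trajectories(D=0.0, dt=2e-3, n_tracks=5, seed=0)
        assert (tracks.displacements() == 0).all()

    def test_lag1_msd_matches_brownian_closed_form(self):
        D, dt = 1.0, 2e-3
        tracks = simulate_trajectories(D, dt, n_tracks=500,
                                       length_distribution=10, seed=4)
        jumps = tracks.displacements()
        msd = np.mean(jumps**2)  # nm^2
        expected = 4.0 * D * 1e6 * dt
        se = np.std(jumps**2) / np.sqrt(jumps.size)
        assert abs(msd - expected) < 3.0 * se

    def test_seed_determinism(self):
        a = simulate_trajectories(1.0, 1e-3, 20, ("uniform", 2, 12), seed=5)
        b = simulate_trajectories(1.0, 1e-3, 20, ("uniform", 2, 12), seed=5)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_invalid_length_spec_rejected(self):
        with pytest.raises(ValueError):
            simulate_trajectories(1.0, 1e-3, 5, length_distribution=("geometric", 0.5))
        with pytest.raises(ValueError):
            simulate_trajectories(1.0, 1e-3, 5, length_distribution=1)


class TestDualChannel:
    def test_mean_projected_separation_matches_analytic(self):
        # channels on rings r1, r2 sharing azimuth: projected separation is
        # |r2 - r1|*|cos(theta)| with mean (2/pi)*|r2 - r1|
        a, b = simulate_dual_channel(25.0, 44.0, 50000, seed=6)
        sep = np.hypot(a["x_nm"] - b["x_nm"], a["y_nm"] - b["y_nm"])
        assert np.isclose(sep.mean(), 19.0 * 2.0 / np.pi, rtol=0.02)

    def test_identical_radii_zero_separation(self):
        a, b = simulate_dual_channel(30.0, 30.0, 100, seed=0)
        sep = np.hypot(a["x_nm"] - b["x_nm"], a["y_nm"] - b["y_nm"])
        np.testing.assert_allclose(sep, 0.0, atol=1e-9)

    def test_noisy_separation_matches_mc_oracle(self):
        n1, n2 = 12.0, 15.0
        a, b = simulate_dual_channel(25.0, 44.0, 100000,
                                     noise_first=n1, noise_second=n2, seed=9)
        sep = np.hypot(a["x_nm"] - b["x_nm"], a["y_nm"] - b["y_nm"])
        rng = np.random.default_rng(1234)
        theta = rng.uniform(0, 2 * np.pi, 300000)
        dx = 19.0 * np.cos(theta) + rng.normal(0, np.hypot(n1, n2), theta.size)
        dy = rng.normal(0, np.hypot(n1, n2), theta.size)
        assert np.isclose(sep.mean(), np.hypot(dx, dy).mean(), rtol=0.02)

    def test_misalignment_offsets_channel_two(self):
        a, b = simulate_dual_channel(30.0, 30.0, 1000, misalignment=5.0, seed=10)
        sep = np.hypot(a["x_nm"] - b["x_nm"], a["y_nm"] - b["y_nm"])
        np.testing.assert_allclose(sep, 5.0, atol=1e-9)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            simulate_dual_channel(25.0, 44.0, 10, noise_first=-1.0)


class TestMembranePopulations:
    def test_symmetric_ratio_splits_evenly(self):
        table = simulate_membrane_populations(1.0, 10**4, peak_sd=8.0, seed=11)
        below = int((table["y_nm"] < 0).sum())
        assert abs(below - 5000) < 3.0 * np.sqrt(10**4 * 0.25)

    def test_peaks_sit_on_membrane_planes(self, geometry):
        table = simulate_membrane_populations(3.0, 10**4, peak_sd=5.0, seed=12)
        inm = table[table["membrane"] == "INM"]["y_nm"]
        onm = table[table["membrane"] == "ONM"]["y_nm"]
        assert abs(inm.mean() - geometry.inm_y) < 0.5
        assert abs(onm.mean() - geometry.onm_y) < 0.5

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            simulate_membrane_populations(0.0, 100, peak_sd=8.0)
        with pytest.raises(ValueError):
            simulate_membrane_populations(1.0, 100, peak_sd=0.0)


class TestRenderSpotStack:
    def test_brightest_pixel_at_emitter(self):
        model = PhotonModel(N=1e5, b=0.0)
        stack = render_spot_stack([(5.5 * 240, 9.5 * 240)], model, frame_size=16, seed=0)
        iy, ix = np.unravel_index(np.argmax(stack[0]), stack[0].shape)
        assert (ix, iy) == (5, 9)

    def test_photon_conservation(self):
        model = PhotonModel(N=10000, b=0.0)
        center = (8 * 240.0, 8 * 240.0)
        stack = render_spot_stack([center] * 5, model, frame_size=16, seed=1)
        total = stack.sum(axis=(1, 2))
        # per-frame total fluctuates with the excess-noise-scaled shot noise
        np.testing.assert_allclose(total, model.N, atol=4 * np.sqrt(model.F * model.N))

    def test_position_outside_frame_rejected(self):
        with pytest.raises(ValueError):
            render_spot_stack([(-1.0, 10.0)], PhotonModel(N=1000), frame_size=8)
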