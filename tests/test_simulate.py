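"""Ground-truth generators: determinism, closed-form statistics, recovery."""

import numpy as np
import pytest

from mptkit import (
    ImageSimConfig,
    SimulationConfig,
    analyze_set,
    compute_msd,
    generate_assay_table,
    generate_nuclei_image,
    simulate_brownian,
    simulate_directed,
    simulate_fbm,
    simulate_immobile,
    simulate_mixture,
    simulate_trajectories,
)
from mptkit.simulate import _fgn_cholesky

DT = 1.0 / 33.3


def _positions(ts):
    return np.stack([tr.positions for tr in ts])


@pytest.mark.parametrize(
    "regime,params",
    [
        ("brownian", {"D": 0.5}),
        ("fbm", {"D": 0.5, "hurst": 0.3}),
        ("immobile", {}),
        ("directed", {"velocity": 0.5, "D": 0.01}),
    ],
)
def test_same_seed_bitwise_identical(regime, params):
    cfg = SimulationConfig(n_trajectories=5, n_frames=60, seed=9,
                           regime=regime, regime_params=params)
    a, la = simulate_trajectories(cfg)
    b, lb = simulate_trajectories(cfg)
    assert np.array_equal(_positions(a), _positions(b))
    assert la.equals(lb)


def test_config_invariants_enforced():
    with pytest.raises(ValueError):
        SimulationConfig(n_frames=1)
    with pytest.raises(ValueError):
        SimulationConfig(frame_interval=0.0)
    with pytest.raises(ValueError):
        SimulationConfig(localization_noise_sd=-0.1)
    with pytest.raises(ValueError):
        SimulationConfig(regime="levy")
    with pytest.raises(ValueError):
        SimulationConfig(
            regime="mixture",
            regime_params={"components": [
                {"regime": "brownian", "fraction": 0.6, "D": 1.0},
                {"regime": "immobile", "fraction": 0.3},
            ]},
        )


class TestBrownian:
    def test_degenerate_zero_diffusion_is_static(self):
        cfg = SimulationConfig(n_trajectories=3, n_frames=50, seed=0,
                               localization_noise_sd=0.0,
                               regime="brownian", regime_params={"D": 0.0})
        ts, _ = simulate_brownian(cfg)
        for tr in ts:
            assert np.all(tr.x == tr.x[0]) and np.all(tr.y == tr.y[0])
            assert np.all(compute_msd(tr, max_lag=10).msd == 0.0)

    def test_single_step_displacement_variance(self):
        # ensemble mean squared single-step displacement = 4·D·dt
        cfg = SimulationConfig(n_trajectories=200, n_frames=651, seed=7,
                               localization_noise_sd=0.0,
                               regime="brownian", regime_params={"D": 0.5})
        ts, _ = simulate_brownian(cfg)
        pos = _positions(ts)
        step_sq = np.sum(np.diff(pos, axis=1) ** 2, axis=2)
        expected = 4.0 * 0.5 * cfg.frame_interval
        assert np.mean(step_sq) == pytest.approx(expected, rel=0.05)

    def test_negative_diffusion_rejected(self):
        cfg = SimulationConfig(regime="brownian", regime_params={"D": -1.0})
        with pytest.raises(ValueError):
            simulate_brownian(cfg)

    def test_ensemble_msd_converges_to_4dt_plus_noise_floor(self):
        D, sigma = 0.5, 0.02
        cfg = SimulationConfig(n_trajectories=500, n_frames=120, seed=21,
                               localization_noise_sd=sigma,
                               regime="brownian", regime_params={"D": D})
        ts, _ = simulate_brownian(cfg)
        profiles = [compute_msd(tr, max_lag=10) for tr in ts]
        mean_msd = np.mean([p.msd for p in profiles], axis=0)
        tau = profiles[0].tau
        expected = 4.0 * D * tau + 4.0 * sigma**2
        assert np.all(np.abs(mean_msd - expected) / expected < 0.05)


class TestFbm:
    @pytest.mark.parametrize("hurst", [0.25, 0.5, 0.75])
    def test_cholesky_reproduces_fgn_covariance(self, hurst):
        L = _fgn_cholesky(40, hurst)
        cov = L @ L.T
        k = np.arange(40.0)
        h2 = 2 * hurst
        gamma = 0.5 * (np.abs(k + 1) ** h2 - 2 * k**h2 + np.abs(k - 1) ** h2)
        expected = gamma[np.abs(np.subtract.outer(k, k)).astype(int)]
        assert cov == pytest.approx(expected, abs=1e-10)

    def test_h_half_matches_brownian_step_statistics(self):
        common = dict(n_trajectories=300, n_frames=200, seed=3,
                      localization_noise_sd=0.0)
        ts_b, _ = simulate_brownian(
            SimulationConfig(**common, regime="brownian", regime_params={"D": 0.5}))
        ts_f, _ = simulate_fbm(
            SimulationConfig(**common, regime="fbm",
                             regime_params={"D": 0.5, "hurst": 0.5}))
        var_b = np.var(np.diff(_positions(ts_b), axis=1))
        var_f = np.var(np.diff(_positions(ts_f), axis=1))
        assert var_f == pytest.approx(var_b, rel=0.05)

    def test_true_alpha_is_twice_hurst(self):
        cfg = SimulationConfig(n_trajectories=2, n_frames=20, seed=0,
                               localization_noise_sd=0.0,
                               regime="fbm", regime_params={"D": 0.5, "hurst": 0.45})
        _, labels = simulate_fbm(cfg)
        assert np.all(labels["true_alpha"] == 0.9)

    def test_subdiffusive_exponent_recovery(self):
        cfg = SimulationConfig(n_trajectories=200, n_frames=651, seed=13,
                               regime="fbm", regime_params={"D": 0.5, "hurst": 0.25})
        ts, _ = simulate_fbm(cfg)
        alphas = [s.alpha for s in analyze_set(ts)]
        assert 0.4 <= np.median(alphas) <= 0.6

    @pytest.mark.parametrize("hurst", [0.0, 1.0, -0.2, 1.5])
    def test_hurst_out_of_range_rejected(self, hurst):
        cfg = SimulationConfig(regime="fbm", regime_params={"D": 0.5, "hurst": hurst})
        with pytest.raises(ValueError):
            simulate_fbm(cfg)


class TestImmobile:
    def test_noise_free_msd_is_zero(self):
        cfg = SimulationConfig(n_trajectories=3, n_frames=40, seed=1,
                               localization_noise_sd=0.0, regime="immobile",
                               regime_params={})
        ts, _ = simulate_immobile(cfg)
        for tr in ts:
            assert np.all(compute_msd(tr, max_lag=10).msd == 0.0)

    def test_msd_plateau_at_four_sigma_squared(self):
        # independent noise at both endpoints: E[MSD] = 4·σ² at every lag
        sigma = 0.02
        cfg = SimulationConfig(n_trajectories=400, n_frames=120, seed=5,
                               localization_noise_sd=sigma, regime="immobile",
                               regime_params={})
        ts, _ = simulate_immobile(cfg)
        mean_msd = np.mean([compute_msd(tr, max_lag=10).msd for tr in ts], axis=0)
        assert np.all(np.abs(mean_msd - 4 * sigma**2) / (4 * sigma**2) < 0.10)

    def test_classified_immobile_end_to_end(self):
        cfg = SimulationConfig(n_trajectories=100, n_frames=651, seed=17,
                               regime="immobile", regime_params={})
        ts, _ = simulate_immobile(cfg)
        modes = [s.mode for s in analyze_set(ts)]
        assert modes.count("immobile") >= 90


class TestDirected:
    def test_pure_ballistic_closed_form(self):
        cfg = SimulationConfig(n_trajectories=5, n_frames=100, seed=2,
                               localization_noise_sd=0.0, regime="directed",
                               regime_params={"velocity": 1.0, "D": 0.0})
        ts, _ = simulate_directed(cfg)
        for tr in ts:
            profile = compute_msd(tr, max_lag=30)
            assert profile.msd == pytest.approx(profile.tau**2, rel=1e-9)
            from mptkit import fit_alpha
            assert fit_alpha(profile, (1, 30)).alpha == pytest.approx(2.0, abs=1e-6)

    def test_direction_is_unit_norm(self):
        cfg = SimulationConfig(n_trajectories=20, n_frames=10, seed=4,
                               regime="directed", regime_params={"velocity": 0.5})
        _, labels = simulate_directed(cfg)
        norms = np.hypot(labels["direction_x"], labels["direction_y"]).to_numpy()
        assert norms == pytest.approx(np.ones(20), abs=1e-12)

    def test_median_alpha_superdiffusive(self):
        cfg = SimulationConfig(n_trajectories=200, n_frames=651, seed=6,
                               regime="directed",
                               regime_params={"velocity": 0.5, "D": 0.01})
        ts, _ = simulate_directed(cfg)
        alphas = [s.alpha for s in analyze_set(ts)]
        assert np.median(alphas) > 1.1

    def test_nonpositive_velocity_rejected(self):
        cfg = SimulationConfig(regime="directed", regime_params={"velocity": 0.0})
        with pytest.raises(ValueError):
            simulate_directed(cfg)


class TestMixture:
    def test_component_counts_and_labels(self):
        cfg = SimulationConfig(
            n_trajectories=101, n_frames=30, seed=8, regime="mixture",
            regime_params={"components": [
                {"regime": "brownian", "fraction": 0.5, "D": 0.5},
                {"regime": "immobile", "fraction": 0.5},
            ]},
        )
        ts, labels = simulate_mixture(cfg)
        assert len(ts) == 101
        counts = labels["regime"].value_counts()
        assert sorted(counts.values) == [50, 51]
        assert len(set(labels["trajectory_id"])) == 101

    def test_every_trajectory_labeled_once(self):
        cfg = SimulationConfig(
            n_trajectories=40, n_frames=20, seed=3, regime="mixture",
            regime_params={"components": [
                {"regime": "brownian", "fraction": 0.25, "D": 1.0},
                {"regime": "directed", "fraction": 0.25, "velocity": 1.0},
                {"regime": "fbm", "fraction": 0.25, "D": 0.5, "hurst": 0.25},
                {"regime": "immobile", "fraction": 0.25},
            ]},
        )
        ts, labels = simulate_mixture(cfg)
        assert sorted(labels["trajectory_id"]) == sorted(ts.ids())


class TestNucleiImageFixture:
    def test_ground_truth_counts_by_construction(self):
        cfg = ImageSimConfig(n_nuclei=100, positive_fraction=0.4, seed=0)
        _, truth = generate_nuclei_image(cfg)
        assert truth.total_nuclei == 100
        assert truth.positive_nuclei == 40
        assert truth.percent_positive == 40.0
        assert len(truth.centroids) == 100
        assert truth.centroids["marker_positive"].sum() == 40

    def test_zero_positive_fraction_marker_is_background(self):
        cfg = ImageSimConfig(n_nuclei=50, positive_fraction=0.0,
                             background_sd=1.0, seed=1)
        image, truth = generate_nuclei_image(cfg)
        assert truth.positive_nuclei == 0
        # pure clipped-Gaussian background: nothing blob-bright
        assert image.marker.max() < 10.0

    def test_min_separation_respected(self):
        cfg = ImageSimConfig(n_nuclei=80, min_separation=15.0, seed=2)
        _, truth = generate_nuclei_image(cfg)
        pts = truth.centroids[["y", "x"]].to_numpy()
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 15.0

    def test_impossible_placement_raises(self):
        cfg = ImageSimConfig(width=64, height=64, n_nuclei=500,
                             min_separation=12.0, seed=0)
        with pytest.raises(RuntimeError, match="could not place"):
            generate_nuclei_image(cfg)

    def test_seeded_determinism(self):
        cfg = ImageSimConfig(n_nuclei=30, seed=11)
        img_a, _ = generate_nuclei_image(cfg)
        img_b, _ = generate_nuclei_image(cfg)
        assert np.array_equal(img_a.nuclear, img_b.nuclear)
        assert np.array_equal(img_a.marker, img_b.marker)


class TestAssayTableFixture:
    def test_row_count_six_by_six_triplicate(self, assay_schedule):
        table = generate_assay_table(assay_schedule, seed=0)
        nc = table[table["group"] == "NC"]
        assert len(nc) == 6 * 6 * 3

    def test_zero_noise_means_exact(self):
        schedule = [
            {"group": "NC", "timepoint": "acute", "n_slices": 2, "mean": 1.5,
             "noise_sd": 0.0},
            {"group": "TX100_acute", "timepoint": "acute", "n_slices": 1,
             "mean": 2.0, "noise_sd": 0.0},
        ]
        table = generate_assay_table(schedule, seed=5)
        assert np.all(table.loc[table["group"] == "NC", "reading"] == 1.5)
        assert np.all(table.loc[table["group"] == "TX100_acute", "reading"] == 2.0)

    def test_seeded_reproducibility(self, assay_schedule):
        a = generate_assay_table(assay_schedule, seed=3)
        b = generate_assay_table(assay_schedule, seed=3)
        assert a.equals(b)

    def test_missing_control_rejected(self):
        with pytest.raises(ValueError, match="TX100_acute"):
            generate_assay_table(
                [{"group": "NC", "timepoint": "acute", "n_slices": 2, "mean": 1.0,
                  "noise_sd": 0.0}],
                seed=0,
            )

    def test_control_flag_set(self, assay_schedule):
        table = generate_assay_table(assay_schedule, seed=0)
        assert table.loc[table["group"] == "TX100_acute", "is_control"].all()
        assert not table.loc[table["group"] == "NC", "is_control"].any()
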