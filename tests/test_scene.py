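"""Synthetic scene, scan, environment and moisture generators."""

import numpy as np
import pandas as pd
import pytest

from cwsibench import (
    CanopyScene,
    SceneParams,
    SensorSpec,
    TreatmentLayout,
    generate_canopy_scene,
    generate_environment_series,
    generate_nwsb_observations,
    simulate_ir_scan,
    simulate_soil_moisture,
    fit_nwsb,
    vpd,
)
from conftest import brute_force_scan


class TestTreatmentLayout:
    def test_regions_partition_the_bench(self):
        layout = TreatmentLayout()
        masks = layout.region_masks((10, 30))
        total = sum(m.sum() for m in masks.values())
        assert total == 300
        overlap = np.zeros((10, 30), dtype=int)
        for m in masks.values():
            overlap += m
        assert overlap.max() == 1

    def test_bad_edges_rejected(self):
        with pytest.raises(ValueError):
            TreatmentLayout(edges=(0.0, 0.5, 0.4, 1.0))
        with pytest.raises(ValueError):
            TreatmentLayout(edges=(0.1, 0.5, 0.8, 1.0))


class TestGenerateCanopyScene:
    def test_deterministic_given_seed(self):
        a = generate_canopy_scene(seed=3)
        b = generate_canopy_scene(seed=3)
        assert np.array_equal(a.rgb, b.rgb)
        assert np.array_equal(a.true_temp, b.true_temp)
        assert np.array_equal(a.truth_mask, b.truth_mask)

    def test_different_seed_differs(self):
        a = generate_canopy_scene(seed=3)
        b = generate_canopy_scene(seed=4)
        assert not np.array_equal(a.rgb, b.rgb)

    def test_zero_offsets_zero_noise_single_leaf_temperature(self):
        params = SceneParams(leaf_offsets=(0.0, 0.0, 0.0), temp_noise_sd=0.0)
        scene = generate_canopy_scene(params, seed=0)
        leaf = scene.true_temp[scene.truth_mask == 1]
        assert leaf.size > 0
        assert np.allclose(leaf, leaf[0])
        expected = params.t_air + params.nwsb_a + params.nwsb_b * vpd(
            params.t_air, params.rh
        )
        assert leaf[0] == pytest.approx(expected)

    def test_zero_density_gives_pure_soil(self):
        params = SceneParams(plant_density=0.0, temp_noise_sd=0.0)
        scene = generate_canopy_scene(params, seed=0)
        assert scene.truth_mask.sum() == 0
        assert np.allclose(scene.true_temp, params.t_air + params.soil_offset)

    def test_treatment_offsets_order_leaf_temperatures(self, quiet_scene):
        means = []
        for lab, region in quiet_scene.treatment_layout.region_masks(
            quiet_scene.shape
        ).items():
            sel = region & (quiet_scene.truth_mask == 1)
            means.append(quiet_scene.true_temp[sel].mean())
        assert means[0] < means[1] < means[2]

    def test_soil_runs_warmer_than_unstressed_leaves(self, quiet_scene):
        soil = quiet_scene.true_temp[quiet_scene.truth_mask == 0]
        t1 = quiet_scene.treatment_layout.region_masks(quiet_scene.shape)["T1"]
        leaves_t1 = quiet_scene.true_temp[t1 & (quiet_scene.truth_mask == 1)]
        assert soil.mean() > leaves_t1.mean()

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            generate_canopy_scene(SceneParams(height_px=0), seed=0)
        with pytest.raises(ValueError):
            generate_canopy_scene(SceneParams(row_spacing_mm=-1), seed=0)
        with pytest.raises(ValueError):
            generate_canopy_scene(SceneParams(leaf_offsets=(0.0, 1.0)), seed=0)

    def test_scene_invariants(self, default_scene):
        assert default_scene.rgb.dtype == np.uint8
        assert set(np.unique(default_scene.truth_mask)) <= {0, 1}
        assert default_scene.emissivity == 0.98


class TestSimulateIrScan:
    def test_constant_field_reads_constant(self, uniform_scene, noiseless_sensor):
        grid = simulate_ir_scan(uniform_scene, noiseless_sensor, seed=0)
        assert np.allclose(grid.values, uniform_scene.true_temp[0, 0])

    def test_matches_brute_force_oracle_small_scenes(self):
        rng = np.random.default_rng(42)
        for trial in range(5):
            h, w = rng.integers(24, 64, size=2)
            temp = rng.uniform(15.0, 30.0, size=(h, w))
            scene = CanopyScene(
                rgb=np.zeros((h, w, 3), dtype=np.uint8),
                true_temp=temp,
                truth_mask=np.zeros((h, w), dtype=np.uint8),
                pixel_pitch=2.5,
                treatment_layout=TreatmentLayout(),
                leaf_offsets=(0.0, 0.0, 0.0),
                t_air=22.0,
                rh=0.5,
            )
            spec = SensorSpec(
                noise_sd=0.0,
                fov_half_angle=12.0,
                grid_nx=3,
                grid_ny=2,
                cell_size=15.0,
            )
            got = simulate_ir_scan(scene, spec, seed=0)
            expected = brute_force_scan(scene, spec)
            assert np.allclose(got.values, expected, atol=1e-9)

    def test_half_soil_half_leaf_footprint(self):
        # left half at 20 degC, right half at 26 degC; footprint centered
        # on the boundary must equal the enumerated mean of covered pixels
        temp = np.full((40, 40), 20.0)
        temp[:, 20:] = 26.0
        scene = CanopyScene(
            rgb=np.zeros((40, 40, 3), dtype=np.uint8),
            true_temp=temp,
            truth_mask=np.zeros((40, 40), dtype=np.uint8),
            pixel_pitch=2.5,
            treatment_layout=TreatmentLayout(),
            leaf_offsets=(0.0, 0.0, 0.0),
            t_air=22.0,
            rh=0.5,
        )
        spec = SensorSpec(
            noise_sd=0.0, fov_half_angle=15.0, grid_nx=2, grid_ny=2, cell_size=50.0
        )
        got = simulate_ir_scan(scene, spec, seed=0)
        expected = brute_force_scan(scene, spec)
        assert np.allclose(got.values, expected, atol=1e-9)

    def test_footprint_shrinks_to_leaf_pixel(self, quiet_scene):
        """As the cone narrows, a cell converges to its center pixel."""
        # place a 1-cell grid on a leaf pixel center
        rows, cols = np.nonzero(quiet_scene.truth_mask)
        k = len(rows) // 2
        row, col = rows[k], cols[k]
        pitch = quiet_scene.pixel_pitch
        target = quiet_scene.true_temp[row, col]
        readings = []
        for half_angle in (20.0, 10.0, 3.0):
            spec = SensorSpec(
                noise_sd=0.0,
                fov_half_angle=half_angle,
                grid_nx=1,
                grid_ny=1,
                cell_size=pitch,
                origin_mm=(col * pitch, row * pitch),
            )
            grid = simulate_ir_scan(quiet_scene, spec, seed=0)
            readings.append(abs(grid.values[0, 0] - target))
        assert readings[-1] <= readings[0]
        assert readings[-1] < 1e-9  # 3 deg cone covers only the center pixel

    def test_out_of_bounds_footprint_rejected(self, default_scene):
        spec = SensorSpec(fov_half_angle=45.0, origin_mm=(0.0, 0.0))
        with pytest.raises(ValueError, match="bounds"):
            simulate_ir_scan(default_scene, spec, seed=0)

    def test_tiny_footprint_warns_and_samples_nearest(self, uniform_scene):
        spec = SensorSpec(
            noise_sd=0.0, fov_half_angle=1.0, grid_nx=2, grid_ny=2, cell_size=20.0
        )
        assert spec.footprint_radius < uniform_scene.pixel_pitch
        with pytest.warns(UserWarning, match="nearest"):
            grid = simulate_ir_scan(uniform_scene, spec, seed=0)
        assert np.allclose(grid.values, uniform_scene.true_temp[0, 0])

    def test_scan_deterministic_given_seed(self, default_scene):
        spec = SensorSpec()
        a = simulate_ir_scan(default_scene, spec, seed=9)
        b = simulate_ir_scan(default_scene, spec, seed=9)
        assert np.array_equal(a.values, b.values)


class TestEnvironmentSeries:
    def test_record_count_30_days(self):
        env = generate_environment_series(days=30, cadence_min=10, seed=0)
        assert len(env) == 4320

    def test_constant_when_amplitude_and_noise_zero(self):
        env = generate_environment_series(
            days=1, t_amplitude=0.0, rh_amplitude=0.0, t_noise_sd=0.0,
            rh_noise_sd=0.0, seed=0,
        )
        assert np.allclose(env.frame["t_air"], env.frame["t_air"].iloc[0])
        assert np.allclose(env.frame["rh"], env.frame["rh"].iloc[0])

    def test_reproducible_and_rh_bounded(self):
        a = generate_environment_series(days=3, seed=2)
        b = generate_environment_series(days=3, seed=2)
        pd.testing.assert_frame_equal(a.frame, b.frame)
        assert a.frame["rh"].between(0, 1).all()

    def test_roundtrip_csv(self, tmp_path):
        env = generate_environment_series(days=1, seed=0)
        path = tmp_path / "env.csv"
        env.to_csv(path)
        back = type(env).from_csv(path)
        assert np.allclose(back.frame["t_air"], env.frame["t_air"])


class TestNwsbObservations:
    def test_noiseless_points_on_the_line(self):
        env = generate_environment_series(days=2, seed=1)
        obs = generate_nwsb_observations(env, a=2.0, b=-1.5, noise_sd=0.0, seed=0)
        assert np.allclose(obs["dt"], 2.0 - 1.5 * obs["vpd"])

    def test_grape_coefficients_recovered_within_3se(self):
        env = generate_environment_series(days=30, seed=8)
        obs = generate_nwsb_observations(env, a=2.54, b=-1.71, noise_sd=0.3, seed=9)
        model = fit_nwsb(obs["dt"], obs["vpd"])
        assert abs(model.a - 2.54) < 3 * model.se_a
        assert abs(model.b - (-1.71)) < 3 * model.se_b

    def test_saturated_air_gives_intercept_only(self):
        frame = pd.DataFrame(
            {
                "timestamp": pd.date_range("2023-01-01", periods=10, freq="10min"),
                "t_air": np.full(10, 22.0),
                "rh": np.ones(10),
            }
        )
        env = type(generate_environment_series(days=1, seed=0))(frame)
        obs = generate_nwsb_observations(env, a=2.54, b=-1.71, noise_sd=0.0, seed=0)
        assert np.allclose(obs["vpd"], 0.0)
        assert np.allclose(obs["dt"], 2.54)


class TestSoilMoisture:
    def test_zero_drydown_flat_no_events(self):
        ms = simulate_soil_moisture(days=5, drydown_per_day=0.0, seed=0)
        assert len(ms.events) == 0
        for lab in ("T1", "T2", "T3"):
            assert np.allclose(ms.frame[lab], ms.frame[lab].iloc[0])

    def test_first_crossing_matches_closed_form(self):
        # start 0.97, threshold 0.85, rate 0.06/day -> crossing at 2 days;
        # with 20-min sampling the event lands on the first step at/after it
        ms = simulate_soil_moisture(
            days=5,
            thresholds=(0.85, 0.75, 0.55),
            drydown_per_day=0.06,
            start_vwc=0.97,
            cadence_min=20,
            seed=0,
        )
        t1_events = ms.events[ms.events["treatment"] == "T1"]
        first = pd.to_datetime(t1_events["timestamp"].iloc[0])
        start = pd.to_datetime(ms.frame["timestamp"].iloc[0])
        crossing_days = (0.97 - 0.85) / 0.06
        elapsed = (first - start).total_seconds() / 86400.0 + 20 / (24 * 60)
        assert elapsed == pytest.approx(crossing_days, abs=20 / (24 * 60))

    def test_threshold_ordering_of_means(self):
        ms = simulate_soil_moisture(days=30, seed=1)
        assert ms.frame["T1"].mean() >= ms.frame["T2"].mean() >= ms.frame["T3"].mean()

    def test_events_triggered_at_or_below_threshold(self):
        ms = simulate_soil_moisture(days=20, seed=2)
        for _, ev in ms.events.iterrows():
            assert ev["vwc_at_trigger"] <= ms.thresholds[ev["treatment"]]

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            simulate_soil_moisture(days=2, thresholds=(1.2, 0.7, 0.5), seed=0)
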