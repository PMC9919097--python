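import numpy as np
import pytest

from cwsibench import (
    SceneParams,
    SensorSpec,
    generate_canopy_scene,
    generate_environment_series,
    generate_nwsb_observations,
    fit_nwsb,
)


@pytest.fixture(scope="session")
def default_scene():
    return generate_canopy_scene(seed=11)


@pytest.fixture(scope="session")
def quiet_scene():
    """Zero-noise scene with distinct per-treatment leaf offsets."""
    params = SceneParams(temp_noise_sd=0.0, leaf_offsets=(0.0, 1.0, 2.0))
    return generate_canopy_scene(params, seed=11)


@pytest.fixture(scope="session")
def uniform_scene():
    """Scene whose true temperature field is a single constant."""
    params = SceneParams(
        temp_noise_sd=0.0,
        leaf_offsets=(0.0, 0.0, 0.0),
        soil_offset=0.0,
        nwsb_a=0.0,
        nwsb_b=0.0,
    )
    return generate_canopy_scene(params, seed=7)


@pytest.fixture(scope="session")
def noiseless_sensor():
    return SensorSpec(noise_sd=0.0)


@pytest.fixture(scope="session")
def fitted_model():
    env = generate_environment_series(days=30, seed=5)
    obs = generate_nwsb_observations(env, a=2.54, b=-1.71, noise_sd=0.3, seed=6)
    return fit_nwsb(obs["dt"], obs["vpd"])


def brute_force_scan(scene, spec):
    """Independent footprint-averaging oracle: explicit pixel loop."""
    pitch = scene.pixel_pitch
    h, w = scene.shape
    r = spec.footprint_radius
    if spec.origin_mm is None:
        ox = (w * pitch - spec.grid_nx * spec.cell_size) / 2.0
        oy = (h * pitch - spec.grid_ny * spec.cell_size) / 2.0
    else:
        ox, oy = spec.origin_mm
    out = np.empty((spec.grid_ny, spec.grid_nx))
    for j in range(spec.grid_ny):
        for i in range(spec.grid_nx):
            xc = ox + (i + 0.5) * spec.cell_size
            yc = oy + (j + 0.5) * spec.cell_size
            acc, n = 0.0, 0
            for row in range(h):
                py = (row + 0.5) * pitch
                if abs(py - yc) > r:
                    continue
                for col in range(w):
                    px = (col + 0.5) * pitch
                    if (px - xc) ** 2 + (py - yc) ** 2 <= r * r:
                        acc += scene.true_temp[row, col]
                        n += 1
            out[j, i] = acc / n if n else np.nan
    return out
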