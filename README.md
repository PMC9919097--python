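# cwsibench

Crop-water-stress mapping for low-cost bench phenotyping: excess-green
plant segmentation, scanned-infrared thermal maps, leaf-temperature-map
fusion, non-water-stressed-baseline CWSI, and EWMA stability monitoring —
with a synthetic bench-scene simulator that supplies ground truth for
every stage.

## The problem

Water stress closes stomata, cuts transpiration, and warms leaves
relative to the air. The **Crop Water Stress Index** turns this into a
0–1 score by normalizing the canopy–air temperature difference between
the limits of a fully transpiring and a non-transpiring canopy:

    CWSI = (dT − dT_LL) / (dT_UL − dT_LL),    dT = T_L − T_A,

where 0 means no water restriction and 1 means no transpiration.
Thermal cameras that resolve T_L per pixel are expensive; an alternative
is a cheap scanning IR thermometer that reads one coarse "object
temperature" per 20 mm grid cell, fused with an RGB image that says
*where the plants are*:

1. **Segmentation** — the excess-green index `ExG = 2g − r − b` on
   chromaticity-normalized channels separates green canopy from soil
   with a single threshold (Otsu by default).
2. **Thermal map** — the scanned grid of object temperatures is
   bilinearly upsampled; the plant mask is nearest-neighbour resampled
   to the same geometry; their pixel-wise crossing keeps temperatures
   only where there is plant: the **Leaf Temperature Map** (LTM).
3. **Baseline** — well-watered plants obey the linear
   **non-water-stressed baseline** `dT = a + b·VPD` (vapor pressure
   deficit in kPa, `VPD = (1 − RH)·0.6108·10^(7.5T/(273.3+T))`). The
   lower CWSI limit is the baseline at the ambient VPD; the upper limit
   follows from the potential-VPD construction at zero ambient VPD.
   An empirical alternative uses wet (sprayed) and dry
   (petroleum-jelly-coated) reference leaves as the two limits.
4. **Monitoring** — daily per-treatment CWSI means and soil-moisture
   traces are charted with exponentially weighted moving averages
   (λ = 0.2, L = 3) to judge process stability over a growing cycle.

Because no public dataset accompanies this measurement protocol, the
package ships a first-class synthetic scene generator: row-planted
elliptical leaves over soil on a 1.22 m × 0.44 m scanned bench area,
a co-registered true temperature field (soil warmer than unstressed
leaves), a conical-FoV scanning sensor model, diurnal ambient series,
and threshold-triggered irrigation of three treatments at 85 / 75 / 55 %
of field capacity. Every downstream stage is therefore testable against
exact ground truth.

## Worked example

```python
from cwsibench import (
    SceneParams, SensorSpec, generate_canopy_scene, simulate_ir_scan,
    excess_green, segment_exg, confusion, metrics, build_ltm,
    generate_environment_series, generate_nwsb_observations, fit_nwsb,
    lower_limit, upper_limit, vpd, stress_map, treatment_summary,
)

params = SceneParams(leaf_offsets=(0.0, 1.0, 2.0))   # imposed stress ladder
scene = generate_canopy_scene(params, seed=1)
grid = simulate_ir_scan(scene, SensorSpec(), seed=2)

mask = segment_exg(excess_green(scene.rgb))
m = metrics(confusion(mask, scene.truth_mask))

env = generate_environment_series(days=30, seed=3)
obs = generate_nwsb_observations(env, a=2.54, b=-1.71, noise_sd=0.3, seed=4)
model = fit_nwsb(obs["dt"], obs["vpd"])

ltm = build_ltm(grid, mask, scene.shape)
smap = stress_map(ltm, t_air=scene.t_air, model=model, rh=scene.rh)
print(treatment_summary(smap, scene.treatment_layout).table)
```

prints

```
segmentation F-score: 0.9876  accuracy: 0.9972
NWSB: dT = 2.552 + (-1.720) * VPD   (n=4320, R^2=0.827)
VPD at T_A=22.1 C, RH=0.47: 1.178 kPa
limits: LL=0.525 C   UL=3.113 C
treatment  mean_cwsi  min_cwsi  max_cwsi  n_pixels
       T1     0.3358    0.0000    0.9124      3277
       T2     0.5754    0.1552    0.9983      3140
       T3     0.8509    0.6740    1.0000      3148
```

Reading the output: segmentation recovers the true plant mask almost
perfectly; the baseline fit recovers the generating coefficients
(a = 2.54, b = −1.71) from a noisy 30-day, 10-minute series; and the
per-treatment mean CWSI rises strictly with the imposed leaf-temperature
offsets (0, +1, +2 °C). Treatment 1's mean sits above zero because
coarse scan cells mix warm soil into leaf readings — the characteristic
bias of the low-cost sensor geometry, which shrinks with a finer scan
grid and narrower field of view.

## Command line

```bash
cwsibench run-all --outdir out/ --seed 1          # all six stages + manifest
cwsibench simulate-scene --outdir out/ --seed 1
cwsibench segment out/scene_rgb.png --reference-mask out/truth_mask.csv --outdir seg/
cwsibench fit-nwsb out/nwsb_observations.csv --out model.json
cwsibench monitor out/moisture.csv --column T1 --out chart.json
```

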