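"""Synthetic bench scenes with co-registered ground truth.

Emulates an indoor cultivation bench (default 1.50 m x 0.75 m) of
row-planted small-leaf plants over soil: an 8-bit RGB canopy image, the
true surface-temperature field, the exact plant mask, a three-treatment
column layout, a scanning IR thermometer with a conical field of view,
diurnal ambient series, and threshold-triggered soil-moisture traces.

Every generator takes an explicit seed and is deterministic given it.

Ground-truth temperature model: soil pixels sit at ``T_A + soil_offset``;
leaf pixels at ``T_A + a + b*VPD(T_A, RH) + treatment_offset + noise``,
i.e. unstressed leaves follow the non-water-stressed baseline and
stressed treatments are warmed by an additive offset.  Soil runs warmer
than leaves by default, as mixed scan footprints then behave like the
real bench (soil-contaminated readings biased high).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skimage.draw import ellipse

from .baseline import vpd
from .thermal import ThermalGrid

__all__ = [
    "TreatmentLayout",
    "CanopyScene",
    "SceneParams",
    "SensorSpec",
    "EnvironmentSeries",
    "MoistureSeries",
    "generate_canopy_scene",
    "simulate_ir_scan",
    "generate_environment_series",
    "generate_nwsb_observations",
    "simulate_soil_moisture",
]


@dataclass(frozen=True)
class TreatmentLayout:
    """Partition of image columns into labelled treatment bands.

    ``edges`` are fractional column boundaries in [0, 1]; band *i* spans
    ``[edges[i], edges[i+1])`` of the width.  Bands are disjoint and
    cover the bench by construction.
    """

    labels: tuple = ("T1", "T2", "T3")
    edges: tuple = (0.0, 1 / 3, 2 / 3, 1.0)

    def __post_init__(self):
        if len(self.edges) != len(self.labels) + 1:
            raise ValueError("need len(labels) + 1 edges")
        if self.edges[0] != 0.0 or self.edges[-1] != 1.0:
            raise ValueError("edges must start at 0 and end at 1")
        if any(b <= a for a, b in zip(self.edges, self.edges[1:])):
            raise ValueError("edges must be strictly increasing")

    def column_slices(self, width: int) -> dict:
        """Column slice per treatment for a raster of the given width."""
        cuts = [round(e * width) for e in self.edges]
        return {
            lab: slice(cuts[i], cuts[i + 1]) for i, lab in enumerate(self.labels)
        }

    def region_masks(self, shape) -> dict:
        h, w = shape
        out = {}
        for lab, sl in self.column_slices(w).items():
            m = np.zeros(shape, dtype=bool)
            m[:, sl] = True
            out[lab] = m
        return out


@dataclass
class CanopyScene:
    """A synthetic bench scene with exact ground truth.

    ``rgb`` (H, W, 3) uint8; ``true_temp`` (H, W) degC; ``truth_mask``
    (H, W) in {0, 1} marking exactly the leaf pixels.  ``pixel_pitch``
    is the physical pixel size in mm.  ``emissivity`` is carried as
    instrument metadata only and never alters simulated readings.
    """

    rgb: np.ndarray
    true_temp: np.ndarray
    truth_mask: np.ndarray
    pixel_pitch: float
    treatment_layout: TreatmentLayout
    leaf_offsets: tuple
    t_air: float
    rh: float
    emissivity: float = 0.98

    def __post_init__(self):
        if self.rgb.shape[:2] != self.true_temp.shape or (
            self.true_temp.shape != self.truth_mask.shape
        ):
            raise ValueError("rgb, true_temp and truth_mask must share H x W")
        if not set(np.unique(self.truth_mask)) <= {0, 1}:
            raise ValueError("truth_mask must be binary")
        if not 0.0 < self.emissivity <= 1.0:
            raise ValueError("emissivity must lie in (0, 1]")

    @property
    def shape(self):
        return self.true_temp.shape

    @property
    def extent_mm(self):
        """(width_mm, height_mm) of the bench."""
        h, w = self.shape
        return (w * self.pixel_pitch, h * self.pixel_pitch)

    def save_rgb(self, path) -> None:
        from PIL import Image

        Image.fromarray(self.rgb).save(path)

    def save_rasters(self, temp_path, mask_path) -> None:
        """Write true_temp and truth_mask as headered CSV rasters."""
        h, w = self.shape
        header = f"# rows={h} cols={w} pixel_pitch_mm={self.pixel_pitch}\n"
        for path, arr, fmt in (
            (temp_path, self.true_temp, "%.6f"),
            (mask_path, self.truth_mask, "%d"),
        ):
            with open(path, "w") as fh:
                fh.write(header)
                np.savetxt(fh, arr, fmt=fmt, delimiter=",")


@dataclass(frozen=True)
class SceneParams:
    """Generator parameters for a bench scene.

    Geometry defaults to the scanned experimental area of the bench,
    1.22 m x 0.44 m at 2.5 mm/pixel (exactly the span of the default
    61 x 22 grid of 20 mm scan cells, so image and thermal map are
    co-extensive and resize-and-overlay fusion is registered), with
    0.20 m row spacing and 0.05 m in-row plant spacing.  The leaf
    temperature model defaults to a grape-type baseline
    (a = 2.54 degC, b = -1.71 degC/kPa).
    """

    height_px: int = 176
    width_px: int = 488
    pixel_pitch_mm: float = 2.5
    row_spacing_mm: float = 200.0
    plant_spacing_mm: float = 50.0
    leaf_length_mm: float = 36.0
    leaf_width_mm: float = 18.0
    leaf_size_rel_sd: float = 0.15
    leaves_per_plant: int = 8
    plant_density: float = 1.0
    plant_color: tuple = (45, 110, 40)
    soil_color: tuple = (120, 90, 62)
    plant_color_sd: float = 12.0
    soil_color_sd: float = 8.0
    t_air: float = 22.1
    rh: float = 0.47
    nwsb_a: float = 2.54
    nwsb_b: float = -1.71
    soil_offset: float = 3.0
    leaf_offsets: tuple = (0.0, 1.0, 2.0)
    temp_noise_sd: float = 0.2
    emissivity: float = 0.98
    treatment_layout: TreatmentLayout = field(default_factory=TreatmentLayout)


def generate_canopy_scene(params: SceneParams = SceneParams(), seed: int = 0) -> CanopyScene:
    """Draw a bench scene: elliptical leaves over soil, with ground truth.

    Leaves are overlapping ellipses with Gaussian-perturbed size,
    orientation and green color; soil is a Gaussian-perturbed brown
    background.  The truth mask marks exactly the drawn leaf pixels.
    """
    p = params
    if p.height_px <= 0 or p.width_px <= 0:
        raise ValueError("image dimensions must be positive")
    if p.row_spacing_mm <= 0 or p.plant_spacing_mm <= 0 or p.pixel_pitch_mm <= 0:
        raise ValueError("spacings and pixel pitch must be positive")
    if not 0.0 <= p.plant_density <= 1.0:
        raise ValueError("plant_density must lie in [0, 1]")
    if len(p.leaf_offsets) != len(p.treatment_layout.labels):
        raise ValueError("one leaf offset per treatment is required")

    rng = np.random.default_rng(seed)
    h, w = p.height_px, p.width_px

    rgb = np.clip(
        rng.normal(loc=p.soil_color, scale=p.soil_color_sd, size=(h, w, 3)),
        0,
        255,
    ).astype(np.uint8)
    mask = np.zeros((h, w), dtype=np.uint8)

    row_step = p.row_spacing_mm / p.pixel_pitch_mm
    plant_step = p.plant_spacing_mm / p.pixel_pitch_mm
    leaf_r = p.leaf_length_mm / (2 * p.pixel_pitch_mm)
    leaf_c = p.leaf_width_mm / (2 * p.pixel_pitch_mm)

    row_centers = np.arange(row_step / 2, h, row_step)
    col_centers = np.arange(plant_step / 2, w, plant_step)
    for rc in row_centers:
        for cc in col_centers:
            if p.plant_density < 1.0 and rng.random() >= p.plant_density:
                continue
            if p.plant_density == 0.0:
                continue
            for _ in range(p.leaves_per_plant):
                jitter = rng.normal(0.0, leaf_c / 2, size=2)
                size = rng.normal(1.0, p.leaf_size_rel_sd, size=2).clip(0.4, 1.8)
                rr, cx = ellipse(
                    rc + jitter[0],
                    cc + jitter[1],
                    max(leaf_r * size[0], 1.0),
                    max(leaf_c * size[1], 1.0),
                    rotation=rng.uniform(0, np.pi),
                    shape=(h, w),
                )
                mask[rr, cx] = 1
                color = np.clip(
                    rng.normal(p.plant_color, p.plant_color_sd), 0, 255
                )
                rgb[rr, cx] = color.astype(np.uint8)

    # pixel-level color speckle on leaves so ExG sees a distribution
    leaf_idx = mask.astype(bool)
    if leaf_idx.any() and p.plant_color_sd > 0:
        speckle = rng.normal(0.0, p.plant_color_sd / 3, size=(int(leaf_idx.sum()), 3))
        rgb[leaf_idx] = np.clip(rgb[leaf_idx] + speckle, 0, 255).astype(np.uint8)

    dt_baseline = p.nwsb_a + p.nwsb_b * vpd(p.t_air, p.rh)
    temp = np.full((h, w), p.t_air + p.soil_offset, dtype=float)
    offsets = np.zeros((h, w))
    for lab, region in p.treatment_layout.region_masks((h, w)).items():
        offsets[region] = p.leaf_offsets[p.treatment_layout.labels.index(lab)]
    leaf_temp = p.t_air + dt_baseline + offsets
    if p.temp_noise_sd > 0:
        leaf_temp = leaf_temp + rng.normal(0.0, p.temp_noise_sd, size=(h, w))
    temp[leaf_idx] = leaf_temp[leaf_idx]

    return CanopyScene(
        rgb=rgb,
        true_temp=temp,
        truth_mask=mask,
        pixel_pitch=p.pixel_pitch_mm,
        treatment_layout=p.treatment_layout,
        leaf_offsets=tuple(p.leaf_offsets),
        t_air=p.t_air,
        rh=p.rh,
        emissivity=p.emissivity,
    )


@dataclass(frozen=True)
class SensorSpec:
    """Scanning IR thermometer geometry and noise.

    The footprint on the canopy is a disc of radius
    ``height_above_canopy * tan(fov_half_angle)``.  The bare sensor has
    a 90-degree cone (half angle 45); the default half angle of 10
    degrees models the collimator tube that narrows the beam so a
    reading resolves individual plant rows.  ``noise_sd`` of
    0.25 degC keeps ~95% of readings within the +/-0.5 degC instrument
    precision.  ``grid_nx x grid_ny`` cells of ``cell_size`` mm default
    to the 61 x 22 map of 20 mm cells; ``origin_mm`` (x, y) places the
    grid on the bench, or None to center it.
    """

    height_above_canopy: float = 50.0
    fov_half_angle: float = 10.0
    noise_sd: float = 0.25
    grid_nx: int = 61
    grid_ny: int = 22
    cell_size: float = 20.0
    origin_mm: tuple | None = None

    def __post_init__(self):
        if self.footprint_radius <= 0:
            raise ValueError("footprint radius must be positive")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.grid_nx < 1 or self.grid_ny < 1:
            raise ValueError("grid dimensions must be at least 1")

    @property
    def footprint_radius(self) -> float:
        return self.height_above_canopy * np.tan(np.deg2rad(self.fov_half_angle))


def simulate_ir_scan(
    scene: CanopyScene, spec: SensorSpec = SensorSpec(), seed: int = 0
) -> ThermalGrid:
    """Simulate one scan of the bench: a soil/plant thermal map.

    Each cell's object temperature is the mean of the true temperature
    field over the circular field-of-view footprint centered on the cell
    (membership by pixel center inside the disc), plus Gaussian sensor
    noise.  Cells may cover plant only, soil only, or a mixture.

    Raises if any footprint extends beyond the bench.  If the footprint
    radius is smaller than one image pixel, sampling degrades to the
    nearest pixel with a warning.
    """
    pitch = scene.pixel_pitch
    h, w = scene.shape
    width_mm, height_mm = w * pitch, h * pitch
    r = spec.footprint_radius

    span_x = spec.grid_nx * spec.cell_size
    span_y = spec.grid_ny * spec.cell_size
    if spec.origin_mm is None:
        ox, oy = (width_mm - span_x) / 2.0, (height_mm - span_y) / 2.0
    else:
        ox, oy = spec.origin_mm

    cx = ox + (np.arange(spec.grid_nx) + 0.5) * spec.cell_size
    cy = oy + (np.arange(spec.grid_ny) + 0.5) * spec.cell_size
    if (
        cx.min() - r < 0
        or cx.max() + r > width_mm
        or cy.min() - r < 0
        or cy.max() + r > height_mm
    ):
        raise ValueError(
            "scan grid footprint extends beyond the scene bounds; shrink the "
            "grid, the field of view, or move the origin"
        )

    nearest_only = r < pitch
    if nearest_only:
        warnings.warn(
            "footprint radius smaller than one image pixel; degrading to "
            "nearest-pixel sampling",
            stacklevel=2,
        )

    px_x = (np.arange(w) + 0.5) * pitch
    px_y = (np.arange(h) + 0.5) * pitch
    values = np.empty((spec.grid_ny, spec.grid_nx), dtype=float)
    r2 = r * r
    for j, yc in enumerate(cy):
        for i, xc in enumerate(cx):
            if nearest_only:
                col = int(np.clip(xc / pitch, 0, w - 1))
                row = int(np.clip(yc / pitch, 0, h - 1))
                values[j, i] = scene.true_temp[row, col]
                continue
            c0 = np.searchsorted(px_x, xc - r)
            c1 = np.searchsorted(px_x, xc + r, side="right")
            r0 = np.searchsorted(px_y, yc - r)
            r1 = np.searchsorted(px_y, yc + r, side="right")
            dx = px_x[c0:c1] - xc
            dy = px_y[r0:r1] - yc
            inside = dy[:, None] ** 2 + dx[None, :] ** 2 <= r2
            if not inside.any():  # radius >= pitch guarantees coverage, but be safe
                col = int(np.clip(xc / pitch, 0, w - 1))
                row = int(np.clip(yc / pitch, 0, h - 1))
                values[j, i] = scene.true_temp[row, col]
            else:
                values[j, i] = scene.true_temp[r0:r1, c0:c1][inside].mean()

    if spec.noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, spec.noise_sd, size=values.shape)

    return ThermalGrid(
        values=values,
        cell_size=spec.cell_size,
        origin_mm=(ox, oy),
        t_air=scene.t_air,
        rh=scene.rh,
    )


@dataclass
class EnvironmentSeries:
    """Ambient temperature / relative humidity series at fixed cadence."""

    frame: pd.DataFrame  # columns: timestamp, t_air, rh

    def __post_init__(self):
        ts = pd.to_datetime(self.frame["timestamp"])
        if not ts.is_monotonic_increasing or ts.duplicated().any():
            raise ValueError("timestamps must be strictly increasing")
        rh = self.frame["rh"].to_numpy()
        if np.any(rh < 0) or np.any(rh > 1):
            raise ValueError("RH must be a fraction in [0, 1]")

    def __len__(self):
        return len(self.frame)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "EnvironmentSeries":
        return cls(pd.read_csv(path, parse_dates=["timestamp"]))


def generate_environment_series(
    days: int = 30,
    cadence_min: int = 10,
    t_mean: float = 22.0,
    t_amplitude: float = 4.0,
    rh_mean: float = 0.60,
    rh_amplitude: float = 0.15,
    t_noise_sd: float = 0.3,
    rh_noise_sd: float = 0.02,
    seed: int = 0,
    start: str = "2023-01-01",
) -> EnvironmentSeries:
    """Sinusoidal diurnal T_A / RH cycles plus noise, RH clipped to [0, 1].

    Temperature peaks at 14:00 and RH runs in anti-phase.  The default
    30 days at 10-minute cadence gives 4320 records.
    """
    if days < 1:
        raise ValueError("days must be at least 1")
    n = days * 24 * 60 // cadence_min
    rng = np.random.default_rng(seed)
    ts = pd.date_range(start=start, periods=n, freq=f"{cadence_min}min")
    hour = ts.hour + ts.minute / 60.0
    phase = np.sin(2 * np.pi * (hour - 8.0) / 24.0)
    t_air = t_mean + t_amplitude * phase + rng.normal(0, t_noise_sd, n)
    rh = np.clip(
        rh_mean - rh_amplitude * phase + rng.normal(0, rh_noise_sd, n), 0.0, 1.0
    )
    return EnvironmentSeries(
        pd.DataFrame({"timestamp": ts, "t_air": t_air, "rh": rh})
    )


def generate_nwsb_observations(
    env: EnvironmentSeries,
    a: float = 2.54,
    b: float = -1.71,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Paired (dT, VPD) observations from well-watered plants.

    VPD is computed per record from the ambient series and
    dT = a + b*VPD + Gaussian noise.  Returns a frame with columns
    timestamp, t_air, rh, vpd, dt.
    """
    if len(env) == 0:
        raise ValueError("environment series is empty")
    rng = np.random.default_rng(seed)
    frame = env.frame.copy()
    frame["vpd"] = vpd(frame["t_air"].to_numpy(), frame["rh"].to_numpy())
    frame["dt"] = (
        a + b * frame["vpd"].to_numpy() + rng.normal(0.0, noise_sd, len(frame))
    )
    return frame


@dataclass
class MoistureSeries:
    """Per-treatment soil moisture normalized to field capacity.

    ``frame`` holds one column per treatment (fraction of FC);
    ``events`` logs each irrigation (timestamp, treatment, vwc at
    trigger, applied volume in liters).
    """

    frame: pd.DataFrame
    events: pd.DataFrame
    thresholds: dict
    cadence_min: int = 20
    volume_l: float = 0.7

    def __post_init__(self):
        cols = [c for c in self.frame.columns if c != "timestamp"]
        if (self.frame[cols].to_numpy() <= 0).any():
            raise ValueError("VWC must be positive")

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def simulate_soil_moisture(
    days: int = 30,
    thresholds: tuple = (0.85, 0.75, 0.55),
    labels: tuple = ("T1", "T2", "T3"),
    drydown_per_day: float | tuple = 0.05,
    recharge: float = 0.10,
    start_vwc: float = 0.95,
    cadence_min: int = 20,
    noise_sd: float = 0.0,
    volume_l: float = 0.7,
    seed: int = 0,
) -> MoistureSeries:
    """Sawtooth drydown/irrigation traces for the three treatments.

    Moisture declines at ``drydown_per_day`` (fraction of FC per day);
    whenever a trace reaches its treatment threshold from above, a fixed
    0.7 L irrigation event is logged and the trace recharges by
    ``recharge`` of FC.  With equal drydown rates the long-run means are
    ordered like the thresholds (T1 >= T2 >= T3).
    """
    if any(not 0.0 < t < 1.0 for t in thresholds):
        raise ValueError("thresholds must lie in (0, 1)")
    rates = (
        tuple(drydown_per_day)
        if np.ndim(drydown_per_day)
        else (drydown_per_day,) * len(thresholds)
    )
    rng = np.random.default_rng(seed)
    n = days * 24 * 60 // cadence_min
    dt_days = cadence_min / (24.0 * 60.0)
    ts = pd.date_range(start="2023-01-01", periods=n, freq=f"{cadence_min}min")

    traces = {}
    events = []
    for lab, thr, rate in zip(labels, thresholds, rates):
        v = start_vwc
        col = np.empty(n)
        for k in range(n):
            v = v - rate * dt_days
            if noise_sd > 0:
                v += rng.normal(0.0, noise_sd)
            if v <= thr:
                events.append(
                    {
                        "timestamp": ts[k],
                        "treatment": lab,
                        "vwc_at_trigger": v,
                        "volume_l": volume_l,
                    }
                )
                v += recharge
            col[k] = v
        traces[lab] = col

    events_df = pd.DataFrame(
        events, columns=["timestamp", "treatment", "vwc_at_trigger", "volume_l"]
    )
    frame = pd.DataFrame({"timestamp": ts, **traces})
    return MoistureSeries(
        frame=frame,
        events=events_df,
        thresholds=dict(zip(labels, thresholds)),
        cadence_min=cadence_min,
        volume_l=volume_l,
    )
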