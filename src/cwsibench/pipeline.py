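"""End-to-end orchestration: simulate -> segment -> fuse -> index -> monitor.

`run_pipeline` executes the whole workflow from a :class:`RunConfig`,
writing every intermediate artifact plus a manifest (seed, parameter
echo, per-stage timing) so a rerun with the same config is bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .baseline import (
    NWSBModel,
    ReferenceTemperatures,
    fit_nwsb_series,
    lower_limit,
    upper_limit,
    vpd,
)
from .cwsi import clip_cwsi, stress_map, treatment_summary
from .monitoring import is_stable, joint_cycle_report
from .scene import (
    SceneParams,
    SensorSpec,
    generate_canopy_scene,
    generate_environment_series,
    generate_nwsb_observations,
    simulate_ir_scan,
    simulate_soil_moisture,
)
from .segmentation import confusion, excess_green, metrics, segment_exg
from .thermal import build_ltm

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "daily_stress_cycle"]

STAGES = ("simulate", "segment", "thermal-map", "fit-nwsb", "cwsi-map", "monitor")


@dataclass
class RunConfig:
    """Parameters for a full synthetic-bench run.

    ``stress_coupling`` converts soil-moisture deficit into the imposed
    leaf warming: daily leaf offset = coupling * (1 - VWC/FC), degC.
    """

    seed: int = 0
    days: int = 30
    scene: dict = field(default_factory=dict)
    sensor: dict = field(default_factory=dict)
    segmentation_method: str = "otsu"
    segmentation_threshold: float | None = None
    ltm_dims: tuple = (310, 620)
    nwsb_env_tag: str = "protected"
    nwsb_noise_sd: float = 0.3
    cwsi_method: str = "nwsb"
    t_wet: float | None = None
    t_dry: float | None = None
    ewma_lambda: float = 0.2
    ewma_L: float = 3.0
    stress_coupling: float = 8.0
    moisture: dict = field(default_factory=dict)

    def __post_init__(self):
        self.ltm_dims = tuple(self.ltm_dims)
        self.validate()

    def validate(self) -> None:
        """Pre-flight check that every stage's inputs are complete."""
        if self.cwsi_method not in ("nwsb", "empirical"):
            raise ValueError(f"unknown cwsi method {self.cwsi_method!r}")
        if self.cwsi_method == "empirical" and (
            self.t_wet is None or self.t_dry is None
        ):
            raise ValueError(
                "cwsi_method='empirical' requires t_wet and t_dry reference "
                "temperatures in the config"
            )
        if self.segmentation_method == "fixed" and self.segmentation_threshold is None:
            raise ValueError("segmentation_method='fixed' requires a threshold")
        if self.days < 1:
            raise ValueError("days must be at least 1")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def daily_stress_cycle(
    moisture_frame: pd.DataFrame,
    model: NWSBModel,
    t_air: float,
    rh: float,
    coupling: float = 8.0,
):
    """Per-treatment daily CWSI and normalized-moisture series.

    Daily mean soil moisture drives the imposed leaf warming
    (coupling * deficit), which is converted to CWSI with the scan-level
    baseline limits and clipped.  Returns (cwsi_df, vwc_df) indexed by
    day - the inputs of the EWMA cycle report.
    """
    ts = pd.to_datetime(moisture_frame["timestamp"])
    cols = [c for c in moisture_frame.columns if c != "timestamp"]
    daily_vwc = moisture_frame.groupby(ts.dt.date)[cols].mean()
    ll = lower_limit(model, vpd(t_air, rh))
    ul = upper_limit(model, t_air)
    dt = ll + coupling * (1.0 - daily_vwc)
    raw = (dt - ll) / (ul - ll)
    cwsi_df = raw.apply(lambda col: clip_cwsi(col.to_numpy())[0])
    return cwsi_df, daily_vwc


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run all six stages and return the manifest (also written to disk)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.validate()
    rng_seed = int(config.seed)
    manifest = {
        "version": __version__,
        "seed": rng_seed,
        "config": config.to_dict(),
        "stages": [],
    }

    def record(stage, artifacts, t0):
        manifest["stages"].append(
            {
                "name": stage,
                "artifacts": [str(a) for a in artifacts],
                "seconds": round(time.perf_counter() - t0, 3),
            }
        )
        logger.info("stage %s done (%.2fs)", stage, time.perf_counter() - t0)

    # --- simulate -----------------------------------------------------
    t0 = time.perf_counter()
    try:
        scene_params = SceneParams(**config.scene)
        sensor = SensorSpec(**config.sensor)
        scene = generate_canopy_scene(scene_params, seed=rng_seed)
        grid = simulate_ir_scan(scene, sensor, seed=rng_seed + 1)
        env = generate_environment_series(days=config.days, seed=rng_seed + 2)
        moisture = simulate_soil_moisture(
            days=config.days, seed=rng_seed + 3, **config.moisture
        )
        scene.save_rgb(outdir / "scene_rgb.png")
        scene.save_rasters(outdir / "true_temp.csv", outdir / "truth_mask.csv")
        grid.to_csv(outdir / "thermal_grid.csv")
        env.to_csv(outdir / "environment.csv")
        moisture.to_csv(outdir / "moisture.csv")
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc
    record(
        "simulate",
        ["scene_rgb.png", "true_temp.csv", "truth_mask.csv", "thermal_grid.csv",
         "environment.csv", "moisture.csv"],
        t0,
    )

    # --- segment ------------------------------------------------------
    t0 = time.perf_counter()
    try:
        exg = excess_green(scene.rgb)
        mask = segment_exg(
            exg,
            method=config.segmentation_method,
            threshold=config.segmentation_threshold,
        )
        seg_metrics = metrics(confusion(mask, scene.truth_mask))
        from PIL import Image

        Image.fromarray((mask * 255).astype(np.uint8)).save(outdir / "mask.png")
        (outdir / "segmentation_metrics.json").write_text(
            json.dumps(seg_metrics.to_dict(), indent=2)
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'segment' failed: {exc}") from exc
    record("segment", ["mask.png", "segmentation_metrics.json"], t0)

    # --- thermal-map --------------------------------------------------
    t0 = time.perf_counter()
    try:
        ltm = build_ltm(grid, mask, target_dims=config.ltm_dims)
        ltm.to_csv(outdir / "ltm.csv")
    except Exception as exc:
        raise RuntimeError(f"stage 'thermal-map' failed: {exc}") from exc
    record("thermal-map", ["ltm.csv"], t0)

    # --- fit-nwsb -----------------------------------------------------
    t0 = time.perf_counter()
    try:
        obs = generate_nwsb_observations(
            env,
            a=scene_params.nwsb_a,
            b=scene_params.nwsb_b,
            noise_sd=config.nwsb_noise_sd,
            seed=rng_seed + 4,
        )
        obs.to_csv(outdir / "nwsb_observations.csv", index=False)
        model = fit_nwsb_series(obs, env_tag=config.nwsb_env_tag, daily_mean=False)
        (outdir / "nwsb_model.json").write_text(json.dumps(model.to_dict(), indent=2))
    except Exception as exc:
        raise RuntimeError(f"stage 'fit-nwsb' failed: {exc}") from exc
    record("fit-nwsb", ["nwsb_observations.csv", "nwsb_model.json"], t0)

    # --- cwsi-map -----------------------------------------------------
    t0 = time.perf_counter()
    try:
        refs = (
            ReferenceTemperatures(t_wet=config.t_wet, t_dry=config.t_dry)
            if config.cwsi_method == "empirical"
            else None
        )
        smap = stress_map(
            ltm,
            t_air=scene.t_air,
            model=model,
            rh=scene.rh,
            refs=refs,
            method=config.cwsi_method,
        )
        smap.to_csv(outdir / "cwsi_map.csv")
        daily_vwc_now = {
            lab: float(moisture.frame[lab].iloc[-1])
            for lab in scene.treatment_layout.labels
        }
        summary = treatment_summary(smap, scene.treatment_layout, vwc=daily_vwc_now)
        summary.to_csv(outdir / "treatment_summary.csv")
    except Exception as exc:
        raise RuntimeError(f"stage 'cwsi-map' failed: {exc}") from exc
    record("cwsi-map", ["cwsi_map.csv", "treatment_summary.csv"], t0)

    # --- monitor ------------------------------------------------------
    t0 = time.perf_counter()
    try:
        cwsi_df, vwc_df = daily_stress_cycle(
            moisture.frame,
            model,
            t_air=scene.t_air,
            rh=scene.rh,
            coupling=config.stress_coupling,
        )
        cwsi_df.to_csv(outdir / "daily_cwsi.csv")
        report = joint_cycle_report(
            cwsi_df, vwc_df, lam=config.ewma_lambda, limit_width=config.ewma_L
        )
        chart_doc = {
            lab: {
                "cwsi_chart": entry["cwsi_chart"].to_dict(),
                "vwc_chart": entry["vwc_chart"].to_dict(),
                "spearman_rho": entry["spearman_rho"],
                "cwsi_stable": is_stable(entry["cwsi_chart"]).stable,
                "vwc_stable": is_stable(entry["vwc_chart"]).stable,
            }
            for lab, entry in report.items()
        }
        (outdir / "ewma_charts.json").write_text(json.dumps(chart_doc, indent=2))
    except Exception as exc:
        raise RuntimeError(f"stage 'monitor' failed: {exc}") from exc
    record("monitor", ["daily_cwsi.csv", "ewma_charts.json"], t0)

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
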