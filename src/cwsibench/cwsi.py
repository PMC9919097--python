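"""Crop water stress index maps and per-treatment summaries.

The CWSI normalizes the canopy-air temperature difference between a
lower limit (a fully transpiring, unstressed canopy) and an upper limit
(a non-transpiring one):

    CWSI = (dT - dT_LL) / (dT_UL - dT_LL),    dT = T_L - T_A,

so 0 means no water restriction and 1 means no transpiration.  Limits
come either from the non-water-stressed baseline (dT_LL at the ambient
VPD, dT_UL by the potential-VPD construction) or empirically from
wet/dry reference leaf temperatures.  Values are clipped to [0, 1] after
map construction and the clip counts are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .baseline import NWSBModel, ReferenceTemperatures, lower_limit, upper_limit, vpd
from .scene import TreatmentLayout
from .thermal import LeafTemperatureMap

__all__ = [
    "StressMap",
    "TreatmentSummary",
    "cwsi_nwsb",
    "cwsi_empirical",
    "clip_cwsi",
    "stress_map",
    "treatment_summary",
]


def cwsi_nwsb(dt, ll: float, ul: float, denominator: str = "canonical"):
    """CWSI from the temperature difference and the baseline limits.

    ``denominator='canonical'`` (default) uses (UL - LL), for which the
    anchors CWSI(LL) = 0 and CWSI(UL) = 1 hold exactly.  The 'literal'
    variant uses (UL - dT) for comparison purposes; it shares only the
    zero anchor.
    """
    if not ul > ll:
        raise ValueError(f"degenerate limits: UL ({ul}) must exceed LL ({ll})")
    dt_arr = np.asarray(dt, dtype=float)
    if denominator == "canonical":
        out = (dt_arr - ll) / (ul - ll)
    elif denominator == "literal":
        with np.errstate(divide="ignore", invalid="ignore"):
            out = (dt_arr - ll) / (ul - dt_arr)
    else:
        raise ValueError("denominator must be 'canonical' or 'literal'")
    return out if out.ndim else float(out)


def cwsi_empirical(t_leaf, refs: ReferenceTemperatures):
    """CWSI from wet/dry reference surface temperatures.

    The water-sprayed leaf gives the minimum (fully transpiring)
    temperature, the petroleum-jelly-coated leaf the maximum
    (non-transpiring) one.
    """
    out = (np.asarray(t_leaf, dtype=float) - refs.t_wet) / (refs.t_dry - refs.t_wet)
    return out if out.ndim else float(out)


def clip_cwsi(value):
    """Clip CWSI to [0, 1]: negative values become 0, values above 1 become 1.

    Returns (clipped, n_below, n_above).  NaNs pass through (they mark
    non-plant pixels) and are not counted.
    """
    arr = np.asarray(value, dtype=float)
    if np.isinf(arr).any():
        raise ValueError("non-finite CWSI value")
    n_below = int(np.nansum(arr < 0.0))
    n_above = int(np.nansum(arr > 1.0))
    clipped = np.clip(arr, 0.0, 1.0)
    if clipped.ndim == 0:
        return float(clipped), n_below, n_above
    return clipped, n_below, n_above


@dataclass
class StressMap:
    """Per-pixel CWSI raster; NaN where there is no plant.

    ``n_clipped_low``/``n_clipped_high`` count the out-of-range values
    mapped back onto the [0, 1] limits.
    """

    values: np.ndarray
    method: str
    n_clipped_low: int = 0
    n_clipped_high: int = 0
    t_air: float = float("nan")
    rh: float = float("nan")
    limits: tuple = (float("nan"), float("nan"))

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        finite = self.values[~np.isnan(self.values)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            raise ValueError("clipped stress map must lie in [0, 1]")

    @property
    def plant_mask(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def to_csv(self, path) -> None:
        np.savetxt(path, self.values, fmt="%.6f", delimiter=",")

    def save_preview(self, path) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(8, 4))
        im = ax.imshow(self.values, cmap="RdYlGn_r", vmin=0.0, vmax=1.0)
        fig.colorbar(im, ax=ax, label="CWSI")
        ax.set_axis_off()
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)


def stress_map(
    ltm: LeafTemperatureMap,
    t_air: float,
    model: NWSBModel | None = None,
    rh: float | None = None,
    refs: ReferenceTemperatures | None = None,
    method: str = "nwsb",
    denominator: str = "canonical",
) -> StressMap:
    """Compute a clipped CWSI map from a leaf temperature map.

    With ``method='nwsb'`` the limits are scan-level: the lower limit is
    the baseline at vpd(t_air, rh) and the upper limit the potential-VPD
    value at t_air.  With ``method='empirical'`` the dT limits are
    (t_wet - t_air) and (t_dry - t_air).  NaN (non-plant) pixels are
    preserved.
    """
    if ltm.n_plant_pixels == 0:
        raise ValueError("leaf temperature map has no plant pixels")
    if method == "nwsb":
        if model is None or rh is None:
            raise ValueError("method='nwsb' requires a fitted model and rh")
        ll = lower_limit(model, vpd(t_air, rh))
        ul = upper_limit(model, t_air)
    elif method == "empirical":
        if refs is None:
            raise ValueError("method='empirical' requires reference temperatures")
        ll = refs.t_wet - t_air
        ul = refs.t_dry - t_air
    else:
        raise ValueError("method must be 'nwsb' or 'empirical'")
    if not ul > ll:
        raise ValueError(
            f"degenerate limits for method={method!r}: LL={ll:.3f}, UL={ul:.3f}"
        )

    dt = ltm.values - t_air
    raw = cwsi_nwsb(dt, ll, ul, denominator=denominator)
    clipped, n_low, n_high = clip_cwsi(raw)
    return StressMap(
        values=clipped,
        method=method,
        n_clipped_low=n_low,
        n_clipped_high=n_high,
        t_air=t_air,
        rh=float("nan") if rh is None else rh,
        limits=(ll, ul),
    )


@dataclass
class TreatmentSummary:
    """Per-treatment CWSI statistics, optionally paired with soil moisture."""

    table: pd.DataFrame = field(repr=False)

    def mean(self, label: str) -> float:
        return float(self.table.set_index("treatment").loc[label, "mean_cwsi"])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def treatment_summary(
    smap: StressMap, layout: TreatmentLayout, vwc: dict | None = None
) -> TreatmentSummary:
    """Mean/min/max CWSI and pixel counts per treatment band.

    Statistics are computed over plant (non-NaN) pixels only; a band
    with no plant pixels is reported with NaN statistics rather than an
    error.  ``vwc`` optionally attaches the per-treatment soil moisture
    (fraction of field capacity) for joint reporting.
    """
    rows = []
    for lab, region in layout.region_masks(smap.values.shape).items():
        vals = smap.values[region]
        vals = vals[~np.isnan(vals)]
        rows.append(
            {
                "treatment": lab,
                "mean_cwsi": float(vals.mean()) if vals.size else float("nan"),
                "min_cwsi": float(vals.min()) if vals.size else float("nan"),
                "max_cwsi": float(vals.max()) if vals.size else float("nan"),
                "n_pixels": int(vals.size),
                "vwc_fc": float(vwc[lab]) if vwc and lab in vwc else float("nan"),
            }
        )
    return TreatmentSummary(table=pd.DataFrame(rows))
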