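"""EWMA control charts for stress and soil-moisture stability.

The exponentially weighted moving average z_t = lam*x_t + (1 - lam)*z_{t-1}
(z_0 = center) is charted against time-varying control limits

    center +/- L * sigma * sqrt(lam/(2 - lam) * (1 - (1 - lam)^(2t))),

which widen monotonically toward the asymptote sigma*sqrt(lam/(2-lam)).
A process is judged stable iff no smoothed point falls outside its
limits.  Defaults lam = 0.2, L = 3 follow standard control-chart
practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

__all__ = ["EWMAChart", "StabilityVerdict", "ewma_chart", "is_stable", "joint_cycle_report"]


@dataclass
class EWMAChart:
    lam: float
    limit_width: float  # L, in sigma multiples
    center: float
    sigma: float
    x: np.ndarray = field(repr=False)
    z: np.ndarray = field(repr=False)
    ucl: np.ndarray = field(repr=False)
    lcl: np.ndarray = field(repr=False)

    @property
    def out_of_control(self) -> np.ndarray:
        """Indices t where z_t exceeds its control limits.

        Comparison carries an absolute tolerance of 1e-9 scaled by the
        center magnitude so float round-off in the recursion cannot
        register as a violation (relevant for zero-width limits).
        """
        tol = 1e-9 * max(1.0, abs(self.center))
        return np.flatnonzero((self.z > self.ucl + tol) | (self.z < self.lcl - tol))

    def to_dict(self) -> dict:
        return {
            "lambda": self.lam,
            "L": self.limit_width,
            "center": self.center,
            "sigma": self.sigma,
            "z": self.z.tolist(),
            "ucl": self.ucl.tolist(),
            "lcl": self.lcl.tolist(),
            "violations": self.out_of_control.tolist(),
        }


@dataclass(frozen=True)
class StabilityVerdict:
    stable: bool
    n_violations: int
    first_violation_index: int | None = None


def ewma_chart(
    x,
    lam: float = 0.2,
    limit_width: float = 3.0,
    center: float | None = None,
    sigma: float | None = None,
    sigma_method: str = "sample_sd",
) -> EWMAChart:
    """Build an EWMA chart for a numeric series.

    ``center`` defaults to the sample mean and ``sigma`` to the sample
    standard deviation; ``sigma_method='moving_range'`` instead uses the
    mean absolute successive difference divided by 1.128 (the d2
    constant for subgroups of two).
    """
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError("series must be 1-D with at least 2 points")
    if not 0.0 < lam <= 1.0:
        raise ValueError("lambda must lie in (0, 1]")
    mu0 = float(arr.mean()) if center is None else float(center)
    if sigma is None:
        if sigma_method == "moving_range":
            sig = float(np.abs(np.diff(arr)).mean() / 1.128)
        else:
            sig = float(arr.std(ddof=1))
        if np.ptp(arr) == 0.0:
            sig = 0.0
            warnings.warn(
                "constant series: control limits have zero width", stacklevel=2
            )
    else:
        sig = float(sigma)

    z = np.empty_like(arr)
    prev = mu0
    for t in range(arr.size):
        prev = lam * arr[t] + (1.0 - lam) * prev
        z[t] = prev

    t_idx = np.arange(1, arr.size + 1)
    half = (
        limit_width
        * sig
        * np.sqrt(lam / (2.0 - lam) * (1.0 - (1.0 - lam) ** (2 * t_idx)))
    )
    return EWMAChart(
        lam=lam,
        limit_width=limit_width,
        center=mu0,
        sigma=sig,
        x=arr,
        z=z,
        ucl=mu0 + half,
        lcl=mu0 - half,
    )


def is_stable(chart: EWMAChart) -> StabilityVerdict:
    """Stable iff no smoothed point lies outside its control limits."""
    viol = chart.out_of_control
    return StabilityVerdict(
        stable=viol.size == 0,
        n_violations=int(viol.size),
        first_violation_index=int(viol[0]) if viol.size else None,
    )


def joint_cycle_report(
    cwsi_series: pd.DataFrame,
    vwc_series: pd.DataFrame,
    lam: float = 0.2,
    limit_width: float = 3.0,
) -> dict:
    """Paired EWMA charts plus rank correlation per treatment.

    Both frames are indexed by day with one column per treatment; the
    indices must align.  Returns, per treatment, the CWSI chart, the
    moisture chart, and the Spearman rank correlation between the two
    series (expected negative: stress rises as the soil dries).
    """
    if not cwsi_series.index.equals(vwc_series.index):
        raise ValueError("cwsi and vwc series must share aligned day indices")
    if list(cwsi_series.columns) != list(vwc_series.columns):
        raise ValueError("cwsi and vwc series must cover the same treatments")
    report = {}
    for lab in cwsi_series.columns:
        c = cwsi_series[lab].to_numpy(dtype=float)
        v = vwc_series[lab].to_numpy(dtype=float)
        rho = spearmanr(c, v).statistic
        report[lab] = {
            "cwsi_chart": ewma_chart(c, lam=lam, limit_width=limit_width),
            "vwc_chart": ewma_chart(v, lam=lam, limit_width=limit_width),
            "spearman_rho": float(rho),
        }
    return report
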