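"""Vapor pressure deficit and the non-water-stressed baseline (NWSB).

The NWSB is the linear relation between the canopy-air temperature
difference of well-watered plants and the vapor pressure deficit of the
air,

    (T_L - T_A) = a + b * VPD,

with intercept ``a`` (degC) and slope ``b`` (degC/kPa, negative for
transpiring crops).  It supplies the lower limit of the crop water
stress index at the ambient VPD, and the upper limit through the
potential-VPD construction evaluated at zero ambient VPD.

Saturation vapor pressure uses the Tetens-type closed form

    es(T) = 0.6108 * 10**(7.5 T / (273.3 + T))   [kPa, T in degC]

and VPD = (1 - RH) * es(T_A) with RH a fraction in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "NWSBModel",
    "ReferenceTemperatures",
    "saturation_vp",
    "vpd",
    "fit_nwsb",
    "fit_nwsb_series",
    "lower_limit",
    "upper_limit",
]

_ABS_ZERO_OFFSET = 273.3  # denominator constant of the Tetens form, degC


def saturation_vp(t_celsius):
    """Saturation vapor pressure es(T) in kPa for air temperature in degC.

    Raises
    ------
    ValueError
        If any temperature is at or below -273.3 degC, where the
        exponent's denominator vanishes.
    """
    t = np.asarray(t_celsius, dtype=float)
    if np.any(t <= -_ABS_ZERO_OFFSET):
        raise ValueError(
            f"temperature must exceed {-_ABS_ZERO_OFFSET} degC; got minimum {t.min()}"
        )
    es = 0.6108 * 10.0 ** (7.5 * t / (_ABS_ZERO_OFFSET + t))
    return es if es.ndim else float(es)


def vpd(t_air, rh):
    """Vapor pressure deficit (kPa) from air temperature (degC) and RH.

    ``rh`` must be a fraction in [0, 1].  Values above 1 look like
    percentages and are rejected rather than silently rescaled.
    """
    rh_arr = np.asarray(rh, dtype=float)
    if np.any(rh_arr < 0.0) or np.any(rh_arr > 1.0):
        raise ValueError(
            "RH must be a fraction in [0, 1]; percent values (e.g. 47) must be "
            "divided by 100 by the caller"
        )
    out = (1.0 - rh_arr) * saturation_vp(t_air)
    out_arr = np.asarray(out)
    return out if out_arr.ndim else float(out_arr)


@dataclass(frozen=True)
class ReferenceTemperatures:
    """Empirical CWSI reference surfaces.

    ``t_wet`` is a water-sprayed leaf (maximal transpiration, the coolest a
    leaf can get); ``t_dry`` a petroleum-jelly-coated leaf (no
    transpiration, the warmest).
    """

    t_wet: float
    t_dry: float

    def __post_init__(self):
        if not self.t_dry > self.t_wet:
            raise ValueError(
                f"t_dry ({self.t_dry}) must exceed t_wet ({self.t_wet})"
            )


@dataclass(frozen=True)
class NWSBModel:
    """Fitted non-water-stressed baseline with residual diagnostics.

    Attributes
    ----------
    a, b : float
        Intercept (degC) and slope (degC/kPa) of dT = a + b*VPD.
    se_a, se_b : float
        Standard errors of the coefficients.
    r_squared : float
    n : int
        Number of points fitted.
    residuals : ndarray
        Fit residuals, degC; mean is zero by the OLS normal equations.
    residual_mean : float
    bias_slope : float
        Slope of residuals regressed on fitted values (zero to numerical
        tolerance for an OLS fit with intercept; retained as a diagnostic).
    het_pvalue : float
        Breusch-Pagan p-value; large values are consistent with
        homoscedastic residuals.
    env_tag : str
        'protected' or 'unprotected' growing environment.
    """

    a: float
    b: float
    se_a: float
    se_b: float
    r_squared: float
    n: int
    residuals: np.ndarray = field(repr=False)
    residual_mean: float
    bias_slope: float
    het_pvalue: float
    env_tag: str = "protected"

    def predict(self, vpd_values):
        return self.a + self.b * np.asarray(vpd_values, dtype=float)

    def to_dict(self) -> dict:
        return {
            "a": self.a,
            "b": self.b,
            "se_a": self.se_a,
            "se_b": self.se_b,
            "r_squared": self.r_squared,
            "n": self.n,
            "residual_mean": self.residual_mean,
            "bias_slope": self.bias_slope,
            "het_pvalue": self.het_pvalue,
            "env_tag": self.env_tag,
        }


def fit_nwsb(dt, vpd_values, env_tag: str = "protected") -> NWSBModel:
    """Ordinary least squares fit of (T_L - T_A) on VPD with intercept.

    Parameters
    ----------
    dt : array-like
        Canopy-air temperature differences, degC.
    vpd_values : array-like
        Vapor pressure deficits, kPa; must not be constant.
    env_tag : str
        Label of the growing environment the points came from.
    """
    y = np.asarray(dt, dtype=float)
    x = np.asarray(vpd_values, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("dt and vpd must be 1-D series of equal length")
    if y.size < 3:
        raise ValueError(f"need at least 3 points to fit the baseline, got {y.size}")
    if np.ptp(x) == 0.0:
        raise ValueError("VPD series is constant; the slope is unidentifiable")

    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    resid = np.asarray(res.resid)

    fitted = np.asarray(res.fittedvalues)
    if np.ptp(fitted) > 0:
        bias_slope = float(np.polyfit(fitted, resid, 1)[0])
    else:  # pragma: no cover - requires b == 0 exactly
        bias_slope = 0.0
    het_pvalue = float(sm.stats.diagnostic.het_breuschpagan(resid, X)[1])

    return NWSBModel(
        a=float(res.params[0]),
        b=float(res.params[1]),
        se_a=float(res.bse[0]),
        se_b=float(res.bse[1]),
        r_squared=float(res.rsquared),
        n=int(res.nobs),
        residuals=resid,
        residual_mean=float(resid.mean()),
        bias_slope=bias_slope,
        het_pvalue=het_pvalue,
        env_tag=env_tag,
    )


def fit_nwsb_series(
    frame: pd.DataFrame,
    env_tag: str = "protected",
    daily_mean: bool = True,
    by_hour: bool = False,
):
    """Fit the baseline from a timestamped (dt, vpd) table.

    ``frame`` needs columns ``timestamp``, ``dt`` and ``vpd``.  With
    ``daily_mean`` (default) points are first averaged per calendar day -
    the simplified correlation appropriate when stress maps are produced
    once a day.  ``by_hour`` instead stratifies by hour of day and returns
    a dict mapping hour -> NWSBModel (the time-resolved variant).
    """
    ts = pd.to_datetime(frame["timestamp"])
    if by_hour:
        out = {}
        for hour, grp in frame.groupby(ts.dt.hour):
            if len(grp) >= 3 and np.ptp(grp["vpd"].to_numpy()) > 0:
                out[int(hour)] = fit_nwsb(grp["dt"], grp["vpd"], env_tag=env_tag)
        return out
    if daily_mean:
        daily = frame.groupby(ts.dt.date)[["dt", "vpd"]].mean()
        return fit_nwsb(daily["dt"], daily["vpd"], env_tag=env_tag)
    return fit_nwsb(frame["dt"], frame["vpd"], env_tag=env_tag)


def lower_limit(model: NWSBModel, vpd_now: float) -> float:
    """Lower CWSI limit (T_L - T_A)_LL: the baseline at the ambient VPD."""
    if vpd_now < 0:
        raise ValueError(f"vpd_now must be non-negative, got {vpd_now}")
    return model.a + model.b * vpd_now

def upper_limit(model: NWSBModel, t_air: float) -> float:
    """Upper CWSI limit (T_L - T_A)_UL by the potential-VPD construction.

    At zero ambient VPD a non-transpiring canopy warms by the intercept
    ``a``; the vapor-pressure gradient this creates is
    es(T_A) - es(T_A + a) (non-positive for a > 0), and re-entering it in
    the baseline gives the maximal temperature difference:

        UL = a + b * (es(T_A) - es(T_A + a))

    For a > 0 and b < 0 this exceeds ``a`` and hence every lower limit,
    keeping the CWSI denominator positive.
    """
    potential_vpd = saturation_vp(t_air) - saturation_vp(t_air + model.a)
    return model.a + model.b * potential_vpd
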