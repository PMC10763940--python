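"""Linear calibration with uncertainty, detection limits, and the assay's
three selection procedures (color channel, reading time, reagent dose).

The response model is a straight line, response = slope * conc + intercept,
fit by ordinary least squares.  Standard errors of slope and intercept come
from the classical closed forms; goodness of fit is reported as both R^2 and
the adjusted R^2 = 1 - (1 - R^2)(n - 1)/(n - 2).

Detection and quantification limits follow the 3.3*sigma/|slope| and
10*sigma/|slope| convention.  Three choices of sigma are supported:

``slope_se``      the standard error of the slope (default — this is the
                  convention under which the assay's published pair of limits,
                  0.12 and 0.36 ppb, is internally consistent),
``intercept_se``  the standard error of the intercept (ICH-style), and
``residual_sd``   the residual standard deviation of the fit.

The choice matters: the three sigmas can differ by orders of magnitude, so a
persisted model records which one produced its limits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.isotonic import IsotonicRegression
from sklearn.utils.validation import check_is_fitted

LOD_FACTOR = 3.3
LOQ_FACTOR = 10.0

SIGMA_MODES = ("slope_se", "intercept_se", "residual_sd")

#: Fixed preference order used to break adjusted-R^2 ties in channel selection.
CHANNEL_ORDER = ("mean_r", "composite_rgb", "mean_g", "mean_b")

__all__ = [
    "CalibrationCurve",
    "ChannelSelector",
    "ReadingTimeSelector",
    "DoseResponseSeries",
    "KineticSeries",
    "SaturationResult",
    "fit_linear",
    "detection_limits",
    "adjusted_r2",
    "select_channel",
    "select_reading_time",
    "saturation_dose",
]


def adjusted_r2(r2: float, n: int, n_params: int = 2) -> float:
    """Adjusted coefficient of determination, 1 - (1-R^2)(n-1)/(n-p-1)."""
    dof = n - n_params
    if dof <= 0:
        return float("nan")
    return 1.0 - (1.0 - r2) * (n - 1) / dof


def detection_limits(
    slope: float, sigma: float, rounded: bool = False
) -> tuple[float, float]:
    """(LOD, LOQ) = (3.3, 10) * sigma / |slope|.

    ``rounded=True`` reports to 2 decimals, the convention used when the
    limits are quoted in ppb.
    """
    if slope == 0:
        raise ValueError("slope is zero: detection limits are undefined")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    lod = LOD_FACTOR * sigma / abs(slope)
    loq = LOQ_FACTOR * sigma / abs(slope)
    if rounded:
        return round(lod, 2), round(loq, 2)
    return lod, loq


class CalibrationCurve(RegressorMixin, BaseEstimator):
    """Ordinary-least-squares linear calibration of response against
    concentration.

    Parameters
    ----------
    sigma_mode : {"slope_se", "intercept_se", "residual_sd"}
        Which dispersion estimate feeds the 3.3/10 detection-limit formulas.
    linear_range : (float, float) or None
        Validated linearity bounds in ppb.  ``None`` uses the span of the
        fitted concentrations.

    Attributes (after ``fit``)
    --------------------------
    slope_, intercept_ : fitted line coefficients
    se_slope_, se_intercept_ : their standard errors
    r2_, adj_r2_ : goodness of fit
    residual_sd_ : root mean squared residual (n-2 degrees of freedom)
    n_ : number of calibration points
    linear_lo_, linear_hi_ : ppb bounds of validated linearity
    lod_ppb_, loq_ppb_ : detection/quantification limits (full precision)
    """

    def __init__(
        self,
        sigma_mode: str = "slope_se",
        linear_range: tuple[float, float] | None = None,
    ):
        self.sigma_mode = sigma_mode
        self.linear_range = linear_range

    # -- fitting ---------------------------------------------------------

    def fit(self, X, y) -> "CalibrationCurve":
        """Fit response ``y`` against concentration ``X`` (shape (n,) or (n,1))."""
        if self.sigma_mode not in SIGMA_MODES:
            raise ValueError(
                f"sigma_mode must be one of {SIGMA_MODES}, got {self.sigma_mode!r}"
            )
        x = np.asarray(X, dtype=float)
        if x.ndim == 2 and x.shape[1] == 1:
            x = x[:, 0]
        if x.ndim != 1:
            raise ValueError("X must be 1-D concentrations or a single column")
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape:
            raise ValueError("X and y must have the same length")
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise ValueError("non-finite values in calibration data")
        n = x.size
        if n < 3:
            raise ValueError("need at least 3 calibration points for standard errors")
        if np.unique(x).size < 2:
            raise ValueError("all concentrations identical: slope is undefined")

        # centered normal equations: numerically stable closed forms
        xbar, ybar = x.mean(), y.mean()
        xc = x - xbar
        sxx = float(np.sum(xc**2))
        self.slope_ = float(np.sum(xc * (y - ybar)) / sxx)
        self.intercept_ = float(ybar - self.slope_ * xbar)
        resid = y - (self.slope_ * x + self.intercept_)
        rss = float(np.sum(resid**2))
        tss = float(np.sum((y - ybar) ** 2))
        # flat data carries no explained variance: r2 = 0 by convention
        self.r2_ = 1.0 - rss / tss if tss > 0 else 0.0
        self.adj_r2_ = adjusted_r2(self.r2_, n)
        s2 = rss / (n - 2)
        self.se_slope_ = float(np.sqrt(s2 / sxx))
        self.se_intercept_ = float(np.sqrt(s2 * (1.0 / n + xbar**2 / sxx)))
        self.residual_sd_ = float(np.sqrt(s2))
        self.n_ = int(n)
        if self.linear_range is not None:
            self.linear_lo_, self.linear_hi_ = map(float, self.linear_range)
        else:
            self.linear_lo_, self.linear_hi_ = float(x.min()), float(x.max())
        if not self.linear_lo_ < self.linear_hi_:
            raise ValueError("linear_lo must be below linear_hi")
        if self.slope_ != 0:
            self.lod_ppb_, self.loq_ppb_ = detection_limits(self.slope_, self.sigma_)
        else:  # flat fit (legit during channel/time screening); limits undefined
            self.lod_ppb_ = self.loq_ppb_ = float("nan")
        return self

    @classmethod
    def from_parameters(
        cls,
        slope: float,
        intercept: float,
        se_slope: float = 0.0,
        se_intercept: float = 0.0,
        r2: float = float("nan"),
        adj_r2: float = float("nan"),
        residual_sd: float = 0.0,
        n: int = 0,
        linear_range: tuple[float, float] = (0.0, float("inf")),
        sigma_mode: str = "slope_se",
    ) -> "CalibrationCurve":
        """Build a fitted model from known coefficients (e.g. a published
        calibration), bypassing ``fit``."""
        if slope == 0:
            raise ValueError("slope must be nonzero")
        model = cls(sigma_mode=sigma_mode, linear_range=tuple(linear_range))
        model.slope_ = float(slope)
        model.intercept_ = float(intercept)
        model.se_slope_ = float(se_slope)
        model.se_intercept_ = float(se_intercept)
        model.r2_ = float(r2)
        model.adj_r2_ = float(adj_r2)
        model.residual_sd_ = float(residual_sd)
        model.n_ = int(n)
        model.linear_lo_, model.linear_hi_ = map(float, linear_range)
        model.lod_ppb_, model.loq_ppb_ = detection_limits(slope, model.sigma_)
        return model

    # -- derived quantities ---------------------------------------------

    @property
    def sigma_(self) -> float:
        """The dispersion estimate selected by ``sigma_mode``."""
        check_is_fitted(self, "slope_")
        return {
            "slope_se": self.se_slope_,
            "intercept_se": self.se_intercept_,
            "residual_sd": self.residual_sd_,
        }[self.sigma_mode]

    def detection_limits(self, rounded: bool = False) -> tuple[float, float]:
        """(LOD, LOQ) in ppb for this model under its sigma_mode."""
        return detection_limits(self.slope_, self.sigma_, rounded=rounded)

    def predict(self, X) -> np.ndarray:
        """Forward model: expected response at concentration X."""
        check_is_fitted(self, "slope_")
        x = np.asarray(X, dtype=float)
        if x.ndim == 2 and x.shape[1] == 1:
            x = x[:, 0]
        return self.slope_ * x + self.intercept_

    def inverse(self, response) -> np.ndarray | float:
        """Invert the line: raw concentration at a measured response.

        Range checking and N.D. flagging live in :mod:`platesense.quantify`.
        """
        check_is_fitted(self, "slope_")
        resp = np.asarray(response, dtype=float)
        if not np.isfinite(resp).all():
            raise ValueError("non-finite response")
        out = (resp - self.intercept_) / self.slope_
        return float(out) if out.ndim == 0 else out


def fit_linear(
    x: Sequence[float],
    y: Sequence[float],
    sigma_mode: str = "slope_se",
    linear_range: tuple[float, float] | None = None,
) -> CalibrationCurve:
    """Functional wrapper: OLS-fit a CalibrationCurve on (conc, response)."""
    return CalibrationCurve(sigma_mode=sigma_mode, linear_range=linear_range).fit(x, y)


# ---------------------------------------------------------------------------
# channel selection
# ---------------------------------------------------------------------------


class ChannelSelector(BaseEstimator):
    """Pick the color statistic with the strongest linear concentration
    response.

    Each candidate channel (R, G, B and the composite R+G+B) is regressed
    against concentration; the channel with the highest adjusted R^2 wins.
    Exact ties go to the earlier entry of the fixed order R, R+G+B, G, B.

    Attributes: ``best_channel_`` and ``report_`` (DataFrame with one row per
    channel: slope, intercept, r2, adj_r2).
    """

    def __init__(self, channels: tuple[str, ...] = CHANNEL_ORDER):
        self.channels = channels

    def fit(self, features: pd.DataFrame, conc=None) -> "ChannelSelector":
        """features: DataFrame with a ``conc_ppb`` column (or ``conc`` given
        separately) plus one column per candidate channel."""
        if conc is None:
            if "conc_ppb" not in features.columns:
                raise ValueError("need conc_ppb column or an explicit conc vector")
            conc = features["conc_ppb"].to_numpy(dtype=float)
        else:
            conc = np.asarray(conc, dtype=float)
        if np.unique(conc).size < 3:
            raise ValueError("need at least 3 concentration levels")
        rows = []
        for ch in self.channels:
            if ch not in features.columns:
                raise ValueError(f"feature table lacks channel column {ch!r}")
            m = fit_linear(conc, features[ch].to_numpy(dtype=float))
            rows.append(
                {
                    "channel": ch,
                    "slope": m.slope_,
                    "intercept": m.intercept_,
                    "r2": m.r2_,
                    "adj_r2": m.adj_r2_,
                }
            )
        report = pd.DataFrame(rows).set_index("channel")
        # stable argmax: first channel in the declared order attaining the max
        best = report["adj_r2"].idxmax()
        self.report_ = report
        self.best_channel_ = str(best)
        return self


def select_channel(
    features: pd.DataFrame, conc=None
) -> tuple[str, pd.DataFrame]:
    """(best channel, per-channel adjusted-R^2 report)."""
    sel = ChannelSelector().fit(features, conc)
    return sel.best_channel_, sel.report_


# ---------------------------------------------------------------------------
# reading-time selection
# ---------------------------------------------------------------------------


@dataclass
class KineticSeries:
    """Color development over time: ``responses[i, j]`` is the channel value
    at ``times[i]`` minutes for concentration ``concs[j]`` ppb."""

    times: np.ndarray
    concs: np.ndarray
    responses: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concs = np.asarray(self.concs, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.responses.shape != (self.times.size, self.concs.size):
            raise ValueError("responses must have shape (n_times, n_concs)")


class ReadingTimeSelector(BaseEstimator):
    """Choose the earliest incubation time at which the response-vs-
    concentration line is both developed and maximally linear.

    For each time point the response is regressed on concentration.  Time
    points whose |slope| is below ``slope_floor_frac`` of the largest
    per-time |slope| are discarded as undeveloped (early flat phase); among
    the remainder, the earliest time attaining the maximal adjusted R^2 is
    returned.

    Attributes: ``best_time_`` (minutes) and ``report_`` (DataFrame indexed
    by time: slope, adj_r2, developed flag).
    """

    def __init__(self, slope_floor_frac: float = 0.25):
        self.slope_floor_frac = slope_floor_frac

    def fit(self, series: KineticSeries) -> "ReadingTimeSelector":
        if series.times.size < 2:
            raise ValueError("need at least 2 time points")
        if np.unique(series.concs).size < 3:
            raise ValueError("need at least 3 concentration levels")
        rows = []
        for i, t in enumerate(series.times):
            m = fit_linear(series.concs, series.responses[i])
            rows.append({"time_min": float(t), "slope": m.slope_, "adj_r2": m.adj_r2_})
        report = pd.DataFrame(rows).set_index("time_min")
        max_slope = report["slope"].abs().max()
        if max_slope == 0:
            raise ValueError(
                "no time point shows color development; incubate longer"
            )
        report["developed"] = (
            report["slope"].abs() >= self.slope_floor_frac * max_slope
        )
        developed = report[report["developed"]]
        if developed.empty:
            raise ValueError(
                "no time point shows color development; incubate longer"
            )
        best_adj = developed["adj_r2"].max()
        best_time = developed.index[developed["adj_r2"] >= best_adj][0]
        self.report_ = report
        self.best_time_ = float(best_time)
        return self


def select_reading_time(
    series: KineticSeries, slope_floor_frac: float = 0.25
) -> tuple[float, pd.DataFrame]:
    """(best reading time in minutes, per-time report)."""
    sel = ReadingTimeSelector(slope_floor_frac=slope_floor_frac).fit(series)
    return sel.best_time_, sel.report_


# ---------------------------------------------------------------------------
# reagent dose saturation
# ---------------------------------------------------------------------------


@dataclass
class DoseResponseSeries:
    """Absorbance (AU, 650 nm) against reagent dose (mM), doses strictly increasing."""

    doses: np.ndarray
    responses: np.ndarray

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.doses.shape != self.responses.shape or self.doses.ndim != 1:
            raise ValueError("doses and responses must be equal-length 1-D arrays")
        if np.any(np.diff(self.doses) <= 0):
            raise ValueError("doses must be strictly increasing")
        if not np.isfinite(self.responses).all():
            raise ValueError("responses must be finite")


@dataclass(frozen=True)
class SaturationResult:
    dose: float
    status: str  # "saturated" | "not_saturated"
    smoothed: np.ndarray


def saturation_dose(
    series: DoseResponseSeries, plateau_tol: float = 0.05
) -> SaturationResult:
    """Smallest reagent dose on the response plateau.

    The response is first monotone-smoothed (isotonic regression in dose),
    then the plateau is the maximal suffix of doses whose smoothed response
    is within ``plateau_tol`` (relative) of the maximum.  The smallest dose
    of that suffix is the optimum.  If only the top dose qualifies the curve
    is still rising there and the result is flagged ``"not_saturated"`` with
    the top dose returned.
    """
    if series.doses.size < 4:
        raise ValueError("need at least 4 doses to judge saturation")
    if not 0 < plateau_tol < 1:
        raise ValueError("plateau_tol must be in (0, 1)")
    iso = IsotonicRegression(increasing=True)
    smooth = iso.fit_transform(series.doses, series.responses)
    rmax = smooth.max()
    scale = abs(rmax) if rmax != 0 else 1.0
    within = np.abs(smooth - rmax) <= plateau_tol * scale
    # maximal suffix of doses all within tolerance of the plateau
    idx = len(within)
    while idx > 0 and within[idx - 1]:
        idx -= 1
    if idx >= len(within) - 1 and not within.all():
        return SaturationResult(
            dose=float(series.doses[-1]), status="not_saturated", smoothed=smooth
        )
    return SaturationResult(
        dose=float(series.doses[idx]), status="saturated", smoothed=smooth
    )
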