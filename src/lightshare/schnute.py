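"""Schnute growth model for phytomer appearance on pea main stems.

The number of visible phytomers on a stem is a saturating, sigmoid-like
function of thermal time (degree-days, base 0 degC).  We model it with a
Schnute-type curve anchored at emergence::

    Y(t) = y_max * [ (1 - exp(-A t)) / (1 - exp(-A t_max)) ] ** (1 / B)

where ``A`` (DD^-1) and ``B`` (dimensionless) jointly set the shape,
``t_max`` is the last observation time of the fitted domain and ``y_max``
is the value of the curve at ``t_max``.  The curve passes through (0, 0)
(no phytomer before emergence) and (t_max, y_max) by construction, and is
monotone non-decreasing for positive parameters.

For 0 < B < 1 the appearance *rate* dY/dt has an interior maximum at

    t* = -ln(B) / A

which is the phyllochron-rate summary used to compare cultivar earliness.
For B >= 1 the rate is maximal at the start of the domain; this is flagged
rather than silently reported.

Fitting uses Levenberg-Marquardt least squares with ``t_max`` fixed to the
last observation time (it is part of the data domain, not a free
parameter).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "SchnuteParams",
    "PhytomerSeries",
    "RateSummary",
    "SchnuteModel",
    "SchnuteResults",
    "schnute_eval",
    "schnute_rate",
    "read_phytomer_csv",
    "fit_table",
]


class ConvergenceError(RuntimeError):
    """Raised when the least-squares optimizer fails to converge."""


@dataclass(frozen=True)
class SchnuteParams:
    """Parameters of the anchored Schnute curve.

    Attributes
    ----------
    A : float
        Rate constant (per degree-day).
    B : float
        Shape exponent (dimensionless).
    y_max : float
        Phytomer count at ``t_max``.
    t_max : float
        End of the fitted thermal-time domain (DD).
    """

    A: float
    B: float
    y_max: float
    t_max: float

    def __post_init__(self) -> None:
        vals = (self.A, self.B, self.y_max, self.t_max)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError(f"non-finite Schnute parameters: {vals}")
        if self.A <= 0 or self.B <= 0 or self.y_max <= 0 or self.t_max <= 0:
            raise ValueError(
                f"Schnute parameters must be positive: A={self.A}, B={self.B}, "
                f"y_max={self.y_max}, t_max={self.t_max}"
            )


@dataclass(frozen=True)
class PhytomerSeries:
    """Phytomer-appearance observations for one plant."""

    plant_id: str
    times: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.counts, dtype=float)
        if t.shape != c.shape or t.ndim != 1:
            raise ValueError("times and counts must be 1-D arrays of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(c < 0):
            raise ValueError("phytomer counts must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "counts", c)


@dataclass(frozen=True)
class RateSummary:
    """Maximum phytomer-appearance rate and when it occurs."""

    t_star: float        # DD of maximal rate
    v_max: float         # phytomers per DD
    at_boundary: bool    # rate maximal at the domain edge (B >= 1)


def schnute_eval(params: SchnuteParams, t) -> np.ndarray | float:
    """Evaluate the phytomer-appearance curve at thermal time(s) ``t`` (DD)."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("thermal time must be non-negative")
    denom = -np.expm1(-params.A * params.t_max)
    y = params.y_max * (-np.expm1(-params.A * t_arr) / denom) ** (1.0 / params.B)
    return float(y) if np.isscalar(t) else y


def schnute_derivative(params: SchnuteParams, t) -> np.ndarray | float:
    """First derivative dY/dt (phytomers per DD)."""
    t_arr = np.asarray(t, dtype=float)
    denom = -np.expm1(-params.A * params.t_max)
    u = -np.expm1(-params.A * t_arr)  # 1 - exp(-A t)
    with np.errstate(divide="ignore", over="ignore"):
        dy = (
            params.y_max
            / denom ** (1.0 / params.B)
            * (1.0 / params.B)
            * np.where(u > 0, u, np.nan) ** (1.0 / params.B - 1.0)
            * params.A
            * np.exp(-params.A * t_arr)
        )
    dy = np.where(u > 0, dy, np.inf if params.B > 1 else np.nan)
    if params.B == 1.0:
        dy = np.where(u > 0, dy, params.y_max * params.A / denom)
    return float(dy) if np.isscalar(t) else dy


def schnute_inverse(params: SchnuteParams, y) -> np.ndarray | float:
    """Thermal time at which the curve reaches count ``y`` (0 <= y <= y_max)."""
    y_arr = np.asarray(y, dtype=float)
    if np.any(y_arr < 0) or np.any(y_arr > params.y_max * (1 + 1e-12)):
        raise ValueError("y outside [0, y_max]")
    denom = -np.expm1(-params.A * params.t_max)
    u = (np.minimum(y_arr, params.y_max) / params.y_max) ** params.B * denom
    t = -np.log1p(-u) / params.A
    return float(t) if np.isscalar(y) else t


def schnute_rate(params: SchnuteParams) -> RateSummary:
    """Locate the maximum of dY/dt on (0, t_max].

    The interior maximum has the closed form ``t* = -ln(B)/A`` when
    0 < B < 1; otherwise the rate decreases from the domain edge and the
    summary is flagged ``at_boundary``.
    """
    if params.B < 1.0:
        t_star = -np.log(params.B) / params.A
        boundary = False
        if t_star >= params.t_max:
            t_star = params.t_max
            boundary = True
    else:
        # rate is decreasing (B=1) or singular at 0+ (B>1)
        t_star = min(1e-6, params.t_max)
        boundary = True
    v_max = float(schnute_derivative(params, t_star))
    return RateSummary(t_star=float(t_star), v_max=v_max, at_boundary=boundary)


DEFAULT_INIT_B = 0.5


class SchnuteModel:
    """Schnute phytomer-appearance model for one plant's series.

    Parameters
    ----------
    series : PhytomerSeries
        Observed counts against thermal time.  ``t_max`` is fixed to the
        last observation time.
    """

    def __init__(self, series: PhytomerSeries):
        if len(series.times) < 5:
            raise ValueError(
                f"need at least 5 observations to fit, got {len(series.times)}"
            )
        self.series = series
        self.t_max = float(series.times[-1])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, plant_id: str) -> "SchnuteModel":
        """Build a model from a tidy frame with columns
        ``plant_id, thermal_time_dd, phytomer_count``."""
        sub = df[df["plant_id"].astype(str) == str(plant_id)]
        sub = sub.sort_values("thermal_time_dd")
        return cls(
            PhytomerSeries(
                plant_id=str(plant_id),
                times=sub["thermal_time_dd"].to_numpy(float),
                counts=sub["phytomer_count"].to_numpy(float),
            )
        )

    def _default_init(self) -> SchnuteParams:
        return SchnuteParams(
            A=2.0 / self.t_max,
            B=DEFAULT_INIT_B,
            y_max=max(float(np.max(self.series.counts)), 1e-6),
            t_max=self.t_max,
        )

    def fit(self, init: SchnuteParams | None = None, max_nfev: int = 2000) -> "SchnuteResults":
        """Least-squares fit (Levenberg-Marquardt) of ``A, B, y_max``.

        Raises
        ------
        ConvergenceError
            If the optimizer reports failure, or the data are degenerate
            (e.g. a constant series pushed to a parameter boundary).
        """
        if np.ptp(self.series.counts) == 0:
            raise ConvergenceError(
                f"plant {self.series.plant_id}: constant phytomer series, "
                "Schnute fit is unidentifiable"
            )
        x0 = init or self._default_init()
        t, c = self.series.times, self.series.counts

        def resid(theta):
            a, b, ym = theta
            p = SchnuteParams(A=abs(a), B=abs(b), y_max=abs(ym), t_max=self.t_max)
            return schnute_eval(p, t) - c

        sol = least_squares(
            resid, x0=[x0.A, x0.B, x0.y_max], method="lm", max_nfev=max_nfev
        )
        if not sol.success or not np.all(np.isfinite(sol.x)):
            raise ConvergenceError(
                f"plant {self.series.plant_id}: Levenberg-Marquardt did not "
                f"converge (status {sol.status}: {sol.message})"
            )
        params = SchnuteParams(
            A=abs(float(sol.x[0])),
            B=abs(float(sol.x[1])),
            y_max=abs(float(sol.x[2])),
            t_max=self.t_max,
        )
        residuals = schnute_eval(params, t) - c
        rmse = float(np.sqrt(np.mean(residuals**2)))
        return SchnuteResults(
            model=self,
            params=params,
            residuals=residuals,
            rmse=rmse,
            n_iter=int(sol.nfev),
        )


@dataclass
class SchnuteResults:
    """Fitted Schnute curve with goodness of fit and rate diagnostics."""

    model: SchnuteModel
    params: SchnuteParams
    residuals: np.ndarray
    rmse: float
    n_iter: int
    rate: RateSummary = field(init=False)

    def __post_init__(self) -> None:
        self.rate = schnute_rate(self.params)

    def predict(self, t) -> np.ndarray | float:
        return schnute_eval(self.params, t)

    def summary(self) -> str:
        p, r = self.params, self.rate
        lines = [
            "Schnute phytomer-appearance fit",
            "=" * 38,
            f"plant            {self.model.series.plant_id}",
            f"n obs            {len(self.model.series.times)}",
            f"A (x1e-3 DD^-1)  {p.A * 1e3:8.3f}",
            f"B                {p.B:8.3f}",
            f"y_max            {p.y_max:8.2f}",
            f"t_max (DD)       {p.t_max:8.1f}",
            f"RMSE (phytomers) {self.rmse:8.3f}",
            f"t* (DD)          {r.t_star:8.1f}" + ("  [boundary]" if r.at_boundary else ""),
            f"v_max (phy/DD)   {r.v_max:8.4f}",
        ]
        return "\n".join(lines)


def read_phytomer_csv(path) -> pd.DataFrame:
    """Read a phytomer time-series CSV with columns
    ``plant_id, thermal_time_dd, phytomer_count``."""
    df = pd.read_csv(path)
    required = {"plant_id", "thermal_time_dd", "phytomer_count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"phytomer CSV missing columns: {sorted(missing)}")
    return df


def fit_table(df: pd.DataFrame, group: str = "cultivar") -> pd.DataFrame:
    """Fit every plant series in ``df`` and summarize per cultivar.

    Returns one row per group with the mean +/- SD of per-plant parameter
    estimates, the mean RMSE and the rate summary derived from the mean
    parameters (columns: A_x1e3, B, y_max, rmse, t_star_dd, v_max).
    """
    rows = []
    group_col = group if group in df.columns else "plant_id"
    for g, sub in df.groupby(group_col):
        fits = []
        for pid in sub["plant_id"].unique():
            try:
                fits.append(SchnuteModel.from_dataframe(sub, pid).fit())
            except ConvergenceError:
                continue
        if not fits:
            continue
        A = np.array([f.params.A for f in fits])
        B = np.array([f.params.B for f in fits])
        ym = np.array([f.params.y_max for f in fits])
        mean_params = SchnuteParams(
            A=float(A.mean()), B=float(B.mean()), y_max=float(ym.mean()),
            t_max=float(np.mean([f.params.t_max for f in fits])),
        )
        rate = schnute_rate(mean_params)
        rows.append({
            group_col: g,
            "n_plants": len(fits),
            "A_x1e3": A.mean() * 1e3,
            "A_x1e3_sd": A.std(ddof=1) * 1e3 if len(fits) > 1 else 0.0,
            "B": B.mean(),
            "B_sd": B.std(ddof=1) if len(fits) > 1 else 0.0,
            "y_max": ym.mean(),
            "y_max_sd": ym.std(ddof=1) if len(fits) > 1 else 0.0,
            "rmse": float(np.mean([f.rmse for f in fits])),
            "t_star_dd": rate.t_star,
            "v_max": rate.v_max,
        })
    return pd.DataFrame(rows)
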