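"""Growth-rate estimation, cumulative cell divisions, and the monotone
fitness trajectory.

The maximum specific growth rate mu_max is the steepest slope of
ln(OD600 - blank) over a rolling window of consecutive readings, fitted by
least squares per window -- the standard rolling log-linear estimator for
microbial growth curves.  Adaptive-evolution bookkeeping counts divisions
per passage as net new cells (N_final - N_inoculum, exactly one division
per new cell under binary fission) and accumulates them across passages.
Fitness versus cumulative cell divisions is summarised by a smooth,
monotone cubic curve: isotonic regression projects the fitness values onto
a non-decreasing sequence, and a PCHIP (monotonicity-preserving piecewise
cubic Hermite) interpolant through the projected points yields a C1,
non-decreasing function on the full data range.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator, make_smoothing_spline
from scipy.optimize import isotonic_regression

#: Default conversion from optical density to cell count,
#: in cells per OD600 unit per mL.
DEFAULT_CELLS_PER_OD_PER_ML = 8e8


@dataclass
class GrowthCurve:
    """An OD600 time series with an optional blank offset."""

    time_h: np.ndarray
    od600: np.ndarray
    blank: float = 0.0

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.od600 = np.asarray(self.od600, dtype=float)
        if self.time_h.shape != self.od600.shape or self.time_h.ndim != 1:
            raise ValueError("time_h and od600 must be 1-D arrays of equal length")
        if len(self.time_h) and not np.all(np.diff(self.time_h) > 0):
            raise ValueError("time_h must be strictly increasing")
        if (self.od600 < 0).any():
            raise ValueError("od600 readings must be non-negative")

    @classmethod
    def from_csv(cls, path, blank: float = 0.0) -> "GrowthCurve":
        df = pd.read_csv(path)
        return cls(time_h=df["time_h"].to_numpy(), od600=df["od600"].to_numpy(), blank=blank)

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_h": self.time_h, "od600": self.od600}).to_csv(path, index=False)


@dataclass(frozen=True)
class GrowthRateEstimate:
    mu_max: float  # per hour
    window: tuple[float, float]  # (t_start, t_end) of the best window
    r_squared: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.mu_max):
            raise ValueError("mu_max must be finite")


def growth_rate(curve: GrowthCurve, window_points: int = 5) -> GrowthRateEstimate:
    """Maximum slope of ln(OD - blank) over rolling windows.

    Windows containing a non-positive blanked reading are skipped.  Raises
    if fewer than ``window_points`` usable readings exist.  R-squared is
    reported for the winning window (1.0 for an exactly flat window).
    """
    if window_points < 3:
        raise ValueError("window_points must be >= 3")
    od = curve.od600 - curve.blank
    usable = od > 0
    if int(usable.sum()) < window_points:
        raise ValueError(
            f"need at least {window_points} readings above blank, "
            f"got {int(usable.sum())}"
        )
    t = curve.time_h
    best: tuple[float, tuple[float, float], float] | None = None
    for i in range(len(t) - window_points + 1):
        j = i + window_points
        if not usable[i:j].all():
            continue
        x = t[i:j]
        y = np.log(od[i:j])
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
        if best is None or slope > best[0]:
            best = (float(slope), (float(x[0]), float(x[-1])), r2)
    if best is None:
        raise ValueError("no contiguous window of usable readings above blank")
    return GrowthRateEstimate(mu_max=best[0], window=best[1], r_squared=best[2])


def cells_from_od(od: float, volume_ml: float,
                  cells_per_od_per_ml: float = DEFAULT_CELLS_PER_OD_PER_ML) -> float:
    """Convert an OD600 reading in a culture volume to a cell count."""
    return od * volume_ml * cells_per_od_per_ml


def cumulative_cell_divisions(
    passages: Sequence[tuple[float, float]] | pd.DataFrame,
    volume_ml: float | None = None,
    cells_per_od_per_ml: float = DEFAULT_CELLS_PER_OD_PER_ML,
) -> np.ndarray:
    """Running cumulative cell divisions (CCD) over serial passages.

    ``passages`` is a sequence of (inoculum_cells, final_cells) pairs, or a
    DataFrame with ``od_start``/``od_end`` (plus ``volume_ml`` column or
    argument) converted at ``cells_per_od_per_ml``.  Divisions per passage
    are net new cells; CCD is their running sum.
    """
    if isinstance(passages, pd.DataFrame):
        vol = passages["volume_ml"] if "volume_ml" in passages.columns else volume_ml
        if vol is None:
            raise ValueError("volume_ml required to convert OD to cells")
        n0 = passages["od_start"].to_numpy() * np.asarray(vol) * cells_per_od_per_ml
        nf = passages["od_end"].to_numpy() * np.asarray(vol) * cells_per_od_per_ml
        pairs = list(zip(n0, nf))
    else:
        pairs = list(passages)
    if not pairs:
        raise ValueError("at least one passage is required")
    divisions = []
    for k, (n0, nf) in enumerate(pairs):
        if n0 <= 0:
            raise ValueError(f"passage {k}: inoculum must be > 0")
        if nf < n0:
            raise ValueError(f"passage {k}: final cells below inoculum")
        divisions.append(nf - n0)
    return np.cumsum(divisions)


def fit_monotone_spline(
    x: Sequence[float],
    y: Sequence[float],
    mode: str = "interpolate",
    smoothing_lam: float | None = None,
):
    """Smooth, monotone (non-decreasing) cubic fit of fitness vs CCD.

    Duplicate x values are averaged first.  In ``interpolate`` mode the
    y values are projected to the nearest non-decreasing sequence
    (isotonic regression; monotone inputs pass through unchanged) and a
    PCHIP interpolant is built through the projected knots.  In ``smooth``
    mode a cubic smoothing spline is fitted first and its knot values are
    then projected and interpolated the same way, trading interpolation
    for noise suppression.  The result is callable anywhere in
    [min x, max x] and is non-decreasing there.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    # average duplicate abscissae
    xu, inverse = np.unique(x, return_inverse=True)
    yu = np.zeros_like(xu)
    cnt = np.zeros_like(xu)
    np.add.at(yu, inverse, y)
    np.add.at(cnt, inverse, 1.0)
    yu /= cnt
    if len(xu) < 3:
        raise ValueError("at least 3 distinct x values are required")
    if mode == "smooth":
        spl = make_smoothing_spline(xu, yu, lam=smoothing_lam)
        yu = spl(xu)
    elif mode != "interpolate":
        raise ValueError(f"unknown mode {mode!r}")
    iso = isotonic_regression(yu, increasing=True)
    return PchipInterpolator(xu, iso.x, extrapolate=False)


def ale_trajectory(
    passages: pd.DataFrame,
    volume_ml: float | None = None,
    cells_per_od_per_ml: float = DEFAULT_CELLS_PER_OD_PER_ML,
    mode: str = "interpolate",
) -> pd.DataFrame:
    """Passage-wise CCD paired with fitness plus the monotone spline fit.

    ``passages`` carries per-passage ``growth_rate`` (per hour) and either
    cell counts (``inoculum_cells``/``final_cells``) or OD bookkeeping
    (``od_start``/``od_end``/``volume_ml``).  Returns a table with columns
    ccd, fitness and spline_eval.
    """
    if {"inoculum_cells", "final_cells"} <= set(passages.columns):
        pairs = list(zip(passages["inoculum_cells"], passages["final_cells"]))
        ccd = cumulative_cell_divisions(pairs)
    else:
        ccd = cumulative_cell_divisions(
            passages, volume_ml=volume_ml, cells_per_od_per_ml=cells_per_od_per_ml
        )
    fitness = passages["growth_rate"].to_numpy(dtype=float)
    spline = fit_monotone_spline(ccd, fitness, mode=mode)
    return pd.DataFrame(
        {"ccd": ccd, "fitness": fitness, "spline_eval": spline(ccd)}
    )
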