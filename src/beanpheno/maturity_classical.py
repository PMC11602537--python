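"""Relative maturity from a vegetation-index time series.

The canopy greenness of a dry-bean plot (mean GLI per flight) decays as pods
brown down.  A smooth curve is fitted through the per-flight means - either a
LOESS local polynomial or a continuous segmented (piecewise-linear)
regression - and the maturity date is read off as the day the fitted curve
first falls to the 0.06 GLI threshold after its seasonal maximum, refined by
linear interpolation between grid points.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .vegindex import VITimeSeries

DEFAULT_THRESHOLD = 0.06


@dataclass
class FittedCurve:
    grid: np.ndarray
    values: np.ndarray
    method: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.size != self.values.size:
            raise ValueError("grid and values must have the same length")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")


@dataclass
class MaturityEstimate:
    plot_id: str
    maturity_dap: float          # NaN when status == "never_crossed"
    method: str
    threshold: float
    status: str                  # crossed | never_crossed


def _day_grid(days: np.ndarray, grid_step: float) -> np.ndarray:
    n = int(np.floor((days[-1] - days[0]) / grid_step + 1e-9)) + 1
    return days[0] + grid_step * np.arange(n)


def fit_loess(series: VITimeSeries, span: float = 0.75, degree: int = 2,
              grid_step: float = 0.1) -> FittedCurve:
    """Tricube-weighted local polynomial fit evaluated on a dense day grid.

    ``span`` is the fraction of observations in each local neighborhood;
    ``degree`` is 1 (local lines) or 2 (local parabolas).
    """
    x, y = series.days, series.values
    n = x.size
    if n < 4:
        raise ValueError(f"plot {series.plot_id}: LOESS needs >=4 observations, got {n}")
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    k = max(int(np.ceil(span * n)), degree + 1)
    if k > n:
        raise ValueError(
            f"plot {series.plot_id}: span {span} with degree {degree} needs "
            f"{degree + 1} points but only {n} available")
    grid = _day_grid(x, grid_step)
    fitted = np.empty_like(grid)
    for i, g in enumerate(grid):
        d = np.abs(x - g)
        h = np.sort(d)[k - 1]
        if h == 0:
            h = max(np.sort(d)[-1], 1e-12)
        w = np.clip(1.0 - (d / h) ** 3, 0.0, None) ** 3
        w[d >= h] = 0.0
        if np.count_nonzero(w) < degree + 1:      # widen until solvable
            w = np.clip(1.0 - (d / (d.max() + 1e-12)) ** 3, 1e-6, None) ** 3
        sw = np.sqrt(w)
        design = np.vander(x - g, degree + 1, increasing=True)
        coef, *_ = np.linalg.lstsq(design * sw[:, None], y * sw, rcond=None)
        fitted[i] = coef[0]
    return FittedCurve(grid, fitted, "LOESS",
                       {"span": span, "degree": degree, "plot_id": series.plot_id})


def _hinge_design(x: np.ndarray, breaks: tuple[float, ...]) -> np.ndarray:
    cols = [np.ones_like(x), x]
    cols += [np.clip(x - b, 0.0, None) for b in breaks]
    return np.column_stack(cols)


def _segmented_sse(x, y, breaks):
    design = _hinge_design(x, breaks)
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return float(resid @ resid), coef


def fit_segmented(series: VITimeSeries, n_breakpoints: int = 2,
                  grid_step: float = 0.1) -> FittedCurve:
    """Continuous piecewise-linear fit with breakpoints chosen by SSE search.

    Breakpoint candidates are scanned on a coarse 1-day grid between the first
    and last observed day, then the best combination is refined locally at
    ``grid_step`` resolution.  The hinge basis {1, t, (t-b)+} keeps the fit
    continuous at every breakpoint.
    """
    x, y = series.days, series.values
    n = x.size
    if n_breakpoints < 1:
        raise ValueError("n_breakpoints must be >= 1")
    if n < 2 * (n_breakpoints + 1):
        raise ValueError(
            f"plot {series.plot_id}: {n_breakpoints} breakpoints need "
            f">={2 * (n_breakpoints + 1)} observations, got {n}")

    lo, hi = x[0] + grid_step, x[-1] - grid_step

    def best_over(candidates):
        best = (np.inf, None, None)
        for combo in itertools.combinations(candidates, n_breakpoints):
            sse, coef = _segmented_sse(x, y, combo)
            if sse < best[0]:
                best = (sse, combo, coef)
        return best

    coarse = np.arange(np.ceil(lo), np.floor(hi) + 1.0, 1.0)
    if coarse.size < n_breakpoints:
        coarse = np.linspace(lo, hi, max(n_breakpoints, 2))
    sse, breaks, coef = best_over(coarse)

    # local refinement: +-1 day around each coarse breakpoint at grid_step
    refine = [np.clip(np.arange(b - 1.0, b + 1.0 + grid_step / 2, grid_step), lo, hi)
              for b in breaks]
    local = np.unique(np.concatenate(refine))
    sse_r, breaks_r, coef_r = best_over(local)
    if sse_r < sse:
        sse, breaks, coef = sse_r, breaks_r, coef_r

    grid = _day_grid(x, grid_step)
    fitted = _hinge_design(grid, breaks) @ coef
    slopes = np.cumsum(coef[1:])  # slope in each successive segment
    return FittedCurve(grid, fitted, "SEG",
                       {"breakpoints": list(breaks), "sse": sse,
                        "segment_slopes": slopes.tolist(), "plot_id": series.plot_id})


def estimate_maturity(curve: FittedCurve, threshold: float = DEFAULT_THRESHOLD,
                      plot_id: str | None = None) -> MaturityEstimate:
    """First day the fitted curve falls to <= threshold after its maximum.

    Greenness can dip spuriously before canopy closure, so the search starts
    at the curve maximum; the crossing day is linearly interpolated between
    the bracketing grid points.  A curve that never reaches the threshold is
    flagged ``never_crossed``; one already at/below it starts ``crossed`` at
    the first grid day.
    """
    if curve.grid.size == 0:
        raise ValueError("empty fitted curve")
    pid = plot_id if plot_id is not None else str(curve.meta.get("plot_id", ""))
    g, v = curve.grid, curve.values
    start = int(np.argmax(v))
    if v[start] <= threshold:
        return MaturityEstimate(pid, float(g[0]), curve.method, threshold, "crossed")
    below = np.flatnonzero(v[start:] <= threshold)
    if below.size == 0:
        return MaturityEstimate(pid, float("nan"), curve.method, threshold, "never_crossed")
    i = start + below[0]
    day = g[i - 1] + (g[i] - g[i - 1]) * (v[i - 1] - threshold) / (v[i - 1] - v[i])
    return MaturityEstimate(pid, float(day), curve.method, threshold, "crossed")


def estimate_from_series(series: VITimeSeries, method: str = "loess",
                         threshold: float = DEFAULT_THRESHOLD,
                         **fit_kwargs) -> MaturityEstimate:
    """Fit ``series`` with LOESS or SEG and return the threshold crossing."""
    method = method.lower()
    if method == "loess":
        curve = fit_loess(series, **fit_kwargs)
    elif method == "seg":
        curve = fit_segmented(series, **fit_kwargs)
    else:
        raise ValueError(f"unknown method {method!r}; use 'loess' or 'seg'")
    return estimate_maturity(curve, threshold, plot_id=series.plot_id)


def estimate_table(series_list: list[VITimeSeries], method: str = "loess",
                   threshold: float = DEFAULT_THRESHOLD, **fit_kwargs) -> pd.DataFrame:
    """Per-plot maturity estimates as the output CSV table."""
    rows = []
    for s in series_list:
        est = estimate_from_series(s, method=method, threshold=threshold, **fit_kwargs)
        rows.append({"plot_id": est.plot_id, "method": est.method,
                     "maturity_dap": est.maturity_dap, "status": est.status,
                     "threshold": est.threshold})
    return pd.DataFrame(rows)
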