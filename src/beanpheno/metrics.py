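"""Shared accuracy metrics for predicted-vs-ground-truth comparisons."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class RegressionMetrics:
    mae: float
    mse: float
    rmse: float
    r: float        # Pearson correlation; NaN when either series is constant
    r2: float       # square of Pearson r (not 1 - SSE/SST)
    n: int


def regression_metrics(predicted, ground_truth) -> RegressionMetrics:
    """MAE, MSE, RMSE, Pearson r and r^2 between aligned vectors.

    r^2 is reported as the square of the Pearson correlation, which differs
    from the regression coefficient of determination for biased predictors.
    """
    p = np.asarray(predicted, dtype=float)
    g = np.asarray(ground_truth, dtype=float)
    if p.shape != g.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {g.shape}")
    if p.size < 2:
        raise ValueError("need at least 2 paired observations")
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(g))):
        raise ValueError("inputs must be finite")
    d = p - g
    mae = float(np.abs(d).mean())
    mse = float((d ** 2).mean())
    if np.ptp(p) == 0 or np.ptp(g) == 0:
        r = float("nan")
    else:
        r = float(stats.pearsonr(p, g).statistic)
    return RegressionMetrics(mae=mae, mse=mse, rmse=float(np.sqrt(mse)),
                             r=r, r2=r * r, n=p.size)


def maturity_window(estimated: dict | pd.Series, ground_truth: dict | pd.Series,
                    bins=None) -> dict:
    """Histogram of signed maturity errors (estimated - GT) across plots.

    Returns the per-plot differences, the binned counts, and the share of
    plots landing within +-1 day - the headline precision figure for a
    maturity pipeline.  Plot ids must match exactly.
    """
    est = pd.Series(estimated, dtype=float)
    gt = pd.Series(ground_truth, dtype=float)
    unmatched = est.index.symmetric_difference(gt.index)
    if len(unmatched):
        raise ValueError(f"unmatched plot ids: {sorted(map(str, unmatched))}")
    diff = (est - gt).reindex(est.index)
    values = diff.to_numpy()
    if bins is None:
        lo = np.floor(values.min()) if values.size else -1
        hi = np.ceil(values.max()) if values.size else 1
        bins = np.arange(lo - 0.5, hi + 1.5)
    counts, edges = np.histogram(values, bins=bins)
    share = float(np.mean((values >= -1) & (values <= 1))) if values.size else float("nan")
    return {"differences": diff, "counts": counts, "bin_edges": edges,
            "share_within_1d": share}
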