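"""Reference connectivity estimators: Pearson correlation networks and
bivariate Granger causality."""

from __future__ import annotations

import numpy as np
from scipy import stats

from .types import DirectedConnectome, RoiTimeSeries

__all__ = ["pearson_connectome", "bivariate_granger", "granger_connectome"]


def pearson_connectome(X: RoiTimeSeries) -> DirectedConnectome:
    """Undirected functional-connectivity network: entry ``(m, i)`` is the
    sample Pearson correlation of regions ``m`` and ``i`` (diagonal zeroed)."""
    sd = X.values.std(axis=0)
    if np.any(sd == 0):
        bad = X.region_names[int(np.argmin(sd))]
        raise ValueError(
            f"region {bad!r} has zero variance; correlation undefined"
        )
    weights = np.corrcoef(X.values, rowvar=False)
    np.fill_diagonal(weights, 0.0)
    return DirectedConnectome(weights=weights,
                              region_names=list(X.region_names),
                              directed=False, method_tag="pearson")


def _lag_design(x: np.ndarray, lag: int) -> np.ndarray:
    """Columns x[t-1], ..., x[t-lag] aligned with targets x[lag:]."""
    return np.column_stack([x[lag - j - 1: len(x) - j - 1]
                            for j in range(lag)])


def bivariate_granger(X: RoiTimeSeries, lag: int = 1
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise Granger-causality F-tests.

    For each ordered pair ``(m, i)`` the restricted model predicts region
    ``i`` from its own ``lag`` past values (plus intercept); the full model
    adds the past values of region ``m``.  The standard nested-model F
    statistic with ``(lag, t - lag - 2*lag - 1)`` degrees of freedom and its
    p-value are returned as ``v x v`` matrices (entry ``(m, i)`` tests
    ``m -> i``; diagonal zero / one).  Matrices are generally asymmetric.
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    t, v = X.t, X.v
    if t <= 3 * lag + 3:
        raise ValueError(
            f"need t > 3*lag + 3 = {3 * lag + 3} time points, got {t}"
        )
    n = t - lag
    df_denom = n - 2 * lag - 1
    f_mat = np.zeros((v, v))
    p_mat = np.ones((v, v))
    designs = [_lag_design(X.values[:, j], lag) for j in range(v)]
    intercept = np.ones((n, 1))
    for i in range(v):
        y = X.values[lag:, i]
        xr = np.hstack([intercept, designs[i]])
        beta_r, *_ = np.linalg.lstsq(xr, y, rcond=None)
        rss_r = float(np.sum((y - xr @ beta_r) ** 2))
        for m in range(v):
            if m == i:
                continue
            xf = np.hstack([xr, designs[m]])
            beta_f, *_ = np.linalg.lstsq(xf, y, rcond=None)
            rss_f = float(np.sum((y - xf @ beta_f) ** 2))
            if rss_f <= 0:
                f_stat = np.inf
            else:
                f_stat = max(0.0, (rss_r - rss_f) / lag / (rss_f / df_denom))
            f_mat[m, i] = f_stat
            p_mat[m, i] = float(stats.f.sf(f_stat, lag, df_denom))
    return f_mat, p_mat


def granger_connectome(X: RoiTimeSeries, lag: int = 1) -> DirectedConnectome:
    """Directed network whose edge weights are the Granger F-statistics."""
    f_mat, _ = bivariate_granger(X, lag=lag)
    return DirectedConnectome(weights=f_mat,
                              region_names=list(X.region_names),
                              directed=True, method_tag=f"granger-lag{lag}")
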