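"""Error metrics, per-station profiles and run summaries.

The percentage-error profile compares an estimated v-velocity against the
centre-plane ground truth at a set of streamwise stations.  Definition D1
(the default): at station y, error% = 100 * sum over dye pixels of
|v_est - v_truth| / sum of |v_truth| — a station-wise relative L1 error.
Two alternatives are available behind the ``definition`` tag: ``mean``
(pointwise mean of |dv|/|v|) and ``max`` (normalization by the station
max |v_truth|).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator
from scipy.stats import ttest_rel

__all__ = ["mae", "mse", "ErrorProfile", "v_error_profile", "extract_profile",
           "summarize_run", "DEFAULT_STATIONS"]

#: streamwise stations (m) for the velocity-profile comparisons
DEFAULT_STATIONS = (0.00083, 0.00166, 0.00332, 0.00498, 0.00664,
                    0.00830, 0.00996, 0.01162, 0.01328)


def mae(pred, truth) -> float:
    """Mean absolute error, ``1/n * sum |p_i - g_i|``."""
    p = np.asarray(pred, float).ravel()
    g = np.asarray(truth, float).ravel()
    if p.size == 0 or p.size != g.size:
        raise ValueError("inputs must be non-empty and of equal length")
    return float(np.mean(np.abs(p - g)))


def mse(pred, truth) -> float:
    """Mean squared error, ``1/n * sum (p_i - g_i)^2``."""
    p = np.asarray(pred, float).ravel()
    g = np.asarray(truth, float).ravel()
    if p.size == 0 or p.size != g.size:
        raise ValueError("inputs must be non-empty and of equal length")
    return float(np.mean((p - g) ** 2))


@dataclass
class ErrorProfile:
    """Per-station percentage errors for one or more estimators."""

    y_stations: np.ndarray
    errors: dict                     # name -> array of % errors (NaN = skipped)
    definition: str = "D1"

    def average(self, name: str, y_min: float = 0.0) -> float:
        """Unweighted mean of station errors with y >= y_min."""
        e = np.asarray(self.errors[name], float)
        sel = (np.asarray(self.y_stations) >= y_min) & np.isfinite(e)
        if not sel.any():
            raise ValueError("no stations selected")
        return float(e[sel].mean())

    def max_error(self, name: str) -> float:
        e = np.asarray(self.errors[name], float)
        return float(np.nanmax(e))

    def to_frame(self) -> pd.DataFrame:
        data = {"y_m": np.asarray(self.y_stations)}
        for k, v in self.errors.items():
            data[f"err_{k}_pct"] = v
        return pd.DataFrame(data)


def _station_error(v_est, v_truth, definition):
    if definition == "D1":
        denom = np.sum(np.abs(v_truth))
        if denom <= 0:
            return np.nan
        return 100.0 * np.sum(np.abs(v_est - v_truth)) / denom
    if definition == "mean":
        vt = np.abs(v_truth)
        ok = vt > 0
        if not ok.any():
            return np.nan
        return 100.0 * np.mean(np.abs(v_est[ok] - v_truth[ok]) / vt[ok])
    if definition == "max":
        denom = np.max(np.abs(v_truth))
        if denom <= 0:
            return np.nan
        return 100.0 * np.mean(np.abs(v_est - v_truth)) / denom
    raise ValueError(f"unknown error definition {definition!r}")


def v_error_profile(
    table: pd.DataFrame,
    estimates: dict,
    y_stations=DEFAULT_STATIONS,
    station_halfwidth: float | None = None,
    definition: str = "D1",
) -> ErrorProfile:
    """Station-wise percentage error of v-velocity estimates.

    ``table`` holds dye-pixel records with ``y_m`` and ``v_truth``
    columns; ``estimates`` maps an estimator name to a per-record array
    of v estimates (e.g. the raw ``v_ofm`` column or model predictions).
    Records are binned to the nearest station within ``station_halfwidth``
    (default: half the smallest station spacing); a station whose truth
    is identically zero is skipped with a warning.
    """
    y_stations = np.asarray(y_stations, float)
    y = table["y_m"].to_numpy()
    vt = table["v_truth"].to_numpy()
    if station_halfwidth is None:
        if y_stations.size > 1:
            station_halfwidth = 0.5 * np.min(np.diff(np.sort(y_stations)))
        else:
            station_halfwidth = np.inf

    errors = {name: np.full(y_stations.size, np.nan) for name in estimates}
    for si, ys in enumerate(y_stations):
        sel = np.abs(y - ys) <= station_halfwidth
        # bind each record to its nearest station only
        nearest = np.abs(y[:, None] - y_stations[None, :]).argmin(axis=1) == si
        sel &= nearest
        if not sel.any():
            continue
        for name, est in estimates.items():
            est = np.asarray(est, float)
            e = _station_error(est[sel], vt[sel], definition)
            if np.isnan(e):
                warnings.warn(f"station y={ys} skipped: zero mean |v_truth|")
            errors[name][si] = e
    return ErrorProfile(y_stations=y_stations, errors=errors, definition=definition)


def extract_profile(field_u: np.ndarray, field_v: np.ndarray,
                    x: np.ndarray, y: np.ndarray, y_station: float):
    """Sample (u, v) along the horizontal line at ``y_station``.

    Bilinear interpolation on the (x, y) grids of a planar field; exact
    at grid rows.  Returns ``(x, u, v)``.
    """
    if not (y.min() <= y_station <= y.max()):
        raise ValueError(f"y={y_station} outside field extent [{y.min()}, {y.max()}]")
    ui = RegularGridInterpolator((x, y), field_u)
    vi = RegularGridInterpolator((x, y), field_v)
    pts = np.column_stack([x, np.full_like(x, y_station)])
    return x, ui(pts), vi(pts)


def summarize_run(cv_scores: pd.DataFrame, profile: ErrorProfile | None = None,
                  baseline: str = "lasso") -> dict:
    """Performance-table-style report with significance markers.

    Aggregates fold scores per (model, loss), attaches a paired t-test of
    each model's fold MAEs against the baseline's (same folds), and, if a
    profile is given, the OFM-vs-model average v-error reduction.
    """
    grid = (cv_scores.groupby(["model", "loss"])
            .agg(mae_mean=("mae", "mean"), mae_std=("mae", "std"),
                 mse_mean=("mse", "mean"), mse_std=("mse", "std"))
            .reset_index())

    pvals = []
    for _, row in grid.iterrows():
        if row["model"] == baseline:
            pvals.append(np.nan)
            continue
        a = cv_scores.query("model == @row.model and loss == @row.loss")["mae"].to_numpy()
        b = cv_scores.query("model == @baseline and loss == @row.loss")["mae"].to_numpy()
        if a.size == b.size and a.size > 1 and not np.allclose(a, b):
            pvals.append(float(ttest_rel(a, b).pvalue))
        else:
            pvals.append(np.nan)
    grid["p_vs_baseline"] = pvals

    report = {"table": grid}
    if profile is not None:
        report["profile"] = profile.to_frame()
        names = list(profile.errors)
        if "ofm" in names:
            avg_ofm = profile.average("ofm")
            report["avg_v_error_ofm_pct"] = avg_ofm
            for name in names:
                if name == "ofm":
                    continue
                avg = profile.average(name)
                report[f"avg_v_error_{name}_pct"] = avg
                report[f"error_reduction_factor_{name}"] = avg_ofm / avg if avg > 0 else np.inf
    return report


def format_report(report: dict) -> str:
    """Human-readable text rendering of a summarize_run report."""
    lines = ["model performance (CV fold scores, m/s)"]
    lines.append(report["table"].to_string(index=False,
                                           float_format=lambda v: f"{v:.3e}"))
    for k, v in report.items():
        if isinstance(v, float):
            lines.append(f"{k}: {v:.4g}")
    return "\n".join(lines)
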