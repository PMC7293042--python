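"""Cell-index doubling time from impedance growth curves.

A real-time impedance proliferation assay reports an arbitrary "cell index"
CI per well over time.  During exponential growth the index follows
CI_i = CI_1 * 2^((t_i - t_1)/DT), which is exactly log-linear, so DT is
estimated by ordinary least squares of log2(CI) on (t - t_1) within a
user-chosen exponential window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class GrowthSeries:
    """An impedance time course; times in hours, strictly increasing."""

    time_h: np.ndarray
    cell_index: np.ndarray
    window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.cell_index = np.asarray(self.cell_index, dtype=float)
        if self.time_h.shape != self.cell_index.shape:
            raise ValueError("time and cell index lengths differ")
        if np.any(np.diff(self.time_h) <= 0):
            raise ValueError("time points must be strictly increasing")

    def windowed(self) -> tuple[np.ndarray, np.ndarray]:
        if self.window is None:
            return self.time_h, self.cell_index
        lo, hi = self.window
        sel = (self.time_h >= lo) & (self.time_h <= hi)
        return self.time_h[sel], self.cell_index[sel]


@dataclass
class DoublingTimeFit:
    doubling_time_h: float  # NaN when the series is not growing
    ci_1: float
    rss_log2: float
    n_points: int

    @property
    def is_growing(self) -> bool:
        return np.isfinite(self.doubling_time_h)


def fit_doubling_time(series: GrowthSeries) -> DoublingTimeFit:
    """Least-squares fit of the exponential cell-index model.

    Fits log2(CI) = log2(CI_1) + (t - t_1)/DT inside the analysis window.
    Requires at least 3 points with positive CI; a non-positive slope
    (non-growing series) yields an undefined doubling time (NaN).
    """
    t, ci = series.windowed()
    if t.size < 3:
        raise ValueError("need at least 3 points in the analysis window")
    if np.any(ci <= 0):
        raise ValueError("cell index must be positive within the window")
    x = t - t[0]
    y = np.log2(ci)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    rss = float(resid @ resid)
    dt = 1.0 / slope if slope > 0 else float("nan")
    return DoublingTimeFit(
        doubling_time_h=float(dt),
        ci_1=float(2.0 ** intercept),
        rss_log2=rss,
        n_points=int(t.size),
    )


def fit_growth_table(
    frame: pd.DataFrame, window: tuple[float, float] | None = None
) -> pd.DataFrame:
    """Fit every replicate of a (time_h, ci, replicate[, group]) table.

    Returns one row per replicate plus, when a ``group`` column is present,
    mean and SD of the doubling time per group.
    """
    required = {"time_h", "ci", "replicate"}
    if missing := required - set(frame.columns):
        raise ValueError(f"growth table misses columns {sorted(missing)}")
    rows = []
    for rep, grp in frame.groupby("replicate"):
        grp = grp.sort_values("time_h")
        fit = fit_doubling_time(
            GrowthSeries(grp["time_h"].to_numpy(), grp["ci"].to_numpy(), window)
        )
        row = {
            "replicate": rep,
            "doubling_time_h": fit.doubling_time_h,
            "ci_1": fit.ci_1,
            "rss_log2": fit.rss_log2,
            "n_points": fit.n_points,
        }
        if "group" in frame.columns:
            row["group"] = grp["group"].iloc[0]
        rows.append(row)
    out = pd.DataFrame(rows)
    if "group" in out.columns:
        summary = (
            out.groupby("group")["doubling_time_h"]
            .agg(["mean", "std", "count"])
            .reset_index()
            .rename(
                columns={
                    "mean": "doubling_time_mean_h",
                    "std": "doubling_time_sd_h",
                    "count": "n_replicates",
                }
            )
        )
        out.attrs["group_summary"] = summary
    return out


def simulate_growth_series(
    doubling_time_h: float,
    ci_1: float = 1.0,
    t_max_h: float = 96.0,
    dt_h: float = 2.0,
    noise_sd_log2: float = 0.0,
    rng: np.random.Generator | None = None,
) -> GrowthSeries:
    """Model-generated series, optionally with log-normal noise."""
    t = np.arange(0.0, t_max_h + dt_h / 2, dt_h)
    log2ci = np.log2(ci_1) + t / doubling_time_h
    if noise_sd_log2 > 0:
        if rng is None:
            raise ValueError("noise requires an rng")
        log2ci = log2ci + rng.normal(0.0, noise_sd_log2, t.size)
    return GrowthSeries(t, 2.0 ** log2ci)
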