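"""Maximum growth rate from plate-reader OD600 time series.

The maximum (exponential-phase) growth rate of a culture is estimated
without fitting a parametric growth model: ordinary least-squares slopes
are computed in overlapping ten-timepoint sliding windows along the
curve, and the 98th percentile of the slope set is reported. The high
percentile targets the steepest sustained stretch of the curve while
remaining robust to a single aberrant window; slopes are per hour.

By default the regression is on natural-log OD, so the slope is the
specific growth rate (h^-1) and the estimate is invariant to the
instrument's OD scale. A linear-OD mode is also available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GrowthCurve",
    "GrowthRate",
    "FitnessChange",
    "sliding_slopes",
    "max_growth_rate",
    "fitness_change",
    "summarize_replicates",
    "read_growth_csv",
]

DEFAULT_WINDOW = 10  # timepoints
DEFAULT_PERCENTILE = 98.0
_OD_FLOOR = 1e-4  # floor after blank subtraction, before log


@dataclass
class GrowthCurve:
    """One well's OD600 trajectory (times in minutes from start)."""

    strain_id: str
    replicate_id: str
    times: np.ndarray
    od: np.ndarray
    blank: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.size != self.od.size:
            raise ValueError("times and od must have equal length")
        if self.times.size < 10:
            raise ValueError("growth curve needs at least 10 timepoints")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class GrowthRate:
    strain_id: str
    replicate_id: str
    rate: float  # per hour
    n_windows: int


@dataclass
class FitnessChange:
    line_id: str
    kind: str  # "by_wgd" | "post_wgd_per_generation" | "mid_experiment"
    delta: float  # per hour, or per hour per generation when divided
    generations: int | None = None


def sliding_slopes(
    curve: GrowthCurve,
    window: int = DEFAULT_WINDOW,
    transform: str = "log",
) -> np.ndarray:
    """OLS slope (per hour) in each overlapping ``window``-point window.

    With ``transform="log"`` the regression is on ln(OD); windows that
    contain a non-positive OD value (after optional blank subtraction)
    are skipped with a warning. Window i covers indices i..i+window-1
    for i = 0..n-window.
    """
    if transform not in ("log", "linear"):
        raise ValueError("transform must be 'log' or 'linear'")
    n = curve.times.size
    if n < window:
        raise ValueError(f"curve has {n} points; window of {window} required")
    t_hours = curve.times / 60.0
    od = curve.od.copy()
    if curve.blank is not None:
        od = od - curve.blank
        if np.any(od <= 0):
            warnings.warn(
                "non-positive OD after blank subtraction; flooring at "
                f"{_OD_FLOOR:g}"
            )
            od = np.maximum(od, _OD_FLOOR)
    if transform == "log":
        valid = od > 0
        y = np.where(valid, np.log(np.where(valid, od, 1.0)), np.nan)
        if not valid.all():
            warnings.warn(
                f"{int((~valid).sum())} non-positive OD values; windows "
                "containing them are skipped"
            )
    else:
        y = od
    slopes = []
    for i in range(n - window + 1):
        yw = y[i : i + window]
        if np.any(~np.isfinite(yw)):
            continue
        tw = t_hours[i : i + window]
        tc = tw - tw.mean()
        slopes.append(float(np.dot(tc, yw - yw.mean()) / np.dot(tc, tc)))
    return np.asarray(slopes)


def max_growth_rate(
    slopes: np.ndarray,
    strain_id: str = "",
    replicate_id: str = "",
    percentile: float = DEFAULT_PERCENTILE,
) -> GrowthRate:
    """98th percentile of the sliding-window slopes.

    The percentile uses linear interpolation between closest order
    statistics (numpy's default convention), fixed here for
    reproducibility across versions.
    """
    slopes = np.asarray(slopes, dtype=float)
    if slopes.size == 0:
        raise ValueError("empty slope set; cannot estimate a growth rate")
    rate = float(np.percentile(slopes, percentile, method="linear"))
    return GrowthRate(
        strain_id=strain_id,
        replicate_id=replicate_id,
        rate=rate,
        n_windows=int(slopes.size),
    )


def fitness_change(
    before: GrowthRate,
    after: GrowthRate,
    generations: int | None = None,
    line_id: str | None = None,
    kind: str | None = None,
) -> FitnessChange:
    """Difference in maximum growth rate, optionally per evolved generation.

    ``delta = after - before``; when ``generations`` is given the delta
    is divided by it (the per-generation convention used for post-WGD
    evolution over the remainder of the experiment).
    """
    delta = after.rate - before.rate
    if generations is not None:
        if generations == 0:
            raise ValueError("cannot divide fitness change by zero generations")
        delta /= generations
        default_kind = "post_wgd_per_generation"
    else:
        default_kind = "by_wgd"
    return FitnessChange(
        line_id=line_id if line_id is not None else before.strain_id,
        kind=kind if kind is not None else default_kind,
        delta=float(delta),
        generations=generations,
    )


def summarize_replicates(rates: list[GrowthRate]) -> pd.DataFrame:
    """Mean rate and standard error per strain over its replicates."""
    df = pd.DataFrame(
        [{"strain_id": r.strain_id, "rate": r.rate} for r in rates]
    )
    if df.empty:
        return pd.DataFrame(columns=["strain_id", "mean_rate", "se_rate", "n"])
    out = (
        df.groupby("strain_id")["rate"]
        .agg(mean_rate="mean", se_rate=lambda x: x.std(ddof=1) / np.sqrt(len(x)), n="size")
        .reset_index()
    )
    return out


def read_growth_csv(path) -> list[GrowthCurve]:
    """Read long-format plate-reader CSV with columns
    strain_id, replicate_id (or well), time_min, od."""
    df = pd.read_csv(path)
    rep_col = "replicate_id" if "replicate_id" in df.columns else "well"
    required = {"strain_id", rep_col, "time_min", "od"}
    if missing := required - set(df.columns):
        raise ValueError(f"growth CSV missing columns: {sorted(missing)}")
    curves = []
    for (strain, rep), grp in df.groupby(["strain_id", rep_col], sort=True):
        grp = grp.sort_values("time_min")
        curves.append(
            GrowthCurve(
                strain_id=str(strain),
                replicate_id=str(rep),
                times=grp["time_min"].to_numpy(dtype=float),
                od=grp["od"].to_numpy(dtype=float),
            )
        )
    return curves
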