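"""Ploidy inference from flow-cytometry DNA-content distributions.

A SYTOX/PI-stained asynchronous culture produces a fluorescence histogram
with two main modes: cells in G1 (one genome copy per ploidy level) and
cells in G2/M (twice that). The G1 peak position is proportional to ploidy,
so calibrating against control strains of known ploidy converts peak
position into genome copy number. Trajectories of per-timepoint ploidy
calls then reveal whole-genome duplications (WGD, e.g. 2n -> 4n), their
timing, and occasional reversions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde

__all__ = [
    "FluorescenceSample",
    "Calibration",
    "PloidyCall",
    "WGDEvent",
    "PeakDetectionError",
    "density_peaks",
    "two_main_peaks",
    "calibrate",
    "call_ploidy",
    "detect_wgd",
    "wgd_rate",
    "read_fluorescence_csv",
]

#: acceptable G2/G1 position ratio for a well-behaved DNA histogram
G2_G1_RATIO_RANGE = (1.6, 2.4)

#: |ploidy - nearest integer| above which a call is reported "fractional"
#: (kept below 0.2 so a 2.8n genome-eroded tetraploid is not rounded to 3n)
FRACTIONAL_TOLERANCE = 0.15


class PeakDetectionError(ValueError):
    """Raised when a fluorescence distribution has no usable density peaks."""


@dataclass
class FluorescenceSample:
    """Per-cell green-fluorescence values for one line at one timepoint."""

    line_id: str
    cross_id: str
    timepoint: int  # generations
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values[np.isfinite(self.values)] < 0):
            raise ValueError("fluorescence values must be non-negative")

    @property
    def n_cells(self) -> int:
        return int(self.values.size)


@dataclass
class Calibration:
    """Fluorescence units per haploid genome equivalent.

    ``unit`` is the zero-intercept least-squares slope of control G1 peak
    position against known ploidy; ``control_peaks`` records the
    (known ploidy, observed G1 peak) pairs actually used.
    """

    unit: float
    control_peaks: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.unit > 0):
            raise ValueError("calibration unit must be positive")


@dataclass
class PloidyCall:
    line_id: str
    timepoint: int
    g1_peak: float
    g2_peak: float | None
    ploidy_continuous: float
    ploidy_class: int | str  # integer n, or "fractional"
    qc_flag: str  # "pass" | "warn"

    @property
    def class_value(self) -> float:
        """Numeric ploidy for ordering: the class when integral, else the
        continuous estimate."""
        if isinstance(self.ploidy_class, int):
            return float(self.ploidy_class)
        return self.ploidy_continuous


@dataclass
class WGDEvent:
    line_id: str
    cross_id: str
    first_tetraploid_timepoint: int
    reverted: bool
    extinct_before_end: bool


def density_peaks(
    values: Sequence[float],
    bandwidth: float | str = "auto",
    min_prominence: float = 0.05,
    grid_size: int = 1024,
) -> list[tuple[float, float]]:
    """Locate local maxima of a Gaussian KDE of the fluorescence values.

    Parameters
    ----------
    values
        Per-cell fluorescence; non-finite entries are dropped.
    bandwidth
        "auto" (Silverman's rule) or a KDE bandwidth factor passed to
        :class:`scipy.stats.gaussian_kde`.
    min_prominence
        Peaks with prominence below this fraction of the maximum density
        are discarded (rejects debris shoulders).

    Returns
    -------
    list of (position, density), sorted by density descending; the first
    two are the main peaks.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 100:
        raise PeakDetectionError(
            f"need at least 100 finite fluorescence values, got {v.size}"
        )
    if np.ptp(v) == 0.0:
        # degenerate distribution: a single spike
        return [(float(v[0]), float("inf"))]
    bw = "silverman" if bandwidth == "auto" else bandwidth
    kde = gaussian_kde(v, bw_method=bw)
    halfwidth = 3.0 * float(np.sqrt(kde.covariance[0, 0]))
    grid = np.linspace(v.min() - halfwidth, v.max() + halfwidth, grid_size)
    dens = kde(grid)
    idx, _ = find_peaks(dens, prominence=min_prominence * dens.max())
    if idx.size == 0:
        # monotone or single-boundary mode: fall back to the global maximum
        idx = np.array([int(np.argmax(dens))])
    peaks = [(float(grid[i]), float(dens[i])) for i in idx]
    peaks.sort(key=lambda p: -p[1])
    return peaks


def two_main_peaks(
    peaks: list[tuple[float, float]], sample_id: str = "?"
) -> tuple[float, float]:
    """Designate the two highest-density peaks; return (lower, higher) position."""
    if len(peaks) < 2:
        raise PeakDetectionError(
            f"sample {sample_id}: fewer than two density peaks detected; "
            "cannot designate G1/G2"
        )
    (p1, _), (p2, _) = peaks[0], peaks[1]
    return (p1, p2) if p1 <= p2 else (p2, p1)


def calibrate(
    control_samples: Iterable[tuple[FluorescenceSample, float]],
    bandwidth: float | str = "auto",
    min_prominence: float = 0.05,
) -> Calibration:
    """Fit fluorescence-per-haploid-genome from control strains of known ploidy.

    Controls whose own G2/G1 position ratio falls outside
    ``G2_G1_RATIO_RANGE`` are excluded (poorly stained or clumped samples).
    The unit is the least-squares slope through the origin,
    sum(p*g) / sum(p^2) over usable (ploidy p, G1 peak g) pairs.
    """
    usable: list[tuple[float, float]] = []
    lo, hi = G2_G1_RATIO_RANGE
    for sample, known_ploidy in control_samples:
        if not known_ploidy > 0:
            raise ValueError(f"control ploidy must be positive, got {known_ploidy}")
        peaks = density_peaks(sample.values, bandwidth, min_prominence)
        if len(peaks) < 2:
            continue
        g1, g2 = two_main_peaks(peaks, sample.line_id)
        if not (lo <= g2 / g1 <= hi):
            continue
        usable.append((float(known_ploidy), g1))
    if not usable:
        raise ValueError("no usable controls: all failed the G2/G1 ratio check")
    p = np.array([u[0] for u in usable])
    g = np.array([u[1] for u in usable])
    unit = float(np.sum(p * g) / np.sum(p * p))
    return Calibration(unit=unit, control_peaks=usable)


def call_ploidy(
    sample: FluorescenceSample,
    calibration: Calibration,
    bandwidth: float | str = "auto",
    min_prominence: float = 0.05,
    fractional_tolerance: float = FRACTIONAL_TOLERANCE,
) -> PloidyCall:
    """Call ploidy for one sample from its G1 peak position.

    G1 is the lower-position of the two main density peaks. If the G2/G1
    ratio check fails, or only one peak is detectable, ploidy is called
    from the single dominant peak and the call is flagged ``warn``.
    """
    peaks = density_peaks(sample.values, bandwidth, min_prominence)
    lo, hi = G2_G1_RATIO_RANGE
    qc = "pass"
    if len(peaks) >= 2:
        g1, g2 = two_main_peaks(peaks, sample.line_id)
        if not (lo <= g2 / g1 <= hi):
            g1, g2 = peaks[0][0], None
            qc = "warn"
    else:
        g1, g2 = peaks[0][0], None
        qc = "warn"
    ploidy = g1 / calibration.unit
    nearest = int(math.floor(ploidy + 0.5))
    if nearest >= 1 and abs(ploidy - nearest) <= fractional_tolerance:
        cls: int | str = nearest
    else:
        cls = "fractional"
    return PloidyCall(
        line_id=sample.line_id,
        timepoint=sample.timepoint,
        g1_peak=g1,
        g2_peak=g2,
        ploidy_continuous=float(ploidy),
        ploidy_class=cls,
        qc_flag=qc,
    )


def detect_wgd(
    trajectory: Sequence[PloidyCall],
    baseline_ploidy: int | None = None,
    cross_id: str = "",
    final_timepoint: int | None = None,
) -> WGDEvent | None:
    """Scan a time-ordered ploidy trajectory for a whole-genome duplication.

    The event is recorded at the first timepoint whose integer ploidy class
    is at least twice the baseline (the line's own initial class by
    default, so triploid-founded lines are handled transparently).
    A single doubled observation suffices; if any later call falls back
    below the doubled level the event is annotated ``reverted`` rather
    than erased.
    """
    if not trajectory:
        raise ValueError("empty ploidy trajectory")
    tps = [c.timepoint for c in trajectory]
    if any(b <= a for a, b in zip(tps, tps[1:])):
        raise ValueError("trajectory timepoints must be strictly increasing")
    if baseline_ploidy is None:
        first = trajectory[0]
        baseline_ploidy = (
            first.ploidy_class
            if isinstance(first.ploidy_class, int)
            else int(math.floor(first.ploidy_continuous + 0.5))
        )
    doubled = 2 * baseline_ploidy
    event_idx = None
    for i, call in enumerate(trajectory):
        if isinstance(call.ploidy_class, int) and call.ploidy_class >= doubled:
            event_idx = i
            break
    if event_idx is None:
        return None
    reverted = any(c.class_value < doubled for c in trajectory[event_idx + 1:])
    extinct = (
        final_timepoint is not None and trajectory[-1].timepoint < final_timepoint
    )
    return WGDEvent(
        line_id=trajectory[event_idx].line_id,
        cross_id=cross_id,
        first_tetraploid_timepoint=trajectory[event_idx].timepoint,
        reverted=reverted,
        extinct_before_end=extinct,
    )


def wgd_rate(
    trajectories: dict[str, Sequence[PloidyCall]],
    cross_id: str = "",
    baseline_ploidy: int | None = None,
    denominator: str = "founding",
    final_timepoint: int | None = None,
) -> tuple[float, pd.DataFrame, list[WGDEvent]]:
    """Per-cross WGD rate and cumulative tetraploid curve.

    Parameters
    ----------
    trajectories
        Mapping line_id -> time-ordered ploidy calls.
    denominator
        "founding": all lines present at the initial timepoint (extinct
        lines stay in the denominator); "surviving": only lines observed
        at ``final_timepoint``.

    Returns
    -------
    (rate, cumulative, events) where ``rate`` is the proportion of lines
    with a WGD event, ``cumulative`` is a DataFrame (timepoint,
    cumulative_count) over all observed timepoints, and ``events`` the
    per-line WGD records.
    """
    if not trajectories:
        raise ValueError("empty cross: no line trajectories")
    if denominator not in ("founding", "surviving"):
        raise ValueError(f"unknown denominator policy {denominator!r}")
    events = []
    for line_id, traj in trajectories.items():
        ev = detect_wgd(
            traj, baseline_ploidy, cross_id=cross_id, final_timepoint=final_timepoint
        )
        if ev is not None:
            events.append(ev)
    if denominator == "founding":
        n = len(trajectories)
    else:
        if final_timepoint is None:
            raise ValueError("surviving denominator requires final_timepoint")
        n = sum(
            1 for traj in trajectories.values() if traj[-1].timepoint >= final_timepoint
        )
    if n == 0:
        raise ValueError("denominator set is empty")
    all_tps = sorted({c.timepoint for traj in trajectories.values() for c in traj})
    event_tps = np.array(
        sorted(e.first_tetraploid_timepoint for e in events), dtype=float
    )
    cumulative = pd.DataFrame(
        {
            "timepoint": all_tps,
            "cumulative_count": [
                int(np.searchsorted(event_tps, t, side="right")) for t in all_tps
            ],
        }
    )
    return len(events) / n, cumulative, events


def read_fluorescence_csv(path) -> list[FluorescenceSample]:
    """Read samples from a long-format CSV with columns
    line_id, cross_id, generations, fluorescence."""
    df = pd.read_csv(path)
    required = {"line_id", "cross_id", "generations", "fluorescence"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"fluorescence CSV missing columns: {sorted(missing)}")
    samples = []
    for (line_id, cross_id, gen), grp in df.groupby(
        ["line_id", "cross_id", "generations"], sort=True
    ):
        samples.append(
            FluorescenceSample(
                line_id=str(line_id),
                cross_id=str(cross_id),
                timepoint=int(gen),
                values=grp["fluorescence"].to_numpy(dtype=float),
            )
        )
    return samples
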