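"""Seeded synthetic data with the structure the analysis modules assume.

Emulated measurements:

* flow-cytometry DNA-content histograms — a G1/G2 two-component mixture
  whose G1 mode sits at (ploidy x unit) arbitrary fluorescence units and
  G2 at twice that, with per-component coefficient of variation and a
  small uniform debris fraction;
* mutation-accumulation cohorts — 48-96 lines per cross evolved through
  35 single-colony passages (~22 generations each, ~770 total), with a
  per-passage whole-genome-duplication hazard, optional reversion and
  extinction hazards, planted aneuploidies and LOH tracts, plus a full
  ground-truth record for parameter-recovery tests;
* windowed read-depth tracks with overdispersed (gamma-distributed
  around copy-number-proportional means) window coverage;
* heterozygous-marker tracks with binomially sampled allele frequencies
  around the diploid/triploid baseline outside planted tracts and around
  the target allele frequency inside them;
* logistic OD600 growth curves on a 15-minute grid with additive
  measurement noise.

The noise models are stand-ins: the source data come with no stated
measurement-noise model, so distributional choices here (Gaussian
fluorescence components, gamma window depth, binomial allele counts,
Gaussian OD noise) are conventional defaults, not inferences.
All randomness flows from explicit seeds; the same seed gives
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .flowploidy import FluorescenceSample
from .loh import MarkerTrack

__all__ = [
    "SimulationConfig",
    "LineTruth",
    "CohortTruth",
    "simulate_fluorescence_sample",
    "simulate_cohort",
    "simulate_depth_track",
    "simulate_marker_track",
    "simulate_growth_curve",
    "make_genome",
]

#: fluorescence per haploid genome equivalent (arbitrary instrument scale)
FLUORESCENCE_UNIT = 100.0

_MAX_SEED = 2**31 - 1


@dataclass
class SimulationConfig:
    """Study-shaped defaults for a synthetic mutation-accumulation cohort.

    Hazards are per line per passage; ``aneuploidy_rate`` and
    ``loh_rate`` are expected planted events per line over the whole
    experiment. ``generations_per_passage`` = 22 makes 35 passages
    ~770 generations. ``coverage_dispersion`` d gives window-depth
    variance d x mean^2 (a gamma, negative-binomial-like overdispersion).
    """

    seed: int
    n_lines_per_cross: int = 96
    n_passages: int = 35
    generations_per_passage: float = 22.0
    wgd_hazard_per_passage: float = 0.002
    reversion_hazard: float = 0.005
    extinction_hazard: float = 0.0005
    aneuploidy_rate: float = 0.5
    loh_rate: float = 2.0
    loh_short_range: tuple[float, float] = (1e2, 1e3)
    loh_long_range: tuple[float, float] = (1e4, 1e5)
    loh_long_fraction: float = 0.3
    coverage_mean: float = 90.0
    coverage_dispersion: float = 0.02
    cv_fluorescence: float = 0.05
    g1_fraction: float = 0.6
    debris_fraction: float = 0.02
    marker_density: float = 2.0  # markers per kb
    n_chromosomes: int = 16
    min_chrom_length: int = 230_000
    max_chrom_length: int = 1_531_000
    triploid_start_fraction: float = 0.0
    n_cells: int = 5000
    unit: float = FLUORESCENCE_UNIT
    observation_passages: tuple[int, ...] = (0, 4, 8, 12, 16, 20, 24, 28, 32, 35)

    def __post_init__(self) -> None:
        for name in (
            "wgd_hazard_per_passage",
            "reversion_hazard",
            "extinction_hazard",
            "triploid_start_fraction",
            "debris_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_passages < 1:
            raise ValueError("n_passages must be >= 1")
        if not self.coverage_mean > 0:
            raise ValueError("coverage_mean must be positive")
        if not 0 < self.g1_fraction < 1:
            raise ValueError("g1_fraction must be in (0, 1)")
        if self.n_lines_per_cross < 1:
            raise ValueError("n_lines_per_cross must be >= 1")
        if max(self.observation_passages) > self.n_passages:
            raise ValueError("observation passages exceed n_passages")


@dataclass
class LineTruth:
    """Ground truth for one simulated line."""

    line_id: str
    initial_ploidy: int
    wgd_passage: int | None
    reverted_passage: int | None
    extinct_passage: int | None
    ploidy_by_passage: tuple[int, ...]
    cn_ini: dict[str, int] = field(default_factory=dict)
    cn_end: dict[str, int] = field(default_factory=dict)
    loh_intervals: list[tuple[str, int, int, str]] = field(default_factory=list)


@dataclass
class CohortTruth:
    lines: list[LineTruth]
    chrom_lengths: dict[str, int]

    @property
    def n_wgd(self) -> int:
        return sum(1 for ln in self.lines if ln.wgd_passage is not None)

    def to_json_dict(self) -> dict:
        return {
            "chrom_lengths": self.chrom_lengths,
            "lines": [asdict(ln) for ln in self.lines],
        }


def simulate_fluorescence_sample(
    true_ploidy: float,
    n_cells: int,
    g1_fraction: float,
    cv: float,
    seed: int,
    unit: float = FLUORESCENCE_UNIT,
    debris_fraction: float = 0.02,
    line_id: str = "sim",
    cross_id: str = "sim",
    timepoint: int = 0,
) -> FluorescenceSample:
    """Per-cell fluorescence from a G1/G2 mixture at a given ploidy.

    G1 cells centre at ``true_ploidy x unit`` and G2 cells at twice
    that, each Gaussian with relative spread ``cv``; a ``debris_fraction``
    of events is uniform on (0, G1 mode), emulating sub-G1 debris.
    """
    if not true_ploidy > 0:
        raise ValueError(f"true_ploidy must be positive, got {true_ploidy}")
    if cv < 0:
        raise ValueError(f"cv must be non-negative, got {cv}")
    if n_cells < 100:
        raise ValueError(f"n_cells must be >= 100, got {n_cells}")
    if not 0 < g1_fraction < 1:
        raise ValueError(f"g1_fraction must be in (0, 1), got {g1_fraction}")
    rng = np.random.default_rng(seed)
    g1_mode = true_ploidy * unit
    probs = np.array(
        [
            (1 - debris_fraction) * g1_fraction,
            (1 - debris_fraction) * (1 - g1_fraction),
            debris_fraction,
        ]
    )
    n_g1, n_g2, n_debris = rng.multinomial(n_cells, probs)
    parts = [
        rng.normal(g1_mode, cv * g1_mode, size=n_g1),
        rng.normal(2 * g1_mode, cv * 2 * g1_mode, size=n_g2),
        rng.uniform(0.0, g1_mode, size=n_debris),
    ]
    values = np.concatenate(parts)
    rng.shuffle(values)
    np.maximum(values, 0.0, out=values)
    return FluorescenceSample(
        line_id=line_id, cross_id=cross_id, timepoint=timepoint, values=values
    )


def make_genome(config: SimulationConfig, rng: np.random.Generator) -> dict[str, int]:
    """Chromosome lengths, log-uniform between the configured bounds."""
    lengths = np.exp(
        rng.uniform(
            np.log(config.min_chrom_length),
            np.log(config.max_chrom_length),
            size=config.n_chromosomes,
        )
    ).astype(int)
    return {f"chr{i + 1:02d}": int(l) for i, l in enumerate(sorted(lengths))}


def _plant_loh(
    config: SimulationConfig,
    genome: dict[str, int],
    rng: np.random.Generator,
) -> list[tuple[str, int, int, str]]:
    chroms = list(genome)
    weights = np.array([genome[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    n_events = rng.poisson(config.loh_rate)
    intervals: list[tuple[str, int, int, str]] = []
    for _ in range(n_events):
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        length_range = (
            config.loh_long_range
            if rng.random() < config.loh_long_fraction
            else config.loh_short_range
        )
        size = int(np.exp(rng.uniform(*np.log(length_range))))
        size = min(size, genome[chrom] - 1)
        for _attempt in range(20):  # retry to keep intervals non-overlapping
            start = int(rng.integers(1, genome[chrom] - size))
            end = start + size
            if all(
                c != chrom or end < s or start > e
                for c, s, e, _p in intervals
            ):
                intervals.append(
                    (chrom, start, end, "a" if rng.random() < 0.5 else "b")
                )
                break
    return intervals


def simulate_cohort(
    config: SimulationConfig,
    include_fluorescence: bool = True,
) -> tuple[list[FluorescenceSample], CohortTruth]:
    """Evolve a synthetic MA cohort and record ground truth.

    Each line starts diploid (or triploid with probability
    ``triploid_start_fraction``, emulating crosses founded by
    spontaneously diploidized parents). Per passage, a surviving
    pre-WGD line doubles its genome with ``wgd_hazard_per_passage``;
    a doubled line reverts with ``reversion_hazard``; any line goes
    extinct with ``extinction_hazard`` and stops producing samples.
    Fluorescence samples are emitted at ``observation_passages``
    (timepoints labelled in generations).
    """
    rng = np.random.default_rng(config.seed)
    genome = make_genome(config, rng)
    chroms = list(genome)
    samples: list[FluorescenceSample] = []
    lines: list[LineTruth] = []
    for i in range(config.n_lines_per_cross):
        line_id = f"line_{i + 1:03d}"
        initial = 3 if rng.random() < config.triploid_start_fraction else 2
        ploidy = initial
        wgd_passage = reverted_passage = extinct_passage = None
        trajectory = [initial]
        for passage in range(1, config.n_passages + 1):
            if extinct_passage is None:
                if wgd_passage is None:
                    if rng.random() < config.wgd_hazard_per_passage:
                        wgd_passage = passage
                        ploidy = 2 * initial
                elif reverted_passage is None:
                    if rng.random() < config.reversion_hazard:
                        reverted_passage = passage
                        ploidy = initial
                if rng.random() < config.extinction_hazard:
                    extinct_passage = passage
            trajectory.append(ploidy)
        # planted genomic events at the sequenced timepoints
        baseline_end = trajectory[-1]
        cn_ini = {c: initial for c in chroms}
        cn_end = {c: baseline_end for c in chroms}
        for _ in range(rng.poisson(config.aneuploidy_rate)):
            chrom = chroms[int(rng.integers(len(chroms)))]
            step = 1 if rng.random() < 0.5 else -1
            cn_end[chrom] = max(0, cn_end[chrom] + step)
        truth = LineTruth(
            line_id=line_id,
            initial_ploidy=initial,
            wgd_passage=wgd_passage,
            reverted_passage=reverted_passage,
            extinct_passage=extinct_passage,
            ploidy_by_passage=tuple(trajectory),
            cn_ini=cn_ini,
            cn_end=cn_end,
            loh_intervals=_plant_loh(config, genome, rng),
        )
        lines.append(truth)
        if include_fluorescence:
            for passage in config.observation_passages:
                if extinct_passage is not None and passage >= extinct_passage:
                    continue
                samples.append(
                    simulate_fluorescence_sample(
                        true_ploidy=trajectory[passage],
                        n_cells=config.n_cells,
                        g1_fraction=config.g1_fraction,
                        cv=config.cv_fluorescence,
                        seed=int(rng.integers(_MAX_SEED)),
                        unit=config.unit,
                        debris_fraction=config.debris_fraction,
                        line_id=line_id,
                        cross_id="sim",
                        timepoint=int(round(passage * config.generations_per_passage)),
                    )
                )
    return samples, CohortTruth(lines=lines, chrom_lengths=genome)


def simulate_depth_track(
    copy_numbers: dict[str, int],
    chrom_lengths: dict[str, int],
    baseline_ploidy: int,
    coverage_mean: float,
    dispersion: float,
    seed: int,
    window: int = 10_000,
) -> pd.DataFrame:
    """Windowed depth with copy-number-proportional means.

    Each window's mean depth is gamma-distributed with mean
    ``coverage_mean x cn / baseline_ploidy`` and variance
    ``dispersion x mean^2`` (dispersion 0 gives exact means).
    Returns a binned track (chrom, start, end, mean_depth).
    """
    if baseline_ploidy < 1:
        raise ValueError("baseline_ploidy must be >= 1")
    if any(cn < 0 for cn in copy_numbers.values()):
        raise ValueError("copy numbers must be >= 0")
    rng = np.random.default_rng(seed)
    chunks = []
    for chrom, length in chrom_lengths.items():
        cn = copy_numbers[chrom]
        n_win = int(np.ceil(length / window))
        starts = np.arange(n_win, dtype=np.int64) * window
        ends = np.minimum(starts + window, length)
        mean = coverage_mean * cn / baseline_ploidy
        if dispersion > 0 and mean > 0:
            shape = 1.0 / dispersion
            depths = rng.gamma(shape, mean / shape, size=n_win)
        else:
            depths = np.full(n_win, mean)
        chunks.append(
            pd.DataFrame(
                {"chrom": chrom, "start": starts, "end": ends, "mean_depth": depths}
            )
        )
    return pd.concat(chunks, ignore_index=True)


def simulate_marker_track(
    chrom_length: int,
    marker_density: float,
    baseline_af: float,
    loh_intervals: Sequence[tuple[int, int, float]],
    depth_law: float | Callable[[np.random.Generator, int], np.ndarray],
    seed: int,
    chromosome: str = "chr01",
    ploidy_context: int = 2,
) -> tuple[MarkerTrack, list[tuple[int, int, float]]]:
    """Heterozygous-marker track with planted LOH tracts.

    Markers land at uniform random positions at ``marker_density`` per
    kb. Outside the planted intervals the parent-a read count is
    binomial around ``baseline_af``; inside interval (start, end,
    target_af) it is binomial around the target. ``depth_law`` is a
    constant Poisson mean, ``np.inf`` for exact (noise-free) allele
    frequencies, or a callable ``(rng, size) -> depths``.
    """
    if not 0 < baseline_af < 1:
        raise ValueError("baseline_af must be in (0, 1)")
    ivs = sorted(loh_intervals)
    for start, end, _t in ivs:
        if not (1 <= start <= end <= chrom_length):
            raise ValueError(f"interval ({start}, {end}) outside chromosome bounds")
    for (s1, e1, _), (s2, e2, _) in zip(ivs, ivs[1:]):
        if s2 <= e1:
            raise ValueError("planted LOH intervals must not overlap")
    rng = np.random.default_rng(seed)
    n_markers = rng.poisson(chrom_length * marker_density / 1000.0)
    pos = np.unique(rng.integers(1, chrom_length + 1, size=n_markers))
    p = np.full(pos.size, baseline_af)
    for start, end, target in ivs:
        p[(pos >= start) & (pos <= end)] = target
    exact = isinstance(depth_law, (int, float)) and np.isinf(depth_law)
    if exact:
        depth = np.full(pos.size, 10**9, dtype=np.int64)
        af = p.copy()
    else:
        if callable(depth_law):
            depth = np.asarray(depth_law(rng, pos.size), dtype=np.int64)
        else:
            depth = rng.poisson(float(depth_law), size=pos.size)
        depth = np.maximum(depth, 1)
        af = rng.binomial(depth, p) / depth
    track = MarkerTrack(
        chromosome=chromosome,
        markers=pd.DataFrame({"pos": pos, "af": af, "total_depth": depth}),
        baseline_af=float(af.mean()) if af.size else baseline_af,
        ploidy_context=ploidy_context,
    )
    return track, list(ivs)


def simulate_growth_curve(
    rate: float,
    od0: float = 0.05,
    carrying_capacity: float = 2.0,
    interval: float = 15.0,
    duration: float = 24.0,
    noise_sd: float = 0.002,
    seed: int = 0,
    strain_id: str = "sim",
    replicate_id: str = "r1",
):
    """Logistic OD600 trajectory on a fixed reading interval.

    ``rate`` is the exponential-phase specific growth rate (per hour),
    ``interval`` minutes between reads, ``duration`` hours total.
    ``carrying_capacity=np.inf`` gives a pure exponential. Additive
    Gaussian noise of ``noise_sd`` OD units emulates reader noise.

    The default od0/K = 0.025 leaves a genuine exponential phase several
    sliding windows long, so the planted rate is identifiable; with a
    larger starting fraction the logistic is already decelerating in the
    first window and any slope-based estimator reports the realized
    (lower) maximum slope rather than the planted rate.
    """
    from .growth import GrowthCurve

    if rate < 0:
        raise ValueError("rate must be >= 0")
    if not interval > 0:
        raise ValueError("interval must be positive")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration * 60.0 + 0.5 * interval, interval)
    t_hours = times / 60.0
    if np.isinf(carrying_capacity):
        od = od0 * np.exp(rate * t_hours)
    else:
        K = carrying_capacity
        growth = np.exp(rate * t_hours)
        od = K * od0 * growth / (K + od0 * (growth - 1.0))
    if noise_sd > 0:
        od = od + rng.normal(0.0, noise_sd, size=od.size)
    return GrowthCurve(
        strain_id=strain_id, replicate_id=replicate_id, times=times, od=od
    )
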