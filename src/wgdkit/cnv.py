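"""Chromosome copy number and aneuploidy from windowed read depth.

Per-base depth (samtools-depth style) is averaged over 10-kb tiling
windows, each window is divided by the genome-wide coverage, and the
median window ratio per chromosome, scaled by the baseline ploidy,
gives an integer chromosome copy number. Differences between the
end-of-experiment and post-mating timepoints yield per-line chromosome
gains and losses.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "bin_depth",
    "genome_wide_coverage",
    "normalize_windows",
    "chromosome_copy_number",
    "consensus_copy_number",
    "aneuploidy_delta",
    "gain_loss_spectrum",
    "read_depth_tsv",
    "read_binned_tsv",
]

WINDOW_SIZE = 10_000  # bp

# round(median_ratio * baseline) is withheld (qc="warn") when the
# fractional part lies in this band; the ratio is then ambiguous between
# two integer copy numbers (e.g. a mosaic or partial-chromosome event)
NO_CALL_BAND = (0.35, 0.65)


def bin_depth(
    per_base_depth: Iterable[tuple[str, int, float]] | pd.DataFrame,
    window: int = WINDOW_SIZE,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Average per-base depth into tiling windows.

    Parameters
    ----------
    per_base_depth
        Iterable of (chromosome, 1-based position, depth) or a DataFrame
        with columns chrom, pos, depth. Positions must be sorted within
        each chromosome.
    window
        Window size in bp; the final window may be shorter.
    chrom_lengths
        When given, positions absent from the input count as depth 0 and
        windows tile the full chromosome length. Otherwise each window's
        mean is taken over observed positions only and the output gains
        a ``partial`` flag column.

    Returns
    -------
    DataFrame with columns chrom, start (0-based), end (half-open),
    mean_depth [, partial].
    """
    if isinstance(per_base_depth, pd.DataFrame):
        df = per_base_depth[["chrom", "pos", "depth"]]
    else:
        df = pd.DataFrame(per_base_depth, columns=["chrom", "pos", "depth"])
    if df.empty and chrom_lengths is None:
        return pd.DataFrame(columns=["chrom", "start", "end", "mean_depth"])
    for chrom, grp in df.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"positions not sorted within chromosome {chrom}")

    out: list[pd.DataFrame] = []
    full = chrom_lengths is not None
    chroms = list(chrom_lengths) if full else list(dict.fromkeys(df["chrom"]))
    grouped = dict(tuple(df.groupby("chrom", sort=False)))
    for chrom in chroms:
        grp = grouped.get(chrom)
        if grp is None:
            pos = np.empty(0, dtype=np.int64)
            depth = np.empty(0, dtype=float)
        else:
            pos = grp["pos"].to_numpy(dtype=np.int64)
            depth = grp["depth"].to_numpy(dtype=float)
        if full:
            length = chrom_lengths[chrom]
        else:
            length = int(pos.max()) if pos.size else 0
        if length == 0:
            continue
        n_win = int(np.ceil(length / window))
        starts = np.arange(n_win, dtype=np.int64) * window
        ends = np.minimum(starts + window, length)
        widx = (pos - 1) // window  # 1-based -> window index
        sums = np.bincount(widx, weights=depth, minlength=n_win)[:n_win]
        counts = np.bincount(widx, minlength=n_win)[:n_win].astype(float)
        if full:
            denom = (ends - starts).astype(float)  # absent positions are depth 0
            mean = sums / denom
        else:
            with np.errstate(invalid="ignore"):
                mean = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
        chunk = pd.DataFrame(
            {"chrom": chrom, "start": starts, "end": ends, "mean_depth": mean}
        )
        if not full:
            chunk["partial"] = counts < (ends - starts)
        out.append(chunk)
    return pd.concat(out, ignore_index=True)


def genome_wide_coverage(track: pd.DataFrame) -> float:
    """Genome-wide coverage: the mean over all window mean depths."""
    if track.empty:
        raise ValueError("empty depth track")
    return float(track["mean_depth"].mean())


def normalize_windows(track: pd.DataFrame, coverage: float | None = None) -> pd.DataFrame:
    """Divide each window's mean depth by the genome-wide coverage."""
    if coverage is None:
        coverage = genome_wide_coverage(track)
    if not coverage > 0:
        raise ValueError("genome-wide coverage must be positive")
    out = track.copy()
    out["mean_depth"] = out["mean_depth"] / coverage
    return out


def chromosome_copy_number(
    ratio_track: pd.DataFrame,
    baseline_ploidy: int,
    sample_id: str = "",
    mask: pd.DataFrame | None = None,
    no_call_band: tuple[float, float] = NO_CALL_BAND,
) -> pd.DataFrame:
    """Integer copy number per chromosome from normalized window ratios.

    The median window ratio per chromosome times the baseline ploidy,
    rounded to the nearest integer, is the chromosome copy number.
    Windows overlapping ``mask`` intervals (BED-style columns chrom,
    start, end; e.g. the rDNA array on chromosome XII) are excluded from
    the median. Calls whose scaled median has a fractional part inside
    ``no_call_band`` are flagged ``warn``.

    Returns columns: sample_id, chrom, normalized_median, copy_number,
    baseline_ploidy, aneuploid, qc.
    """
    if baseline_ploidy < 1:
        raise ValueError("baseline_ploidy must be >= 1")
    track = ratio_track
    if mask is not None and not mask.empty:
        keep = np.ones(len(track), dtype=bool)
        for _, row in mask.iterrows():
            hit = (
                (track["chrom"] == row["chrom"])
                & (track["start"] < row["end"])
                & (track["end"] > row["start"])
            )
            keep &= ~hit.to_numpy()
        track = track[keep]
    rows = []
    for chrom, grp in track.groupby("chrom", sort=False):
        if len(grp) < 3:
            raise ValueError(
                f"chromosome {chrom}: need >= 3 windows for a copy-number call"
            )
        med = float(grp["mean_depth"].median())
        scaled = med * baseline_ploidy
        cn = int(np.floor(scaled + 0.5))
        frac = scaled - np.floor(scaled)
        qc = "warn" if no_call_band[0] <= frac <= no_call_band[1] else "pass"
        rows.append(
            {
                "sample_id": sample_id,
                "chrom": chrom,
                "normalized_median": med,
                "copy_number": cn,
                "baseline_ploidy": baseline_ploidy,
                "aneuploid": cn != baseline_ploidy,
                "qc": qc,
            }
        )
    return pd.DataFrame(rows)


def consensus_copy_number(
    window_cn_calls: Iterable[int], baseline_ploidy: int = 2
) -> int:
    """Modal copy number across per-window integer calls for one chromosome.

    Ties are broken toward the value closest to the baseline ploidy, then
    toward the smaller value.
    """
    calls = list(window_cn_calls)
    if not calls:
        raise ValueError("empty window call list")
    counts = Counter(calls)
    top = max(counts.values())
    candidates = [v for v, c in counts.items() if c == top]
    candidates.sort(key=lambda v: (abs(v - baseline_ploidy), v))
    return candidates[0]


def aneuploidy_delta(
    cn_ini: pd.DataFrame, cn_end: pd.DataFrame, line_id: str = ""
) -> tuple[pd.DataFrame, int]:
    """Chromosome gains/losses between two timepoints of one line.

    Both inputs are ``chromosome_copy_number`` tables for the same
    chromosome set. Returns (per-chromosome delta table, aneuploidy
    count), where the count is the number of chromosomes whose
    end-timepoint copy number deviates from the end-timepoint baseline
    ploidy (so a 4n line carrying a CN-3 chromosome counts one).
    """
    ini = cn_ini.set_index("chrom")
    end = cn_end.set_index("chrom")
    if set(ini.index) != set(end.index):
        raise ValueError("mismatched chromosome sets between timepoints")
    chroms = list(ini.index)
    delta = pd.DataFrame(
        {
            "line_id": line_id,
            "chrom": chroms,
            "cn_initial": ini.loc[chroms, "copy_number"].to_numpy(),
            "cn_end": end.loc[chroms, "copy_number"].to_numpy(),
        }
    )
    delta["delta"] = delta["cn_end"] - delta["cn_initial"]
    baseline_end = end["baseline_ploidy"].to_numpy()
    count = int(np.sum(end.loc[chroms, "copy_number"].to_numpy() != baseline_end))
    return delta, count


def gain_loss_spectrum(calls: pd.DataFrame, n_lines: int | None = None) -> pd.DataFrame:
    """Per-chromosome gain and loss frequencies over a set of lines.

    ``calls`` is a concatenation of ``aneuploidy_delta`` tables. When
    ``n_lines`` is omitted it is the number of distinct line_ids present.
    Returns columns chrom, n_gain, n_loss, gain_freq, loss_freq.
    """
    if calls.empty:
        raise ValueError("no aneuploidy calls supplied")
    if n_lines is None:
        n_lines = calls["line_id"].nunique()
    rows = []
    for chrom, grp in calls.groupby("chrom", sort=False):
        n_gain = int((grp["delta"] > 0).sum())
        n_loss = int((grp["delta"] < 0).sum())
        rows.append(
            {
                "chrom": chrom,
                "n_gain": n_gain,
                "n_loss": n_loss,
                "gain_freq": n_gain / n_lines,
                "loss_freq": n_loss / n_lines,
            }
        )
    return pd.DataFrame(rows)


def read_depth_tsv(path) -> pd.DataFrame:
    """Read a samtools-depth TSV (chrom, 1-based pos, depth), no header."""
    return pd.read_csv(
        path, sep="\t", names=["chrom", "pos", "depth"], comment="#"
    )


def read_binned_tsv(path) -> pd.DataFrame:
    """Read a pre-binned window TSV with header chrom, start, end, mean_depth."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "mean_depth"}
    if missing := required - set(df.columns):
        raise ValueError(f"binned depth TSV missing columns: {sorted(missing)}")
    return df
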