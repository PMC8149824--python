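"""Loss-of-heterozygosity detection from parental allele frequencies.

In a hybrid or intra-lineage cross, every site that is heterozygous
between the two parental genomes is a marker: the fraction of reads
carrying the parent-a allele should sit at the chromosome baseline
(1/2 in diploids, 1/3 or 2/3 in triploids with two copies of one
parental subgenome). Mitotic recombination converts tracts to
homozygosity; such tracts appear as runs of markers whose allele
frequency departs from the baseline. Segmentation follows three rules:

* a marker is a candidate when its allele frequency deviates from the
  chromosome average by more than ``deviation`` (default 0.15);
* a segment needs at least three successive candidate markers that share
  the same allele frequency within ``af_tolerance`` (default 0.1) of the
  run's running mean;
* consecutive member markers may be at most ``max_gap`` bp apart
  (300 bp for hybrid crosses, 1 kb for the low-heterozygosity
  intra-lineage crosses, where markers are sparse).

Segment size is the distance between the first and last member marker.
Segments touching the first or last retained marker of a chromosome are
"terminal" (consistent with break-induced replication reaching the
telomere), all others "interstitial" (gene-conversion-like).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MarkerTrack",
    "LOHSegment",
    "filter_snps",
    "assign_parent_alleles",
    "compute_af",
    "detect_loh",
    "loh_summary",
    "triploid_allele_loss",
    "read_freebayes_vcf",
    "segments_to_bed",
]

# Freebayes-dialect site filters for trustworthy biallelic SNPs:
# quality, per-strand support, read-placement balance, and matched
# mapping quality between alleles.
MIN_QUAL = 1.0
MIN_QUAL_PER_AO = 10.0
MQM_RATIO_RANGE = (0.9, 1.05)

MIN_MARKER_DEPTH = 20  # strictly-greater-than cutoff on total read depth

#: below this marker density (markers per bp) LOH calling is refused —
#: very low heterozygosity makes tract boundaries meaningless
MIN_MARKER_DENSITY = 1 / 10_000


@dataclass
class MarkerTrack:
    """Ordered parent-labelled heterozygous markers for one chromosome."""

    chromosome: str
    markers: pd.DataFrame  # columns: pos, af, total_depth (pos strictly increasing)
    baseline_af: float
    ploidy_context: int = 2

    def __post_init__(self) -> None:
        pos = self.markers["pos"].to_numpy()
        if pos.size and np.any(np.diff(pos) <= 0):
            raise ValueError("marker positions must be strictly increasing")

    @property
    def n_markers(self) -> int:
        return len(self.markers)


@dataclass
class LOHSegment:
    chromosome: str
    start: int  # position of first member SNP (1-based, inclusive)
    end: int  # position of last member SNP
    n_markers: int
    segment_af: float
    retained_parent: str  # "a" | "b"
    kind: str  # "interstitial" | "terminal"

    @property
    def size(self) -> int:
        return self.end - self.start


def filter_snps(
    records: pd.DataFrame, repeat_bed: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Select trustworthy biallelic SNPs from Freebayes-annotated records.

    ``records`` needs columns chrom, pos, ref, alt, qual, ao, saf, sar,
    rpr, rpl, mqm, mqmr. Rows failing any of: QUAL > 1, QUAL/AO > 10,
    SAF > 0, SAR > 0, RPR > 1, RPL > 1, 0.9 < MQM/MQMR < 1.05 are
    dropped, as are indels, multiallelic records, rows with missing
    annotations, and SNPs overlapping ``repeat_bed`` intervals (0-based
    half-open chrom/start/end).

    Returns (kept records, drop counts by reason).
    """
    df = records.copy()
    dropped: dict[str, int] = {}

    def drop(mask: pd.Series, reason: str) -> None:
        n = int(mask.sum())
        if n:
            dropped[reason] = dropped.get(reason, 0) + n
        nonlocal df
        df = df[~mask]

    numeric = ["qual", "ao", "saf", "sar", "rpr", "rpl", "mqm", "mqmr"]
    missing_cols = [c for c in numeric + ["chrom", "pos", "ref", "alt"] if c not in df]
    if missing_cols:
        raise ValueError(f"records missing required columns: {missing_cols}")
    drop(df[numeric].isna().any(axis=1), "missing_fields")

    alt = df["alt"].astype(str)
    ref = df["ref"].astype(str)
    drop(alt.str.contains(","), "multiallelic")
    alt = df["alt"].astype(str)
    ref = df["ref"].astype(str)
    drop((ref.str.len() != 1) | (alt.str.len() != 1), "indel")

    drop(~(df["qual"] > MIN_QUAL), "qual")
    drop(~(df["qual"] / df["ao"] > MIN_QUAL_PER_AO), "qual_per_ao")
    drop(~(df["saf"] > 0), "saf")
    drop(~(df["sar"] > 0), "sar")
    drop(~(df["rpr"] > 1), "rpr")
    drop(~(df["rpl"] > 1), "rpl")
    ratio = df["mqm"] / df["mqmr"]
    lo, hi = MQM_RATIO_RANGE
    drop(~((ratio > lo) & (ratio < hi)), "mqm_ratio")

    if repeat_bed is not None and not repeat_bed.empty:
        in_repeat = pd.Series(False, index=df.index)
        for _, row in repeat_bed.iterrows():
            in_repeat |= (
                (df["chrom"] == row["chrom"])
                & (df["pos"] - 1 >= row["start"])
                & (df["pos"] - 1 < row["end"])
            )
        drop(in_repeat, "repeat")
    return df.reset_index(drop=True), dropped


def assign_parent_alleles(
    snps: pd.DataFrame, parents: pd.DataFrame
) -> pd.DataFrame:
    """Keep sites heterozygous between the parental genomes and label depths.

    ``parents`` has columns chrom, pos, parent_a_allele, parent_b_allele.
    A SNP is kept when its {ref, alt} equals the (distinct) parental
    allele pair; ``depth_a`` is then the read depth of the parent-a
    allele (``ro`` if parent a carries the reference allele, else ``ao``).
    """
    par = parents[parents["parent_a_allele"] != parents["parent_b_allele"]]
    merged = snps.merge(par, on=["chrom", "pos"], how="inner")
    match = (
        (merged["ref"] == merged["parent_a_allele"])
        & (merged["alt"] == merged["parent_b_allele"])
    ) | (
        (merged["ref"] == merged["parent_b_allele"])
        & (merged["alt"] == merged["parent_a_allele"])
    )
    merged = merged[match].copy()
    a_is_ref = merged["ref"] == merged["parent_a_allele"]
    merged["depth_a"] = np.where(a_is_ref, merged["ro"], merged["ao"])
    merged["depth_b"] = np.where(a_is_ref, merged["ao"], merged["ro"])
    merged["total_depth"] = merged["depth_a"] + merged["depth_b"]
    return merged


def compute_af(
    markers: pd.DataFrame,
    min_depth: int = MIN_MARKER_DEPTH,
    ploidy_context: int = 2,
) -> list[MarkerTrack]:
    """Per-marker parent-a allele frequency and per-chromosome baseline.

    ``markers`` needs chrom, pos, depth_a, total_depth. Markers with
    total depth not strictly greater than ``min_depth`` are removed.
    The baseline is the arithmetic mean allele frequency over all
    retained markers of the chromosome.
    """
    kept = markers[markers["total_depth"] > min_depth].copy()
    if kept.empty:
        warnings.warn("no markers pass the depth filter; empty track set")
        return []
    kept["af"] = kept["depth_a"] / kept["total_depth"]
    tracks = []
    for chrom, grp in kept.groupby("chrom", sort=False):
        grp = grp.sort_values("pos")
        tracks.append(
            MarkerTrack(
                chromosome=str(chrom),
                markers=grp[["pos", "af", "total_depth"]].reset_index(drop=True),
                baseline_af=float(grp["af"].mean()),
                ploidy_context=ploidy_context,
            )
        )
    return tracks


def detect_loh(
    track: MarkerTrack,
    deviation: float = 0.15,
    af_tolerance: float = 0.1,
    max_gap: int = 300,
    min_markers: int = 3,
    min_marker_density: float | None = None,
) -> list[LOHSegment]:
    """Segment LOH tracts from a marker track (rules in module docstring).

    Candidate markers (|af - baseline| > deviation) are scanned in
    order. A run breaks at any intervening non-candidate marker, at an
    inter-marker gap above ``max_gap``, or when a marker's allele
    frequency leaves ±``af_tolerance`` of the running mean of the
    current run. Runs of at least ``min_markers`` become segments.
    """
    if min_marker_density is not None and track.n_markers > 0:
        pos = track.markers["pos"]
        span = int(pos.iloc[-1] - pos.iloc[0]) or 1
        if track.n_markers / span < min_marker_density:
            raise ValueError(
                f"chromosome {track.chromosome}: marker density below "
                f"{min_marker_density:g}/bp; heterozygosity too low for "
                "reliable LOH calling"
            )
    pos = track.markers["pos"].to_numpy()
    af = track.markers["af"].to_numpy()
    n = pos.size
    if n == 0:
        return []
    candidate = np.abs(af - track.baseline_af) > deviation
    eps = 1e-12

    segments: list[LOHSegment] = []
    run: list[int] = []

    def flush() -> None:
        if len(run) >= min_markers:
            seg_af = float(np.mean(af[run]))
            kind = "terminal" if run[0] == 0 or run[-1] == n - 1 else "interstitial"
            segments.append(
                LOHSegment(
                    chromosome=track.chromosome,
                    start=int(pos[run[0]]),
                    end=int(pos[run[-1]]),
                    n_markers=len(run),
                    segment_af=seg_af,
                    retained_parent="a" if seg_af > track.baseline_af else "b",
                    kind=kind,
                )
            )
        run.clear()

    for i in range(n):
        if not candidate[i]:
            flush()
            continue
        if run:
            gap_ok = pos[i] - pos[run[-1]] <= max_gap
            mean_ok = abs(af[i] - float(np.mean(af[run]))) <= af_tolerance + eps
            if not (gap_ok and mean_ok):
                flush()
        run.append(i)
    flush()
    return segments


def loh_summary(
    segments_by_line: dict[str, Sequence[LOHSegment]],
    min_size_for_comparison: int = 1000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-line LOH counts and a flat segment table.

    Cross-to-cross comparisons should use only segments strictly larger
    than ``min_size_for_comparison`` (1 kb by default, so crosses whose
    sparse markers cannot resolve smaller tracts are comparable); these
    carry ``in_comparison=True`` in the segment table and feed the
    ``n_comparison`` per-line count. The full table retains everything.
    """
    seg_rows = []
    line_rows = []
    for line_id, segs in segments_by_line.items():
        n_comp = 0
        n_int = n_ter = 0
        for s in segs:
            in_comp = s.size > min_size_for_comparison
            n_comp += in_comp
            n_int += s.kind == "interstitial"
            n_ter += s.kind == "terminal"
            seg_rows.append(
                {
                    "line_id": line_id,
                    "chrom": s.chromosome,
                    "start": s.start,
                    "end": s.end,
                    "size": s.size,
                    "n_markers": s.n_markers,
                    "segment_af": s.segment_af,
                    "retained_parent": s.retained_parent,
                    "kind": s.kind,
                    "in_comparison": in_comp,
                }
            )
        line_rows.append(
            {
                "line_id": line_id,
                "n_segments": len(segs),
                "n_interstitial": n_int,
                "n_terminal": n_ter,
                "n_comparison": n_comp,
            }
        )
    per_line = pd.DataFrame(
        line_rows,
        columns=["line_id", "n_segments", "n_interstitial", "n_terminal", "n_comparison"],
    )
    segments = pd.DataFrame(
        seg_rows,
        columns=[
            "line_id", "chrom", "start", "end", "size", "n_markers",
            "segment_af", "retained_parent", "kind", "in_comparison",
        ],
    )
    return per_line, segments


TRIPLOID_BASELINES = (1 / 3, 2 / 3)


def triploid_allele_loss(
    track: MarkerTrack,
    deviation: float = 0.15,
    af_tolerance: float = 0.1,
    max_gap: int = 300,
    min_markers: int = 3,
) -> pd.DataFrame:
    """LOH segmentation in a triploid (2+1 parental copy) context.

    The chromosome baseline is snapped to the nearest triploid
    expectation (1/3 or 2/3 parent-a copies); a warning is issued when
    the observed baseline is far from both. Each segment is annotated
    with which parental allele class was lost and how many copies, from
    the copy-proportion change round(3 x (segment_af - baseline)).
    """
    if track.ploidy_context != 3:
        raise ValueError("triploid_allele_loss requires ploidy_context == 3")
    expected = min(TRIPLOID_BASELINES, key=lambda b: abs(b - track.baseline_af))
    if abs(track.baseline_af - expected) > 0.08:
        warnings.warn(
            f"chromosome {track.chromosome}: baseline AF {track.baseline_af:.3f} "
            "inconsistent with a triploid 1/3 or 2/3 expectation"
        )
    snapped = MarkerTrack(
        chromosome=track.chromosome,
        markers=track.markers,
        baseline_af=expected,
        ploidy_context=3,
    )
    segs = detect_loh(snapped, deviation, af_tolerance, max_gap, min_markers)
    rows = []
    for s in segs:
        delta_a = int(round(3 * (s.segment_af - expected)))
        lost_parent = "a" if delta_a < 0 else "b"
        rows.append(
            {
                "chrom": s.chromosome,
                "start": s.start,
                "end": s.end,
                "size": s.size,
                "n_markers": s.n_markers,
                "segment_af": s.segment_af,
                "kind": s.kind,
                "lost_parent": lost_parent,
                "copies_lost": abs(delta_a),
                "two_copy_parent": "a" if expected > 0.5 else "b",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "size", "n_markers", "segment_af",
            "kind", "lost_parent", "copies_lost", "two_copy_parent",
        ],
    )


def read_freebayes_vcf(path) -> pd.DataFrame:
    """Read a Freebayes VCF into the flat record table ``filter_snps`` expects.

    Extracts QUAL plus the INFO fields AO, SAF, SAR, RPR, RPL, MQM, MQMR
    and RO (reference-allele depth). Multiallelic records keep their
    comma-joined ALT string and first-allele INFO values; ``filter_snps``
    drops them.
    """
    from cyvcf2 import VCF

    def first(val):
        if val is None:
            return np.nan
        if isinstance(val, (tuple, list, np.ndarray)):
            return float(val[0]) if len(val) else np.nan
        return float(val)

    rows = []
    for rec in VCF(str(path)):
        info = rec.INFO
        rows.append(
            {
                "chrom": rec.CHROM,
                "pos": rec.POS,
                "ref": rec.REF,
                "alt": ",".join(rec.ALT),
                "qual": rec.QUAL if rec.QUAL is not None else np.nan,
                "ao": first(info.get("AO")),
                "ro": first(info.get("RO")),
                "saf": first(info.get("SAF")),
                "sar": first(info.get("SAR")),
                "rpr": first(info.get("RPR")),
                "rpl": first(info.get("RPL")),
                "mqm": first(info.get("MQM")),
                "mqmr": first(info.get("MQMR")),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "ref", "alt", "qual",
            "ao", "ro", "saf", "sar", "rpr", "rpl", "mqm", "mqmr",
        ],
    )


def segments_to_bed(segments: Iterable[LOHSegment]) -> pd.DataFrame:
    """Segments as BED-style rows (0-based half-open; name=kind, score=n_markers)."""
    return pd.DataFrame(
        [
            {
                "chrom": s.chromosome,
                "start": s.start - 1,
                "end": s.end,
                "name": s.kind,
                "score": s.n_markers,
            }
            for s in segments
        ],
        columns=["chrom", "start", "end", "name", "score"],
    )
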