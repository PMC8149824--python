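"""Detect loss-of-heterozygosity tracts from parental allele frequencies.

Simulates a hybrid chromosome with two planted LOH tracts — a short
interstitial (gene-conversion-like) one and a long tract reaching the
chromosome end (break-induced-replication-like) — then segments the
marker track and summarizes sizes by kind.
"""

from wgdkit.loh import detect_loh, loh_summary
from wgdkit.simulate import simulate_marker_track

chrom_len = 400_000
tracts = [
    (120_000, 122_000, 1.0),       # short tract, parent-a retained
    (360_000, 400_000, 0.0),       # long terminal tract, parent-b retained
]
track, truth = simulate_marker_track(
    chrom_len, marker_density=5.0, baseline_af=0.5,
    loh_intervals=tracts, depth_law=60.0, seed=7,
)
print(f"{track.n_markers} heterozygous markers, baseline AF {track.baseline_af:.3f}")

segments = detect_loh(track, deviation=0.15, af_tolerance=0.1, max_gap=1000)
for s in segments:
    print(
        f"  {s.kind:12s} {s.start:>7}-{s.end:<7} size {s.size:>6} bp  "
        f"{s.n_markers:>3} markers  AF {s.segment_af:.2f}  parent {s.retained_parent}"
    )

per_line, table = loh_summary({"H2_21": segments}, min_size_for_comparison=1000)
print(
    f"\nsegments: {per_line['n_segments'].iloc[0]} total, "
    f"{per_line['n_comparison'].iloc[0]} above the 1 kb cross-comparison cutoff"
)
# Segment AF near 1 means the parent-a allele was retained (parent b
# lost); the "terminal" tract touches the last marker of the chromosome.
# A long tract can be reported as several adjacent segments when a
# marker desert wider than max_gap interrupts it — the gap rule refuses
# to bridge stretches with no informative markers.
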