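"""Chromosome copy numbers and aneuploidy from windowed read depth.

Simulates 90x sequencing depth for a diploid line that gains one copy of
chromosome 3 during the experiment, then runs the window/normalize/median
pipeline at both sequenced timepoints and reports the gained chromosome.
"""

from wgdkit.cnv import (
    aneuploidy_delta,
    chromosome_copy_number,
    genome_wide_coverage,
    normalize_windows,
)
from wgdkit.simulate import simulate_depth_track

genome = {"chr01": 230_000, "chr02": 560_000, "chr03": 320_000, "chr04": 1_100_000}
cn_ini = {c: 2 for c in genome}
cn_end = dict(cn_ini, chr03=3)  # trisomy acquired during the experiment

calls = {}
for label, cns, seed in (("T_ini", cn_ini, 1), ("T_end", cn_end, 2)):
    track = simulate_depth_track(cns, genome, 2, coverage_mean=90.0,
                                 dispersion=0.02, seed=seed)
    ratios = normalize_windows(track, genome_wide_coverage(track))
    calls[label] = chromosome_copy_number(ratios, baseline_ploidy=2)
    print(f"{label}:")
    for _, row in calls[label].iterrows():
        print(
            f"  {row['chrom']}: median ratio {row['normalized_median']:.3f} "
            f"-> CN {row['copy_number']}"
        )

delta, n_aneu = aneuploidy_delta(calls["T_ini"], calls["T_end"], line_id="VLC1_12")
gained = delta[delta["delta"] != 0]
print(f"\naneuploidies at T_end: {n_aneu}")
print(gained.to_string(index=False))
# delta +1 on chr03 is the chromosome gain; a euploid line would show
# all-zero deltas and an aneuploidy count of 0.
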