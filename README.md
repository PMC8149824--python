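# wgdkit

Analysis toolkit for yeast mutation-accumulation (MA) experiments that
track spontaneous **whole-genome duplication (WGD)** and genomic
instability in crosses and hybrids evolved under relaxed selection.
It is written for experimental-evolution labs who have, per line and
timepoint: flow-cytometry DNA-content histograms, short-read depth
tables, Freebayes variant calls against two parental genomes,
plate-reader OD₆₀₀ growth curves, and tetrad dissection counts.

The toolkit answers, per line and per cross:

* **Ploidy & WGD** — the G1/G2 density peaks of each fluorescence
  histogram are found by kernel density estimation; the G1 position,
  calibrated against control strains (fluorescence unit
  u = Σpᵢgᵢ/Σpᵢ²), gives continuous ploidy n = g₁/u and an integer
  class; the first doubled timepoint of a trajectory dates the WGD,
  with reversions annotated; per-cross rates and cumulative
  tetraploid curves follow.
* **Aneuploidy** — per-base depth is averaged in 10-kb windows,
  normalized by genome-wide coverage, and each chromosome's copy
  number is round(median ratio × baseline ploidy); deltas between the
  post-mating and end-of-experiment timepoints count chromosome gains
  and losses.
* **LOH** — heterozygous parental markers (strict site filters on
  Freebayes annotations, depth > 20) yield allele-frequency tracks;
  runs of ≥ 3 successive markers deviating > 0.15 from the chromosome
  baseline, agreeing within ±0.1, with inter-marker gaps ≤ 300 bp
  (hybrids) or 1 kb (low-heterozygosity crosses), become interstitial
  or terminal loss-of-heterozygosity segments.
* **Fitness** — the maximum growth rate is the 98th percentile of OLS
  slopes in ten-timepoint sliding windows over log OD₆₀₀; fitness
  change is the rate difference across a WGD, optionally per evolved
  generation.
* **Fertility & statistics** — spore viability (colonies/spores) with
  paired t-tests before/after WGD; Kruskal-Wallis + pairwise
  Mann-Whitney-Wilcoxon comparisons across crosses and ploidy classes.

A seeded simulator (`wgdkit.simulate`) generates every input with
known ground truth — fluorescence mixtures, MA cohorts with planted
WGD/reversion/extinction events, overdispersed depth tracks, marker
tracks with planted LOH tracts, logistic growth curves — so the whole
pipeline is verifiable end to end without the deposited data.

## Worked example

```python
from wgdkit.flowploidy import calibrate, call_ploidy, detect_wgd
from wgdkit.simulate import simulate_fluorescence_sample

controls = [
    (simulate_fluorescence_sample(1.0, 5000, 0.6, 0.05, seed=1), 1.0),
    (simulate_fluorescence_sample(2.0, 5000, 0.6, 0.05, seed=2), 2.0),
]
cal = calibrate(controls)

trajectory = []
for gen, ploidy in [(0, 2.0), (90, 2.0), (385, 4.0), (770, 4.0)]:
    s = simulate_fluorescence_sample(ploidy, 5000, 0.6, 0.05,
                                     seed=100 + gen, timepoint=gen)
    trajectory.append(call_ploidy(s, cal))
event = detect_wgd(trajectory, baseline_ploidy=2)
```

Running `python examples/ploidy_from_flow.py` prints:

```
calibration: 99.8 fluorescence units per haploid genome
gen    0: G1 peak   200.0 -> 2.00n (class 2)
gen   90: G1 peak   200.5 -> 2.01n (class 2)
gen  385: G1 peak   400.4 -> 4.01n (class 4)
gen  770: G1 peak   399.9 -> 4.01n (class 4)
WGD first observed at generation 385; reverted=False
```

The calibration slope converts G1 peak position to genome copies; the
doubling of the G1 peak between generations 90 and 385 is the WGD, and
the event is dated to the first tetraploid observation. The other
scripts in `examples/` demonstrate copy-number calling, LOH
segmentation, growth rates, and the full cohort pipeline the same way.

File formats: flow samples from CSV (or any per-cell export),
samtools-depth TSV or pre-binned window TSV, Freebayes VCF via cyvcf2,
BED repeat/rDNA masks, long-format plate-reader CSV. See
`docs/methods.md` for the models, parameter defaults, and design
choices.

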