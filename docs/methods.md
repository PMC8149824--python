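# Methods

`wgdkit` analyses yeast mutation-accumulation (MA) experiments in which
hundreds of independent diploid (or triploid) lines are propagated
through repeated single-colony bottlenecks for ~35 passages
(~770 generations), so that genome dynamics — whole-genome duplication
(WGD), aneuploidy, loss of heterozygosity (LOH) — accumulate with
minimal interference from selection. This note documents each model,
its assumptions, the tunable parameters, and the design choices made
where several readings were defensible.

## Ploidy from flow cytometry

An asynchronous stained culture yields a DNA-content histogram with a
G1 mode proportional to genome copy number and a G2/M mode at twice
that position. The pipeline:

1. **Peak finding.** A Gaussian kernel density estimate of the per-cell
   fluorescence (Silverman bandwidth by default; overridable) is
   evaluated on a 1024-point grid, and local maxima with prominence
   ≥ 5% of the maximum density are kept. The two highest-density maxima
   are designated the main (G1, G2) peaks; the 5% prominence floor
   rejects debris shoulders. Samples with fewer than 100 finite events
   are refused.
2. **QC.** A well-behaved histogram has G2/G1 position ratio in
   [1.6, 2.4]. Outside that band (or with a single detectable peak) the
   call falls back to the dominant peak and is flagged `warn`.
3. **Calibration.** Control strains of known ploidy give the
   fluorescence unit per haploid genome as the zero-intercept
   least-squares slope Σpᵢgᵢ/Σpᵢ² of G1 position g against ploidy p.
   Controls failing their own G2/G1 check are excluded.
4. **Classification.** `ploidy_continuous = G1 / unit`. The call is the
   nearest integer when within 0.15n of it, else "fractional". The
   0.15n tolerance is deliberately below 0.2 so that a genome-eroded
   ~2.8n strain is reported fractional rather than rounded to 3n, while
   still absorbing peak-position noise at 5000 cells and CV ≤ 0.08
   (classification error well under 1% in the recovery tests).
5. **WGD events.** Scanning a line's time-ordered calls, an event is
   recorded at the first timepoint whose integer class reaches twice
   the line's baseline (its own initial class, so triploid-founded
   lines need 6n). One doubled observation suffices; later calls below
   the doubled level annotate the event `reverted` (fractional calls
   compare by their continuous value) instead of erasing it. Rates can
   be computed against founding lines (default; extinct lines stay in
   the denominator) or surviving lines — both policies are exposed
   because printed per-cross rates in this literature do not pin the
   denominator down.

## Chromosome copy number from read depth

Per-base depth is averaged over 10-kb tiling windows (short final
window allowed); each window is divided by the genome-wide coverage,
defined here as the mean over all window means; the median window ratio
per chromosome, multiplied by the baseline ploidy and rounded, is the
chromosome copy number. The median is robust to local coverage
artefacts; an optional BED mask (e.g. the rDNA array on chromosome XII,
one of the least stable regions of the genome) removes known-unstable
windows from the median. Calls whose scaled median has fractional part
in [0.35, 0.65] are flagged `warn` rather than forced to an integer —
the window/median rule gives no guidance for mosaics or partial
events, so an explicit no-call band is safer than silent rounding.
A separate consensus rule (modal per-window integer copy number, ties
broken toward the baseline then toward the smaller value) supports
pre-binned external window calls.

Aneuploidy per line is counted at the end-timepoint against the line's
end-timepoint ploidy class, so a tetraploid carrying one CN-3
chromosome counts one aneuploidy; gains and losses between the two
sequenced timepoints are per-chromosome copy-number deltas. All calls
are exactly invariant under rescaling of raw depth.

## LOH segmentation

Markers are sites heterozygous between the two parental genomes,
selected from Freebayes-annotated VCF records by QUAL > 1,
QUAL/AO > 10, SAF > 0, SAR > 0, RPR > 1, RPL > 1,
0.9 < MQM/MQMR < 1.05, excluding indels, multiallelic records and
repeat-overlapping sites. The parent-a allele frequency uses only
markers with total depth strictly greater than 20 reads; the
chromosome baseline is the arithmetic mean allele frequency over all
retained markers (computed before any candidate exclusion).

Segmentation applies three rules: candidates deviate from the baseline
by more than 0.15; a segment needs ≥ 3 successive candidate markers
agreeing within ±0.1; consecutive member markers may be at most
`max_gap` apart (300 bp for marker-dense hybrid crosses, 1 kb for
low-heterozygosity intra-lineage crosses). Choices where the rules
admit several readings, each exposed as a parameter:

* the gap window bounds the distance between *consecutive member
  markers*, not the total run span — segments much longer than the
  window must remain possible;
* the ±0.1 agreement is evaluated against the *running mean* of the
  current run, which tolerates per-marker binomial noise but stops a
  drifting run;
* an intervening non-candidate marker breaks a run;
* "terminal" means the segment contains the chromosome's first or last
  retained marker; everything else is interstitial.

Segment size is last-minus-first member position. Cross-to-cross
comparisons use only segments > 1 kb, since sparse-marker crosses
cannot resolve smaller tracts; chromosomes whose marker density falls
below 1/10 kb are refused outright rather than segmented unreliably.
Triploid (2+1 subgenome) chromosomes are segmented against a baseline
snapped to 1/3 or 2/3, and each segment is annotated with which
parental allele class was lost and how many copies, from
round(3·(segment AF − baseline)). In tetraploids the same diploid
baseline (1/2) applies, with the caveat that recombination between
identical homologues is invisible, so tetraploid LOH rates are
lower bounds.

The segmentation is verified against an exhaustive brute-force oracle
(independent enumeration of candidate runs plus independent
application of the three rules) on 1000+ random tracks.

## Maximum growth rate

Ordinary least-squares slopes are fitted in overlapping ten-timepoint
sliding windows along the OD₆₀₀ curve (15-min reads → 2.25-h windows),
and the 98th percentile of the slope set is the maximum growth rate.
The percentile uses linear interpolation between closest order
statistics. Regression is on natural-log OD by default — the slope is
then the specific growth rate (h⁻¹) and is invariant to the OD scale —
with a linear-OD mode for the literal raw-OD reading, since the
original convention is ambiguous. Windows containing non-positive OD
(possible after blank subtraction, which floors at 10⁻⁴ with a
warning) are skipped. Replicates (typically 4–5 per strain) are
summarized by mean and standard error.

The statistic has a known downward bias for saturating cultures: the
best window slope is ≈ r·(1 − OD/K) averaged over the window, so the
estimate approaches the planted exponential rate r only when the
culture starts well below capacity. The simulator's defaults
(od0 = 0.05, K = 2.0 OD, i.e. od0/K = 0.025) leave an exponential
phase several windows long precisely so recovery is meaningful;
with od0/K ≈ 0.05 the deficit already reaches ~7%. Reader noise
(default 0.002 OD additive Gaussian) contributes a much smaller upward
bias through the high percentile.

Fitness changes are growth-rate differences: after-minus-before WGD,
optionally divided by the number of generations evolved post-WGD.

## Statistics

Group comparisons are rank-based: Kruskal-Wallis omnibus plus pairwise
two-sided Mann-Whitney-Wilcoxon tests, reported for every pair
regardless of the omnibus outcome, exact enumeration up to n = 50 per
group and midranks with normal approximation above (exact with ties
falls back to the asymptotic form). Before/after designs (spore
viability, growth rate around WGD) use a two-sided paired t-test;
all-zero difference vectors are reported as an explicit "no-change"
note rather than a p-value. Spore viability is colonies per dissected
spore. No multiple-testing correction is applied; pairwise p-values
are raw, and any thresholding for display is left to the caller.

## The simulator

`wgdkit.simulate` generates every input the analysis consumes, plus
ground truth, so each stage is testable end to end without deposited
data. It emulates: G1/G2 fluorescence mixtures at ploidy-proportional
positions (unit fixed at 100 a.u. per haploid genome — flow units are
instrument-specific — G1 fraction 0.6, debris 2%); MA cohorts of
48–96 lines × 35 passages with per-passage WGD, reversion and
extinction hazards and planted aneuploidies/LOH tracts; 10-kb window
depth tracks with gamma (negative-binomial-like) overdispersion
(variance = dispersion·mean², default dispersion 0.02 ≈ 14% CV at
90×); marker tracks with binomial allele counts and planted tracts
drawn from a short (10²–10³ bp) / long (10⁴–10⁵ bp) mixture; and
logistic growth curves on a 15-min grid with additive reader noise.

What it does **not** emulate: GC and mappability bias in depth,
read-level errors, linked marker noise, S-phase cells between the
G1/G2 modes, cell clumping, plate effects or lag-phase variation in
growth curves, or selection during passaging. Passing recovery tests
therefore demonstrate correctness of the inference rules under the
stated noise models, not robustness to every artefact of real data.
All generators are deterministic given a seed; identical configurations
give byte-identical output.

## Problem sizes used in the test suite

The verification suite uses deliberately chosen scales: 1000 random
tracks (≤ 50 markers) for the segmentation oracle; 300 planted tracts
plus 200 null tracks at binomial depth 30 for LOH recovery and false
discovery; 200 replicate samples of 5000 cells per ploidy class (1n–4n)
plus a 40-line cohort for ploidy/WGD recovery; ~1000 simulated
chromosomes at 90× for copy-number recovery; 100 seeds per rate for
growth-rate recovery; 200 cohorts of 96 lines for agreement of the
simulated WGD fraction with its closed form 1−(1−h)³⁵. These sizes give
stable Monte-Carlo estimates of each error rate while keeping the whole
suite inside a few minutes on one core.

## Known limitations

* Peak calling assumes exactly two cell-cycle modes; heavily clumped or
  S-phase-rich samples degrade to the `warn` fallback rather than a
  cell-cycle model fit (Dean-Jett-Fox is out of scope).
* Copy-number calling is whole-chromosome only; segmental CNVs,
  breakpoints and GC correction are out of scope.
* LOH segmentation reports a long tract as several adjacent segments
  when a marker desert wider than `max_gap` interrupts it; mechanism
  (gene conversion vs break-induced replication) is inferred only
  through the size/kind readout.
* The growth estimator reports the realized maximum slope; for
  cultures inoculated near capacity this is systematically below the
  underlying exponential rate (see above).
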