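# Methods

## Scope and model

`coveval` evaluates whole-genome sequencing platforms on three linked
questions: how coverage depends on GC content, how evenly the genome is
covered, and how coverage limits SNV calling against an externally
genotyped truth set. Because the metrics are only meaningful when their
inputs have realistic structure, the package pairs every metric with a
generative model that plants that structure under seed control.

## The synthetic-data generator

**Genome.** Contigs are built from fixed-length composition blocks, each
with a target GC fraction; within a block every base is G/C with that
probability (split evenly between G and C). N runs are stamped at
configured coordinates and excluded from everything downstream. The default
calibration genome is 2 Mb (two 1 Mb contigs) of 1 kb blocks cycling GC
0.15 → 0.75 in steps of 0.025, which gives the GC-poor (≤ 25%) and GC-rich
(≥ 60%) comparison regimes solid window support — a real mammalian genome
concentrates its windows near 40% GC and supports the tails only sparsely,
so the synthetic regime tests are better powered than real ones at equal
size. Block coordinates are retained so annotation rules ("CpG islands are
the blocks with target GC ≥ 0.7") can address planted structure exactly.

**Reads.** A platform profile specifies a piecewise-linear non-negative
sampling weight w(g) over fragment GC, fragment length mean/sd, read
length, a duplicate rate, an overdispersion parameter, and a
repeat-mappability retention probability. Fragments are drawn with
probability proportional to w(fragment GC) times a per-1 kb-tile gamma
factor with shape 1/dispersion, making per-locus fragment counts
negative-binomial with variance μ(1 + dispersion·μ) and collapsing to
Poisson as dispersion → 0. The fragment GC used for weighting is computed
over the window of the profile's mean fragment length at the fragment
start; the realized length is then drawn normally and clamped so fragments
never overlap N runs or contig ends. Paired reads sit at the two fragment
ends. Fragments starting inside a low-mappability region lose unique-mapping
status with probability 1 − repeat_mappability; a duplicate_rate fraction
of extra fragments is emitted as flagged duplicates. Sampling continues
until unique, non-duplicate reads supply the target mean coverage times the
informative genome length, so the post-filter mean tracks the target to
within read granularity (< 0.1% at ≥ 1 Mb). Base-level errors, quality
strings, indels and structural variants are out of scope.

Three presets (`illumina_like`, `solid_like`, `cg_like`) encode the
qualitative platform archetypes that motivate the analyses: narrow
dispersion with mild GC bias; strong GC-rich dropout with short fragments;
nearly flat GC response with broad dispersion. They are YAML config files,
not code constants, so users can add profiles.

**Truth genotypes and calls.** Variants are planted on informative bases at
a configured density (default 5×10⁻⁴/bp, 60% het), with an equal density of
genotyped hom-ref sites emulating the reference-genotype positions an array
panel reports — these are the denominator of the false-positive rate. The
call simulator draws alt-supporting reads Binomial(d, 0.5) for het and
Binomial(d, 0.98) for hom-alt at a site of depth d and calls a variant iff
alt ≥ 2 and d ≥ 3, the minimum evidence for a het call (two non-reference
reads plus one reference). A configurable het allele fraction below 0.5
emulates tumor samples; it is off by default. Spurious het calls appear at
hom-ref sites with probability fp_rate (default 10⁻³).

What passing tests on this generator do **not** show: robustness to
alignment artifacts, base-quality structure, real repeat families, or
chromosome-scale heterogeneity — the simulator's dropout is exactly the
dropout the metrics model, no more.

## Metric definitions and numerical choices

**Filtering.** Duplicate and non-uniquely-mapping reads are removed before
any depth computation. Depth is pileup-style: each read interval
contributes one unit per base, so overlapping mates count twice at
overlapped bases (the behaviour of a naive pileup; mate-aware collapsing is
not attempted). Excluded contigs (the analogue of dropping a sex
chromosome) keep their tracks but are masked from every summary, so region
queries against them fail loudly instead of returning zeros.

**GC bias.** Windows are non-overlapping 1 kb tiles from each contig start;
trailing partial windows and windows containing any N are discarded. The
response variable is log2 of the window's summed per-base coverage;
zero-coverage windows are dropped from the fit rather than floored with a
pseudocount (a +1 pseudocount mode exists for datasets where dropouts are
the signal). The trend is statsmodels lowess (tricube, local linear),
span 0.3 by default, evaluated on a 0.005-GC grid restricted to the
observed support; no extrapolation.

**Regime comparison.** Two platforms are compared by two-sample KS tests on
curve samples taken every 0.5 GC-percentage points in the regimes g ≤ 0.25
and g ≥ 0.60, with asymptotic p-values and significance at p ≤ 0.05.
Deterministic grid samples of two independently fitted trends turn out to
be useless as KS inputs: the smoother's bandwidth exceeds the regime width,
each curve is nearly constant within a regime, and the KS statistic — being
scale-free — saturates at D ≈ 1 for any noise offset, rejecting replicate
simulations of the *same* platform 85–95% of the time. The comparison
therefore resamples each curve's own in-regime residuals onto the grid
(`sample_curve_noisy`), restoring the window-level noise scale. Measured on
2 Mb at 30x over 100 seed pairs, replicate flat platforms then reject in
≤ ~10% of pairs while a halved sampling weight above 60% GC is detected in
100%. `sample_curve` itself remains deterministic for users who want raw
trend values.

**Uncovered regions.** Maximal runs of informative bases with depth below
min_reads (default 3; 1 gives the strict zero-coverage variant). N runs
terminate regions — bridging a gap would report uncovered stretches longer
than any real sequence — and excluded contigs never contribute. Element
fractions are computed on merged footprints on both sides
(overlap(merge(U), merge(E)) / |merge(E)|), so duplicated annotation
entries cannot double-count.

**Annotation derivation.** Shores are the 2 kb flanks of CpG islands,
clipped to contig bounds, excluding the island itself; overlaps between
shores of different islands are kept verbatim because merging is an
explicit downstream operation. Promoters are 2 kb upstream / 500 bp
downstream of the TSS and are strand-aware — "upstream" is undefined
without a strand. Introns are the within-transcript complement of exons;
abutting exons produce no intron and overlapping exons are an error.

**ROC.** Thresholds enumerate the depths observed at called truth positions
plus zero. Sensitivity at t is the fraction of truth variant positions
carrying any non-reference call with depth ≥ t; genotype agreement is
deliberately not required here (it is reported separately in the
concordance table), since presence-detection is the quantity a depth
threshold actually controls. The FPR denominator is the truth hom-ref
positions, matching the array-anchored design; novel calls outside the
truth panel are ignored. AUC integrates by trapezoid with a (0, 0) anchor
and a horizontal extension to FPR = 1, the continuation of the curve once
every call is accepted. Between observed depths the sensitivity step
function holds the value of the next threshold up, which is the direct
evaluation of "fraction with depth ≥ t".

**Tests.** Element-fraction comparisons use equal-variance two-sample
t-tests and sensitivity comparisons paired t-tests, both two-sided;
degenerate inputs (zero variance) are flagged non-informative rather than
returning NaN. The no-call asymmetry uses an exact two-sided binomial test
at p = 0.5. Groups below two samples are refused.

**Downsampling** is independent Bernoulli thinning of read pairs and
singletons at ratio target/current, pair-atomic; an exact-count mode exists
for reproducibility studies. **Merging** is multiset union with platform
tags preserved and pair-ids re-keyed; merged depth is exactly the
elementwise sum of component depths.

## Pipeline and determinism

`run_pipeline` executes simulate → filter/depth → GC bias → uncovered
census → ROC/concordance, then downsampling and platform-combination
experiments, from one config dict. Every stage derives its seed from the
master seed by stable hashing of the stage name, so adding a stage never
perturbs earlier streams, and a rerun with the same config is bit-identical
(table checksums are recorded in the provenance block). The demo config is
two 1 Mb contigs, three presets at 30x with a 15x downsample and a
15x+15x combination; it runs in under a minute on one CPU. Calibration
experiments use the 2 Mb genome at 30x with 100 seed pairs; het-detection
recovery uses 12,000 planted hets per depth. These sizes were chosen so a
full validation pass stays in the minutes range while keeping Monte-Carlo
error well inside the asserted tolerances.

## Known limitations

- Fragment GC is evaluated at the mean fragment length, not the realized
  length; for the default sd/mean ratios the difference is far below the
  1 kb window resolution.
- The KS regime comparison's residual-noise sampling makes its p-values
  conditional on the fitted residual distribution; it is a calibration
  device, not an exact test.
- The caller model knows nothing about base quality, strand bias or
  mapping ambiguity at the call site; its sensitivities are upper bounds
  with respect to those effects.
- Genotype concordance imputes no-calls as hom-ref, which inflates
  "identical" counts at hom-ref truth sites exactly as an array-anchored
  comparison does.
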