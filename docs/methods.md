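# Methods note

## Genome model

The genome is a table of fixed-width bins (default 100 kb) over 24
chromosomes. Two scales exist: `"toy"` (hg19 chromosome lengths ÷ 10;
3113 bins at 100 kb) for tests and examples, and `"full"` (hg19
lengths, 50 kb default) for realistic runs. Each chromosome gets a
centromere at 40 % of its length, splitting bins into p/q arms. Per-bin
GC content is a smooth AR(1) series on the logistic scale squashed into
(0.2, 0.7), mean ≈ 0.41 — smooth along the genome, like real GC
tracks, but synthetic; the generating seed is part of the model
definition (seed 1 everywhere in this package). Pseudo-autosomal
regions at the X/Y tips (2.7 Mb and 0.35 Mb, scaled) are masked: reads
there are ambiguous between X and Y in real data, so the simulator
assigns them zero counts and the pipeline excludes them.

## Count model

A karyotype is an ordered list of `(region, copy_number)` events over a
diploid background (regions: chromosome, arm, or cytoband interval;
sex chromosomes start at the sex-appropriate baseline). Cytoband
intervals map to fixed fractions of the arm (e.g. q21–q24 covers
[0.10, 0.45] of the arm measured from the centromere); this is a
documented convention, not an hg19 cytoband claim.

Expected per-bin read fractions are proportional to the purity-mixed
copy number (`purity · cn + (1 − purity) · cn_normal`, with the
normal baseline diploid on autosomes and sex-appropriate on X/Y)
times the GC bias
`g(gc) = max(floor, 1 − amplitude/span² · (gc − peak)²)` (defaults:
peak 0.45, amplitude 0.30 at span 0.25, floor 0.05 — a unimodal
coverage bias of realistic size). Counts are negative binomial with
variance-inflation dispersion: `var = μ(1 + d)`, implemented as NB with
`size = μ/d`; `d = 0` is Poisson. Default `d = 0.05` and 2,000,000
reads per sample (~650 per toy bin) give per-bin log2-ratio noise of a
few hundredths — the regime in which a balanced profile has ≥ 99 % of
bins inside ±0.2, as shallow WGS at working depth does. The
alternative NB-α convention (`var = μ + dμ²`) at d = 0.05 would force
≥ 22 % CV per bin at any depth and was rejected for that reason.

Each sample draws from an independent `SeedSequence`-spawned stream,
so panels are reproducible and order-independent.

## Normalization

1. **Total-read normalization** divides counts by the unmasked total.
2. **GC correction** fits LOWESS (statsmodels, fraction 0.3, one
   robustifying iteration, delta = 0.001 × range) of rate vs GC and
   divides by the fit, rescaling to mean 1. Bins with non-positive
   fitted values are masked. A degenerate (constant) GC track warns
   and returns flat corrections.
3. **Reference**: the per-bin median of 30 GC-corrected controls.
   Bins are masked when the reference is 0, when more than 10 % of
   controls have zero counts there, or when any control masked them.
4. **Log2 ratios**: `log2((sample + ε)/(reference + ε))`, ε = 1e−9,
   then median re-centering (default on, config-exposed). Centering
   matters: total-read normalization divides by the genome-wide mean
   copy number, so in a heavily aberrant genome every amplitude is
   shifted; re-centering on the median anchors the modal (diploid)
   state at 0 and restores the canonical purity-1 amplitudes
   (single-copy gain ≈ 0.585, two-copy gain ≈ 1.0) that the calling
   thresholds assume.

## Segmentation

Circular binary segmentation: for each chromosome the candidate split
is the arc `(i, j]` maximizing the pooled-variance two-sample t²
between arc and complement. Only non-wrapped arcs are scanned —
by complement symmetry they cover every circular split. Arcs and the
edge pieces they induce must have ≥ `min_width` (3) bins. Ties break
to the lexicographically smallest `(i, j)`, and a winning arc touching
the right boundary is canonicalized to its complement touching the
left, so the tie-break cannot be flipped by last-bit float differences
between the two arithmetic paths.

Significance is a permutation test (default α = 0.01, 1000
permutations) on the max-t² statistic, computed in vectorized blocks
with early termination: once the exceedance count reaches α·nperm,
significance is impossible and the test stops — the accept/reject
decision is identical to running all permutations. Permutation streams
derive from `SeedSequence(seed, spawn_key=(chromosome, depth,
offset))`, so results do not depend on processing order. Recursion
proceeds on significant pieces until no split is significant.

**Pruning** (`sd_undo = 1.0`): adjacent same-chromosome segments whose
mean difference is ≤ `sd_undo × 1.4826 × MAD` of the bin-level
residuals merge greedily, smallest difference first, to a fixpoint;
`sd_undo = 0` is the identity, and exactly-equal means always merge.

**z-scores**: a segment's mean corrected rate is standardized against
the mean and sample standard deviation (n − 1) of the same statistic
across the controls; zero spread flags the z-score undefined.

## Calling

Segment status from mean log2: > 0.2 gain, < −0.2 loss, ≥ 0.75
high-level gain (between the purity-1 single-copy and two-copy
amplitudes), else balanced; both comparisons strict, so 0.20 itself is
balanced. A chromosome (or, failing that, an arm) is called a whole
gain/loss when ≥ 90 % of its unmasked bins sit in segments of that
status. Purity arithmetic: `expected_log2(cn, p) = log2((p·cn +
(1−p)·2)/2)`; cn = 0 at purity 1 returns −inf.

## Authentication

PowerPlex-16 profiles are marker → allele-set maps (allele labels are
exact strings, including micro-variants like 9.3 and X/Y for
amelogenin). Tanabe = 100·2·shared/(n_query + n_reference); Masters =
100·shared/n_reference; both exclude amelogenin, as is standard.
`allele_losses` includes amelogenin (a lost Y is meaningful) and
reports every reference allele absent from the query. Same-origin
verdict at Tanabe ≥ 80 %.

## Growth assays

`estimate_doubling_time` is ordinary least squares of log2(cell index)
on time (scipy `linregress`); doubling time = 1/slope. Non-positive
cell-index points are excluded and counted; a non-positive slope flags
the fit instead of reporting a negative doubling time. The automatic
window scans all sub-windows ≥ 24 h with cumulative sums (O(n²)) and
keeps the longest window maximizing R². Bead-assay background
subtraction clips negative net fluorescence to 0 and reports an
analyte non-informative when every point is at or below its detection
floor (defaults: FGF2 26 FI, PDGF 3.5 FI).

## What the generator does and does not emulate

Emulated: bin-level depth proportional to copy number, purity
dilution, smooth unimodal GC bias, overdispersed counting noise,
control-panel variability, PAR ambiguity, male/female sex chromosomes,
STR allele dropout (by editing tables), exponential growth with
multiplicative log-normal noise.

Not emulated: mappability and blacklist structure, replication-timing
waves, correlated (wavy) noise along the genome, subclonality,
allele-specific copy number, chromothripsis-scale rearrangement
geometry, STR stutter/peak heights, lag/plateau phases beyond what a
fitted window excludes. Bins are conditionally independent given their
expected rates.

## Numerical choices

All statistics in float64. Every stochastic component takes an
explicit seed; identical configs produce byte-identical pipeline
artifacts (checksummed in the run manifest). LOWESS is the only
numerical fit bought from a library (statsmodels); CBS, pruning,
z-scores, calling, authentication scores and the growth fits are
implemented here and tested against closed forms, brute-force oracles
(exhaustive arc scan, scipy `ttest_ind`), and simulation.

## Limitations

The toy genome's GC track and band conventions are synthetic, so
absolute coordinates do not correspond to real hg19 loci. Thresholds
(±0.2, 0.75, 90 %) are fixed conventions exposed in config, not fitted
quantities. The z-score assumes approximate normality of per-segment
control rates; with 30 controls its tails are t-like, slightly heavier
than Gaussian. The permutation test's early termination returns p = 1
whenever significance is impossible, so reported p-values above α are
not exact. Doubling-time estimates assume a single exponential phase
inside the fitted window.
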