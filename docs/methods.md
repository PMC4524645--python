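# Methods

`pmeth` implements a comparative analysis of placental (and placenta-like)
DNA methylomes from whole-genome bisulfite sequencing calls.  This note
documents the models and procedures, the parameters that matter, the
synthetic-data generator the test suite runs against, and the numerical
choices made where the design was genuinely open.

## Data model

A methylome is a table of per-CpG calls: chromosome, 0-based forward-strand
position of the CpG cytosine, methylated read count, total read count.
Methylation is symmetric across strands, so calls from the two strands of
one CpG (positions *p* and *p+1*) may be merged by summing counts.  Public
tracks often carry only a percentage; such fraction-only sites are treated
as weight-1 observations wherever sites are averaged.  All coordinates are
0-based half-open in every module; 1-based inputs are converted on read.

Two different averages are deliberately distinct:

* **global methylation** — read-weighted, `sum(meth_reads)/sum(total_reads)`
  over all sites.  This is the number quoted as "X% average methylation".
* **window / feature means** — unweighted means of per-site fractions.
  Window tracks, gene bodies and feature classes all use site averages, so
  a deeply covered site cannot dominate a window.

## Window tracks and density summaries

Chromosomes are tiled into non-overlapping, abutting windows (default
20 kb).  A window's mean is the unweighted mean fraction over the CpG
sites with methylation information inside it; windows with fewer than
`min_cpgs` (default 20) informative sites are *missing*, not zero.  The
final partial window of a chromosome is kept if it meets the filter.

Density summaries use a Gaussian KDE (Silverman bandwidth) of window
means on a 0–100% grid, renormalized to integrate to one on the grid.
Bimodality — the visual signature of a genome partitioned into partially
methylated domains (PMDs) and highly methylated domains (HMDs) — is
operationalized: the density is bimodal iff it has two local maxima
separated by a trough lower than `(1 - trough_depth)` times the lower
peak, with `trough_depth = 0.15`.  Peaks below 2% of the mode are ignored
as numerical ripple.  A visual call has no unique formalization; this
rule is a monotone surrogate that agrees with the obvious cases (two
well-separated Gaussians; a single Gaussian) and is configurable.

Smoothing for display/comparison is Nadaraya–Watson with a Gaussian
kernel over window centers (default bandwidth: three windows' worth of
bp).  Windows with no observed window within one bandwidth stay missing:
kernel smoothers otherwise interpolate across long coverage gaps and
produce spurious excursions, so the smoother never invents values there.

## PMD/HMD segmentation

A two-state Gaussian-emission hidden Markov model is fitted to the
non-missing window means by Baum–Welch (emissions pooled genome-wide) and
decoded per chromosome with Viterbi.  Missing-data gaps longer than
`gap_max` windows (default 5) restart the chain; shorter gaps are skipped
within one chain.

* Initialization: state means at the 25th/75th percentile of window means,
  both SDs at half the interquartile range, self-transition 0.99.  The
  heavy self-transition prior encodes the empirical persistence of domains
  over hundreds of kb.
* Labeling: the state with the lower fitted emission mean is PMD.  PMD is
  a model-relative label, not an absolute methylation cutoff.
* Post-processing: adjacent same-state windows merge into domains; domains
  shorter than `min_domain_bp` (default 100 kb, the characteristic domain
  scale) are absorbed into their longer neighbor.
* Degenerate outcome: if the two fitted means are closer than
  `min_separation = 0.10`, the track is declared to have **no PMD
  structure** and every chromosome becomes a single HMD.  This gives
  unimodal methylomes (mouse- or cow-placenta-like) a principled
  single-state answer instead of a noise-chasing split.  A zero-variance
  track short-circuits to the same outcome.

The full log-likelihood history is retained; the test suite asserts it is
non-decreasing across iterations, and decoding is deterministic given the
seed.

**Boundary proximity.**  Whether PMD/HMD boundaries sit closer to genomic
features (gene ends, CpG-island edges) than chance is tested with a
permutation null: each boundary is re-placed uniformly within its
chromosome's analyzable span (the union of called domains, so boundaries
are never placed into missing-data gaps), preserving per-chromosome
counts.  The statistic is the median distance to the nearest feature
point, and `p = (1 + #{null <= observed}) / (1 + n_perm)` for the
one-sided "closer than chance" alternative.  Chromosomes without features
contribute no distances.

## Cross-species comparison

CpG calls of one species are mapped onto a reference genome through UCSC
chain files.  The lift is purely positional — no sequence-conservation
requirement — because the downstream objects are multi-window averages,
not individual sites.  Each site maps through the highest-scoring chain
whose aligned blocks contain it; inter-block gaps leave sites unmapped.
Negative-strand chains reflect coordinates (`forward = qSize − 1 − pos`
for a single base).  When two source sites collide on one target
position, the higher chain score wins, then the lower source coordinate
(a deterministic tie-break).  Input/mapped/unmapped/removed counts always
reconcile exactly.

Sites falling in second-level synteny-net fills shorter than 1 Mb (small
translocations and duplications) are removed before comparison; level-1
fills and large level-2 fills are kept.  Syntenic *breaks* are the
boundaries between level-1 fills and between >1 Mb level-2 fills —
matching what survives the cleaning.

**Differential regions.**  Both 20-kb window tracks are affinely rescaled
to the reference's mean/SD, the per-window difference is taken, and the
difference is smoothed with a width-15 running median.  Regions are
maximal same-sign runs of windows whose smoothed difference exceeds 1.5
times the SD of the *unsmoothed* difference series.  Two choices deserve
explanation:

* *Smoothing the difference rather than each track.*  Median-filtering
  each species separately and then subtracting creates order-statistic
  artifacts at domain boundaries the species share: at a transition
  window the median equals an extreme order statistic of one side, whose
  sampling noise carries the full per-window SD rather than the
  sqrt(width)-suppressed SD, and a genuine step acquires a half-width
  halo.  Differencing first cancels all shared structure exactly, and the
  running median — an edge-preserving filter — keeps the extent of real
  differential segments intact.
* *Which SD the 1.5 multiplies.*  Thresholding any series at 1.5 times
  its own SD flags roughly 13% of windows whenever the series is
  noise-like, regardless of scale.  The threshold therefore uses the SD
  of the raw (unsmoothed) difference — the per-window noise scale —
  while the quantity thresholded is the smoothed difference, which
  suppresses noise by roughly sqrt(width).  Replicate-quality pairs then
  yield no regions, while a 0.25 offset over 400 kb exceeds the threshold
  many-fold.  A floor of 1e-9 on the threshold keeps numerically
  identical tracks from tripping on round-off.

Break enrichment in differential regions uses the same uniform
re-placement null as boundary proximity.  Because its statistic (the
fraction of breaks inside regions) is discrete, the two-sided empirical
p-value uses the mid-p convention (ties get half weight); the plain
counting rule is lumpily conservative under ties and would not be
uniform under its own null.

## Gene-body and feature methylation

Promoters are 1000 bp upstream to 100 bp downstream of the TSS,
strand-aware.  Gene-body methylation is the unweighted site mean over the
transcribed span (introns included; an exon-only mode exists) after
masking the gene's own promoter and all CpG islands; genes with fewer
than 20 informative CpGs remaining are dropped.  Feature summaries report
per-feature means (minimum 10 informative CpGs) and per-class pooled
site means, including a complement class for sites outside every feature.

The spinogram quantifies how predictive methylation is of genic location:
5-kb windows with at least 10 covered CpGs are binned by methylation
(5% bins) and each bin reports P(window is genic | bin) with an
informativeness score |P − 0.5|.  A window is genic iff its *midpoint*
falls in a gene body — an unambiguous single assignment for windows
straddling gene ends (an any-overlap rule would double-count).

Ortholog matrices join per-species gene-body tables through pairwise
ortholog maps onto a pivot species; duplicate orthologs keep the entry
with the most informative CpGs, and rows with fewer than two species are
dropped.  The exported matrix is raw (no per-species normalization);
scaling choices belong to the consumer.

## Methylation–expression coupling

Expression is transformed as `log10(FPKM + 0.01) + 1`.  The base-10 log
with a 0.01 pseudo-count keeps the conventional 0.56 high/low threshold
meaningful (≈0.36 FPKM) and handles zeros; both are configurable.

The co-independence test cuts both axes (gene-body methylation,
transformed expression) into 20 equally spaced bins over their observed
ranges (rank-based bins optional), forms the 20×20 contingency grid, and
compares observed counts to the product-of-marginals expectation.  The
chi-square statistic is computed after pooling cells with expected count
below 1 into contiguous neighbors along the expression axis (within each
methylation row; a trailing underfilled group folds left).  Significance
comes either from the asymptotic chi-square distribution or — the default,
since the grid has many sparse cells — from a permutation null that
shuffles expression labels across genes.  The pooling pattern depends
only on the marginals and is therefore held fixed across permutations.
`sector_deviation` sums observed-minus-expected over a grid sector; the
default sector (top third of methylation bins × middle third of
expression bins) captures the characteristic excess of intermediate
expression among highly methylated genes.

Quadrant classification labels each gene high/low in two tissues at
threshold 0.56 on the transformed scale; genes absent from either tissue
are excluded and counted.

## The synthetic-data generator

The generator produces, deterministically given a seed, everything the
pipeline consumes, with the statistical structure the analyses assume:

* **Genome bundle** — CpG positions from an inhomogeneous Poisson process
  (background 1 per 200 bp; 10× inside islands), 300 non-overlapping
  genes of 5–50 kb, 400 CpG islands (half anchored at TSSs), repeat
  intervals by class (LINE/SINE/LTR fractions 0.10/0.08/0.04), on 2
  chromosomes × 10 Mb (~120k CpGs).  This "demo genome" is sized so the
  full pipeline runs in well under two minutes.
* **Methylome** — alternating PMD/HMD blocks with truncated-exponential
  lengths (mean 250 kb, min 120 kb, max 800 kb; a terminal remainder
  shorter than the minimum is absorbed so every planted domain respects
  it), per-block baselines N(0.40, 0.03) and N(0.80, 0.03), optional
  single-state mode; +0.10 over the bodies of expressed genes; islands
  overridden to 0.10; truncated-Gaussian per-site noise (SD 0.03, clipped
  to [0, 1]); Poisson read depth (mean 5, the low-coverage regime of
  placental WGBS) with binomial sampling; zero-depth sites are uncovered.
  The domain length scale reproduces the qualitative window-length
  sensitivity of bimodality: 5–50 kb windows mostly sit inside single
  domains (bimodal densities), 200 kb windows usually mix states
  (unimodal).
* **Expression** — genes are expressed with probability
  `logistic(kappa × (gene-body methylation − mean))`, `kappa = 8`, then
  FPKM is log-normal (median ≈5 for expressed, ≈0.02 for silent).  One
  knob (kappa) controls the coupling; zero gives exact independence.
* **Species pair** — a second genome identical up to declared
  rearrangements (inversions → negative-strand chains; unmapped spans →
  chain gaps; level-2 segments → second-level synteny fills), an exactly
  corresponding chain file, and a second methylome that carries the first
  methylome's per-site true fractions through the map, applies declared
  differential-region offsets, re-noises and re-samples reads.  An
  offset-free pair is therefore a technical replicate.

What the generator does **not** emulate: nucleotide sequence (no
sequence-dependent artifacts, no bisulfite conversion failure), read-level
structure (no mapping bias, no PCR duplicates), correlated noise between
neighboring CpGs, CpG-density/methylation coupling inside PMDs,
non-stationary domain structure along chromosomes, and many-to-many
orthology.  Passing tests demonstrate the pipeline's correctness on data
satisfying its statistical assumptions, not robustness to alignment or
chemistry artifacts in real libraries.

## Problem sizes and runtime

The bundled checks run the demo genome (2 × 10 Mb, ~120k CpGs, 1000
20-kb windows), 1000 null datasets of 2000 genes at 200 permutations for
test calibration, and 200 replicates at 199 permutations for the
permutation-null self-calibrations.  The complete suite runs in about
half a minute on one CPU.

## Known limitations

* Beta emissions for the HMM are not implemented; Gaussian emissions with
  SD ≪ range are adequate at these window sizes but can misbehave for
  very small windows where means crowd 0 or 1.
* The chain reader supports the standard single-coverage chain layout;
  self-overlapping chains within one source region resolve by score, not
  by net hierarchy.
* The simplified synteny table (chrom, start, end, level) deliberately
  ignores the full net grammar; only fill level and span are used.
* Fraction-only tracks cannot contribute to read-weighted global
  methylation; the site-mean fallback is reported with a warning.
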