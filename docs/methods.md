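# Methods

## Coordinate model

All internal coordinates are 0-based half-open; 1-based dialects (GFF3,
per-cytosine methylation reports) are converted at the I/O boundary and
property-tested for round-trip identity. A genome layout records, per
chromosome: length, subgenome (A or C), one representative centromere
point, and a homoeolog-group id. The packaged default layout is synthetic:
19 chromosomes with loosely realistic rapeseed proportions (A chromosomes
22–45 Mbp, C chromosomes 41–65 Mbp, ~740 Mbp total; the C subgenome larger
than A), centromeres at varied arm fractions, and homoeolog groups pairing
A0k with C0k for k = 1..8 plus the A09/A10/C09 triple (A10 lacks a C
counterpart). Real centromere coordinates are inputs, never inferred.

The bin grid partitions every chromosome into non-overlapping 0.3-Mbp bins
(ceil(length/width) per chromosome); a truncated terminal bin keeps its true
length, and the rate formula divides by the actual bin length in Mbp.

**Telomere distance.** The relative arm position of a bin midpoint is
reported with 0 at the telomere and 1 at the centromere — the orientation
used on the feature axis of the landscape figures. The reflected ratio
(distance from the centromere to the midpoint over the centromere-to-telomere
distance, 0 at the centromere) is available as
`telomere_distance(..., orientation="centromere")` for parity checks; the
two conventions are mirror images and the package standardizes on the
telomere-origin one so that "small distance = near telomere" reads
naturally.

## Crossover filtering and rates

Filters run individuals-first: (1) every CO of an individual with more than
100 COs over all meioses is removed (strictly more than; exactly 100 is
retained), the threshold evaluated on raw per-individual totals; (2) CO
intervals strictly longer than 2 Mbp are discarded. Each removed individual
subtracts its two informative meioses from its population's denominator.
With the threshold evaluated on the raw set, the two filters commute; the
individuals-first order is the one logged.

A CO interval spanning several bins contributes overlap/length to each —
mass-conserving by construction (Σ fractional counts = retained CO count,
asserted to 1e-9). Rates are cM/Mbp:
rate_i = 100 · count_i / meioses / len_i(Mbp). Multi-population sets are
combined by summing per-bin counts and meiosis counts; per-population maps
can be built by subsetting the CO table.

SNP-normalized rate = rate / SNP count per bin; bins with zero markers are
flagged and excluded from percentile computation, hotspot labelling and all
modelling tables — an array cannot see COs where it has no markers, so the
zero is ascertainment, not biology.

**Hotspots.** Hotspot bins lie strictly above the genome-wide 95th
percentile (linear-interpolation empirical quantile) of the raw rate over
marker-covered bins; a bin equal to the threshold is not a hotspot. For each
chromosome, the same number of non-hotspot bins is drawn uniformly without
replacement from that chromosome's bins strictly below the 75th percentile;
if too few are eligible the sample truncates with a warning. Percentiles use
the raw rate; the regression target is the normalized rate.

## Features

- **Coverage fractions**: within-type intervals are unioned before coverage;
  optional cross-type trimming removes regions claimed by a higher-priority
  type (default priority gene > TE, configurable). Checked exactly against
  per-base boolean-mask oracles.
- **Methylation**: single-base rate per cytosine = methylated/total calls per
  replicate; cytosines absent from any replicate of a tissue are excluded
  for that tissue; rates average replicates-then-tissues, and the bin value
  is the unweighted mean over retained cytosines. The read-weighted variant
  pools counts (Σ methylated / Σ total) per bin; the two agree exactly under
  uniform coverage. TE-body CHH restricts the cascade to cytosines inside
  annotated TEs.
- **Sequence composition**: GC is the fraction of G/C bases
  (case-insensitive, ambiguity codes count as non-GC); dinucleotide coverage
  is the fraction of bin positions covered by at least one match
  (overlapping matches union-covered).
- **Accessibility**: per tissue, log10(accessible length + 1)/log10(bin
  length), capped at 1, then averaged over tissues — the log tames large
  tissue-specific peaks.
- **Expression**: per gene, TPM averaged over replicates within tissue,
  log10(mean + 0.1), averaged over tissues; genes attach to the bin holding
  their midpoint (a deterministic rule for boundary-spanning genes); binless
  values and geneless bins sit at the transform floor −1.
- **Imputation**: bins with no underlying observations (no cytosines in a
  context, etc.) are column-median imputed with a per-column count kept in
  the table's imputation log; median preserves rank structure and the counts
  make the imputation auditable.
- **Smoothing**: simple exponential smoothing s_t = αx_t + (1−α)s_{t−1},
  α = 0.1, initial level pinned at the first observation (reproducible,
  rather than optimizing the initial level), applied per chromosome to every
  smoothable feature and to the regression target after SNP-empty bins are
  dropped and after hotspot labelling, immediately before modelling.
  Positional/identity features (telomere distance, subgenome flag) and the
  binary classification target are never smoothed — genome binning cannot
  inject noise into them.

## Statistics

Hotspot-vs-non-hotspot contrasts use two-sample pooled-variance t-tests on
jointly z-scored values (z-scoring is affine, so t is unchanged; it is kept
for scale convention), a chi-square test on the 2×2 subgenome hotspot-count
table, and Benjamini–Hochberg step-up FDR adjustment with significance at
adjusted p < 0.1 (strict Bonferroni available as a sensitivity option). The
hotspot ~ SNP + C_subgenome logistic model is a binomial GLM fitted by IRLS
on all marker-covered bins (hotspot = top-5% membership) with raw SNP
counts by default and z-scored counts as an option; perfect separation is
detected and reported. The test-suite oracle for this fit is an independent
Newton/IRLS implementation.

## Modelling protocol

Folds are homoeolog groups (nine genome-wide); restricted to one subgenome,
each chromosome is its own fold (ten for A, nine for C). Rows are shuffled
within chromosomes; fold membership is deterministic. Per fold,
preprocessing is fitted on the training split only: dummy encoding (the
binary subgenome flag is its own dummy), removal of zero-variance
predictors, z-scoring by training mean/SD. SNP count is carried as metadata
and never enters the predictor set (rates are already SNP-normalized, and
marker density would otherwise confound the chromatin signal).

Learners are scikit-learn estimators: decision tree (cost-complexity,
depth, min leaf), elastic-net logistic/linear regression (penalty,
mixture), random forest (mtry fraction, trees, min leaf), gradient-boosted
trees (mtry, trees, learning rate, depth, loss reduction, min leaf).
Candidate 0 of every search is a fixed package default, so budget = 1
evaluates a deterministic baseline; further candidates come from seeded
random search or a Gaussian-process expected-improvement loop (5 random
warm-up draws, Matern-5/2 surrogate, EI maximized over 128 random
candidates). Selection maximizes mean fold AUROC (classification) or mean
fold R² (regression). Both the fold-mean and the pooled out-of-fold metric
are reported — they legitimately differ — plus per-chromosome Pearson
correlations for regression.

## Importance, robustness, interpretation

Importance: unnormalized total impurity reduction (Gini or RSS) for
tree/forest, gain-type importance for boosted trees, |standardized
coefficient| for the regularized linear models; average ranks for ties;
direction from coefficient signs (linear) or post hoc (tree models:
predicted-class feature means for classification, Spearman sign of feature
vs prediction for regression).

Feature clusters are connected components of the |Pearson r| > 0.8 graph
(transitive closure, size ≥ 2); representatives are user-fixable (CpG for
the chromatin cluster, AT for nucleotide composition) or default to the
member with highest mean within-cluster |r|. The robustness protocol refits
each learner on the reduced set (representatives plus unclustered
features), computes Spearman correlation between full- and reduced-set
ranks over the reduced set's features (a representatives-only variant
exists), and the mean within-cluster SD of full-set importances over the
overall SD. Model selection is lexicographic: Spearman, then CV metric,
then SD ratio, then name — fully deterministic. Rankings come from a single
full-data refit by default (a per-fold-averaged variant is a natural
extension; the full-data refit is cheaper and its ranking is what the
pipeline reports).

ALE curves use quantile interval edges (K = 20, duplicates merged); local
effects are mean prediction differences between upper- and lower-edge
substitution over each interval's observations, accumulated and centered by
the interval-midpoint rule; a binary feature uses the two-level categorical
variant centered by level counts. H-statistics follow Friedman's
definitions with all partial dependences estimated on a seeded subsample
(default 200–500 rows, O(n²) model calls, computed in single batched
predictions; single-feature profiles are cached across pairs). Two
documented guards apply to the *dominant-interaction summary* (not to the
reported values): the scan covers the model's leading predictors, because
the H ratio is numerically meaningless for near-inert features, and pairs
of mutually correlated features (|r| > 0.8) are flagged and skipped when
choosing the top pair, because both marginal partial dependences absorb
their shared signal and push H toward 1 regardless of any real interaction.
All pairwise values, including flagged ones, are written to the report.

## Synthetic-data generator

The generator is first-class, tested code; its defaults are the emulated
study conditions. Population design: two populations of 1,243 and 1,323
informative individuals, two meioses each, Poisson(1.2) COs per chromosome
per meiosis (no obligate CO or interference — the expectation is what the
analysis consumes). A latent heterochromatin field c ∈ [0,1] per bin is a
sigmoid of telomere distance (midpoint 0.80 in A arms, 0.45 in C — the C
subgenome's heterochromatin reaches much further out, which is what makes
the A/C feature distributions bimodal) plus moving-average-smoothed
Gaussian noise (window 5 bins) so that tracks are spatially autocorrelated
and exponential smoothing has something real to do. Methylation contexts
and TE coverages increase with c; gene coverage, expression and
accessibility decrease; GC tracks c weakly and AT mirrors GC tightly
(reproducing the two observed correlation clusters); TE-body CHH follows
gene coverage positively; SNP counts are Poisson with intensity increasing
in gene coverage (mean 4 markers per 0.3-Mbp bin, ~11k genome-wide,
matching a 15K-array scale), which yields marker-empty bins in gene-poor
regions.

CO intensity is λ ∝ exp(β·x̃ + s_sub(d)) with planted standardized
coefficients β = (CpG −1.5, TE −1.1, gene +1.3) and Gaussian positional
bumps s_A peaking at d = 0.25 (amplitude 2.0, width 0.25) and s_C at
d = 0.75 (amplitude 7.5, width 0.22); λ is clamped to zero within
a centromere window of ±4% of chromosome length. The C amplitude is large
by design: in the emulated biology the C subgenome's pericentromeric COs
occur *despite* anti-recombinatory chromatin, so the positional term must
beat the feature term there — this is exactly the subgenome × telomere-
distance interaction the interpretation stage is supposed to find. CO
points are sampled proportionally to λ, then reported as the interval
between the two flanking simulated markers (array-resolution censoring;
points outside the outermost markers are unobservable and dropped). A
configurable fraction of individuals (default 1%) draws COs at 6× the mean,
pushing them over the 100-CO filter threshold; their ids are the planted
artifact truth. The driver features carry less independent noise than the
remaining chromatin proxies so that the planted drivers are
correlated-but-identifiable, as in real panels where tightly coupled marks
still differ in measurement noise.

What the generator does **not** emulate: linkage disequilibrium and pedigree
structure, CO interference, sequence-level signal (motifs), read-level noise
in methylation/ATAC/RNA quantification, structural variation and
homoeologous exchange. Passing recovery tests therefore show that the
pipeline can find planted bin-level structure of realistic shape and
magnitude — not that it would survive artifacts the generator omits.

## Problem sizes and numerical choices

Tests and the acceptance script run the full genome at its default ~740-Mbp
scale (~2,470 bins, ~120k raw COs) for recovery checks, and scaled-down
layouts (5–50%) for unit tests; these sizes give stable statistics while
keeping the suite quick on a single CPU. Percentiles use linear
interpolation; hotspot threshold ties break strictly upward; SES initial
level is pinned; IRLS convergence and separation are surfaced, never
silent; AUROC counts ties as one half; all stochastic stages consume seeds
derived deterministically from one master seed via CRC-based expansion
(pure function of seed and stage name, below 2³¹).

## Known limitations

- The robustness Spearman is computed over the reduced feature set (or
  representatives only); with very few clusters it rests on few points and
  is flagged when fewer than three features remain.
- H-statistics inherit the extrapolation weaknesses of partial dependence
  under correlated features; the flags described above mark, but cannot
  repair, that bias.
- The GLM is fitted on all marker-covered bins; fitting on the balanced
  hotspot sample instead changes the intercept's meaning (an option covers
  both).
- The generator's latent single-field design means all chromatin features
  share one axis of variation; real epigenomes have more than one.
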