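# Methods

## The problem

A convolutional classifier trained on museum habitus images emits, for each
image, a softmax vector over species classes. Species-level accuracy is
limited: congeneric beetles are often near-indistinguishable in dorsal
view. The package implements the post-processing that makes such output
usable — aggregate confidence up the taxonomy, refuse to answer at a rank
where confidence is insufficient, and quantify the resulting trade-off
between taxonomic resolution and correctness — together with the models
that explain *which* images are answered correctly.

## Rank ladder and absent ranks

The ladder is fixed: species, subgenus, genus, tribe, subfamily, family
(coarsest). Genus and family are mandatory in a taxonomy table; subgenus,
tribe and subfamily may be absent per species. At an absent rank a species
inherits its class from the nearest finer present rank (a species with no
subgenus is its own subgenus class). This makes every species resolvable at
every rank, so roll-up conserves probability mass and every image can
traverse the full ladder; the alternative — skipping absent ranks — would
make per-rank specimen counts ambiguous. Taxon names are compared
case-sensitively after whitespace trimming, and the hierarchy must be a
strict tree (a genus in two tribes is a load-time error).

## Backoff semantics

At each rank the rolled-up maximum is compared with the threshold using
`>=`, so the procedure emits *at* the first rank that clears the bar and a
threshold of 1.0 still terminates (family mass is exactly 1). Rows must sum
to 1 within 1e-6 and are renormalized exactly before roll-up; argmax ties
break toward the lexically first taxon, making every prediction
deterministic. Correctness is evaluated only at the emitted rank. Note that
the coarse-rank argmax need not contain the species-level argmax — several
middling congeners can out-sum one confident outsider; this is a property
of sum-aggregation, not a defect, and is asserted by a constructed
counterexample in the test suite.

The minimum-top-1 exclusion filter (drop images whose best species value is
below a cutoff, e.g. 0.25) is implemented as an independent pre-filter so
it can be combined with either fixed species-level evaluation or backoff.

## Metrics

Per-class counts are one-vs-rest over the evaluated image set. Recall is
`tp/(tp+fn)`, identical to TPR; precision `tp/(tp+fp)`; balanced accuracy
`(TPR+TNR)/2`. (One published formula sheet prints recall as "tp/tp + tn)";
that conflicts with its own TPR definition and with recall's verbal
description, so it is treated as a typo for `tp/(tp+fn)`.) Zero
denominators yield explicit missing values — e.g. a rank holding a single
specimen has no negatives, so TNR and balanced accuracy are undefined while
precision and recall are 100%.

Per-rank summaries partition images by emitted rank; within a partition,
every taxon with at least one specimen (as truth or prediction) is scored
one-vs-rest against that partition only, and defined per-class values are
averaged unweighted. The bottom-row aggregate weights each rank's defined
column values by its specimen count, excluding undefined entries from that
column's weights — this reproduces the published table's weighted means
(75.8/70.6/55.4) from its rank rows exactly. Percentages are rounded
half-up to one decimal only in report output; internal values keep full
precision.

## Deterministic splitting

The subset is a pure per-image function: SHA-256 of the UTF-8 filename,
first 8 digest bytes as a big-endian unsigned integer, scaled by 100/2^64
to a percentage; bands [0,20) validation, [20,50) test, [50,100) training.
The source procedure named only "encrypting the filename" and left the band
edges open at 20 and 50; SHA-256 and half-open bands were fixed here for
reproducibility and to guarantee a partition. Curation order is: unlabeled
records out, quality-tag exclusions (ventral, missing part, larva,
unidentified) out, then the rare-species threshold (default 50 specimens)
applied to the *remaining* counts — rarity must be judged after quality
exclusions, or borderline species would be mis-kept.

## Synthetic generator

The generator stands in for the trained CNN. Defaults describe the study
system: 80 genera with zero-truncated geometric sizes of mean 291/80 ≈ 3.6
(so ~291 species), 66 images per species (the test set's per-species mean),
log-normal body sizes (`exp(N(−1.2, 0.7²))` megapixels, median ≈ 0.3 Mpx —
cropped museum beetles span roughly two orders of magnitude in area).

Per image, the correctness propensity is
`p = expit(β₀ + β_size·Mpx − β_genus·log g)` with defaults β₀ = 0.5,
β_size = 1.0, β_genus = 0.5 — positive body-size and negative genus-size
effects. With probability `p` the Dirichlet concentration `α_true` (default
3.0) is placed on the true species, otherwise on a uniformly drawn congener
(for a monotypic genus, a random other species); `α_genus` (2.0) is split
over the remaining genus members and `α_bg` (1.5) over all species outside
the genus, and the softmax row is one Dirichlet draw. The concentration
defaults put the mean top-1 value near 0.5, so a 0.5 threshold splits the
images roughly in half between species-rank and coarser-rank answers and
the backoff trade-off is exercised in the regime the real system operates
in, with strong within-genus leakage.

What the generator does *not* model: image content, preparation artifacts,
calibration error of real softmax outputs (wrong predictions here are as
confident as right ones, which real CNNs violate in a favourable
direction), shared visual difficulty between related genera, and
per-species idiosyncrasy beyond genus size and body size. Passing tests
therefore validate the post-processing machinery and the statistical
pipeline, not any claim about real-image accuracy.

Randomness is split into independent streams (taxonomy / specimens /
softmax) spawned from one seed, so the body-size draws cannot share
underlying bits with the correctness draws.

## Correctness GLMs

Model 1 regresses the per-image correctness flag on species identity
(treatment coding); model 2 on top-1 value, body size, congener count and
training-image count. Fits are maximum-likelihood binomial GLMs
(statsmodels IRLS) with Wald 95% intervals — adequate at the sample sizes
used and much cheaper than profile likelihood. Covariates are z-scored
internally; slopes are reported on both the standardized and raw scales
(the slope transform `β/σ` is exact; the raw-scale intercept is reported
without an interval, which would need the full covariance). Complete
separation — a species predicted perfectly — is flagged when a link-scale
magnitude exceeds 15 rather than silently reported. The sensitivity
profile holds all covariates at their mean (median for congener count,
whose distribution is long-tailed) and sweeps one over its observed range
through the inverse link.

Parameter recovery is validated against the generator's latent correctness
indicator — the Bernoulli(p) draw itself — for which the logistic law holds
exactly, so nominal 95% coverage is testable. Realized argmax correctness
adds Dirichlet noise whose size depends on genus structure; its coefficient
*signs* still match the generative signs and are checked on realized data,
but its true coefficients are not the generative ones, so coverage is not
asserted there.

## Problem sizes and numerical choices

The default test and acceptance runs use ~10,000–20,000 synthetic images
over ~291 species (full study scale; a complete run takes seconds), 1,000
random rows for mass-conservation checks (tolerance 1e-9), 10,000 filenames
for split uniformity (±2 percentage points around 20/30/50, KS test at
α = 0.01), and 100 replicates of 5,000 images for GLM recovery. Published
count ratios are recomputed from the printed counts; the real image
archive and trained network are not needed anywhere.

## Known limitations

* The published subset counts of the source workflow cannot be reproduced:
  they depend on the real filenames and an unnamed digest, and the printed
  counts are internally inconsistent (they do not sum to the dataset size).
  The split here reproduces the *procedure* and its band design, not those
  counts.
* Printed GLM coefficient values from the source are not comparable: their
  scale and parameterization are not recoverable, so only effect signs and
  interval behaviour are meaningful targets.
* Backoff assumes the taxonomy is correct and complete; a wrong lineage
  silently redirects roll-up mass.
* `weighted_mean_summary` trusts the caller's per-rank means; it does not
  recompute them from predictions.
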