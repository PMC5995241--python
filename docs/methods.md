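# Methods

This note documents the models, algorithms and numerical choices behind
`mibc-subtyper`, the assumptions they rest on, and what the synthetic-data
tests do and do not demonstrate about real data.

## nCounter normalization

Raw digital counts are normalized in four fixed steps, per sample:

1. **Positive-control scaling.** Each sample is scaled by
   `G* / G_s`, where `G_s` is the geometric mean of its positive-control
   spike-in probes and `G*` is the geometric mean of the `G_s` over the
   cohort.  This removes hybridization/lane efficiency differences.
2. **Background subtraction.** The negative-control summary (policy
   `mean`, `mean + 2·SD`, or `max`; default `mean`) is subtracted from
   every probe, flooring at zero.  The default mirrors common nSolver-style
   practice; the policy is a configuration switch because vendors and
   laboratories differ.
3. **Housekeeping scaling.** Samples are scaled so that the geometric mean
   of the 6 reference genes (CALM2, RPL37A, B2M, TUBB, GAPDH, G6PD),
   computed *after* steps 1–2, equals the cohort geometric mean.  After
   this step the reference geomean is equal across samples to a relative
   tolerance of 1e-9 (asserted in tests).
4. **log2(x + 1).** The unit pseudocount keeps zeros (which survive the
   background floor) finite.  Control and reference probes are removed
   from the output matrix.

The order positive → background → housekeeping is standard platform
practice; it is fixed, not configurable.  A sample whose reference geomean
is zero after background subtraction, or whose positive-control geomean is
zero, is a hard error naming the sample — these indicate failed assays, not
data to be patched.

A consequence worth knowing: per-sample global factors (e.g. doubling
every count of one sample) cancel exactly *within* that sample, but the
cohort-wide targets `G*` are geometric means over samples, so such a change
rescales all samples' linear outputs by one common factor.  Relative
structure — everything the downstream correlation-based clustering sees —
is unchanged.

## Quantile normalization (arrays)

Log2 intensities are mapped to the across-sample mean of order statistics.
Ties within a sample receive the mean of the quantile values their
positions span; this keeps the transform deterministic and rank-preserving
up to ties.  The textbook property "every sample's sorted vector is
identical afterwards" holds exactly for tie-free data; tie groups replace
their span of quantile values by the span's mean.  Missing values are a
hard error — imputation is out of scope.

## Gene clustering and the consensus panel

Subtyping genes are clustered by agglomerative hierarchical clustering on
the dissimilarity `d(g, h) = 1 − r(g, h)` (Pearson correlation across
samples) with Ward's criterion, and the tree is cut into exactly k = 3
clusters.  Two Ward dialects exist in the wild; both are supported:

- `ward_on="distance"` (default): the Lance–Williams Ward update applied
  to `d` as given — the classic `hclust(..., "ward.D")` usage on
  correlation distances.  Implemented by running Ward on `sqrt(d)` and
  squaring the merge heights, which is algebraically identical (the
  Euclidean-oriented implementation squares its input internally).
- `ward_on="squared"`: treats `d` as a Euclidean distance (ward.D2).

Merge heights and the k = 3 partition are verified against an independent
naive O(n³) Lance–Williams implementation in the test suite.  Correlation
is invariant to per-gene affine transforms, so no separate per-gene
standardization is needed before *gene* clustering.

Cluster → label assignment ("which cluster is basal?") maximizes the total
overlap with seed marker lists over all 3! label permutations.  Ties are a
hard error demanding more seed markers; the tool never guesses silently.
The seed lists default to the markers named above plus MDM4, CDK6 and
CDKN1A for the p53-like group.

The consensus panel keeps exactly the genes carrying the same label in
every cohort (Venn intersection); discordant genes are reported as
unstable with their per-cohort labels.  The consensus is order-invariant
in the cohort list and monotone: adding a cohort can only shrink it.

## Subtype calling and prediction

Samples are clustered on their per-gene z-scored consensus-panel profiles
(same `1 − r` / Ward machinery, k = 3).  Each cluster is named after the
subtype whose signature mean z-score is highest in it, again via the
exhaustive 3!-optimal assignment.  The p53-like signature label maps to
the subtype name **infiltrated** in all outputs, reflecting the
immune/stromal character of those tumors; the alias is retained in JSON.

Cross-cohort prediction is Pearson nearest-centroid: centroids are the
per-subtype means of z-scored consensus-gene expression in a reference
cohort; a new sample gets the subtype of the centroid it correlates with
best, with the margin to the runner-up reported.  Cohorts with fewer than
3 samples cannot be z-scored per gene and are correlated on raw profiles.
An exact correlation tie is a hard error naming the sample.  This is the
minimal defensible prediction rule and is isolated behind its own
function so alternatives can be added.

## Survival analysis

Kaplan–Meier estimation uses the product-limit estimator with the standard
convention that censorings at an event time remain in the at-risk set for
that time.  The log-rank test is the usual O−E chi-square with
df = groups − 1.  Both are backed by lifelines and cross-checked in tests
against closed forms and a hand-coded O−E tabulation.

Cox models maximize the Efron-ties partial likelihood (lifelines).  Only
Efron handling is offered: it is more accurate than Breslow under ties,
and maintaining a second fitter solely for an alternative tie rule was not
judged worth the extra code path.  Wald intervals are
`exp(coef ± 1.96·SE)`.  Monotone likelihood (complete separation) and
constant covariates are hard errors with actionable messages, never silent
divergence.

Forward selection starts from the empty model and repeatedly enters the
candidate with the smallest **likelihood-ratio** p-value while it is below
0.05, with no removal step.  The likelihood-ratio criterion is used in
place of the score test because the fitted log-likelihoods are directly
available; the two are asymptotically equivalent, and at the package's
cohort sizes the selected sets coincide in simulation.

Covariate encodings follow clinical convention: pT3–4 vs lower stage, N+
vs N0, M+ vs M0, chemotherapy yes/no, male vs female, age continuous, and
luminal (1) vs non-luminal (0) from the subtype call.  Survival times are
months; "8-year survival" is the step value at 96 months.  **No
multiple-testing adjustment is applied anywhere** — p < 0.05 is reported
as-is.  This mirrors the screening character of the analysis and is a
deliberate, documented choice; treat marginal p-values accordingly.

## Exact r×c association tests

The Freeman–Halton generalization of Fisher's exact test defines the
two-sided p as the total multivariate-hypergeometric probability of all
tables with the observed margins whose probability does not exceed the
observed table's.  Probabilities are computed in log space (gammaln), so
n ≈ 50-scale tables cannot overflow.  The probability comparison uses a
relative tolerance of 1e-7: ties in table probability are common on small
lattices and floating-point drift must not flip them.  Enumeration is
exact up to a configurable lattice cap (default 5×10⁶ tables); beyond it a
margin-preserving Monte Carlo estimate (label permutation) is used with a
reported replicate count and seed.  The 2×2 case reduces to the classic
two-sided hypergeometric test and is checked against scipy.

The Kruskal–Wallis test uses midranks and the tie correction (scipy); the
degenerate all-values-equal case returns H = 0, p = 1 by convention.  The
drug-target screen asserts that targets are disjoint from the subtyping
panel, so target attribution is independent of the clustering that defined
the groups.

## GSEA

Genes are ranked by signal-to-noise (default) or Welch t between two
phenotype classes; each class needs ≥ 3 samples.  The signal-to-noise
denominator floors each class SD at max(0.2·|mean|, 0.2), the convention
of the reference implementation, so flat genes cannot produce huge scores.
The enrichment score is the signed extremum of the weighted KS running sum
(hits weighted by |score|^p, p = 1, normalized to one; misses by
1/(N − Nh)).  Significance uses phenotype-label permutations — not
gene-set permutations — preserving gene–gene correlation.  The nominal p
is add-one smoothed ((1 + extreme)/(n_perm + 1)), so it is never zero and
has resolution 1/(n_perm + 1).  NES divides ES by the mean magnitude of
same-sign permuted scores; the single-set FDR q is the share of same-sign
permuted NES at least as extreme.  When the label space is smaller than
the requested permutation count, all distinct labelings are enumerated
exhaustively (with a warning).  If a gene set spans the entire ranked
list the miss penalty is undefined; the running sum then only rises and
ES = 1 — flagged here because such a call is almost certainly a mistake.

## The synthetic cohort generator

The generator's defaults define the study conditions the tests run under:

| parameter | default | meaning |
|---|---|---|
| subtype proportions | 9/47, 13/47, 25/47 | luminal / basal / infiltrated prevalence |
| `marker_effect` | 2.0 log2 | elevation of a subtype's own markers |
| `infiltration_effect` | 1.5 log2 | immune-gene elevation in infiltrated tumors |
| `dispersion` | 0.1 | negative-binomial overdispersion (Var = μ + 0.1 μ²) |
| `library_size_range` | 0.7–1.4 | per-sample depth factor |
| `baseline_hazard` | 0.0033 /month | infiltrated disease-specific hazard (8-year DSS ≈ 73%) |
| hazard ratios | luminal 5, basal 2 | disease-specific, vs infiltrated |
| `censoring_rate` | 0.004 /month | random loss to follow-up |
| `followup_cap` | 120 months | administrative censoring |

Counts are gamma-Poisson: digital counting data are overdispersed, and the
dispersion is configurable.  The positive-control ladder is a fixed
6-point 4-fold geometric series with Poisson noise and the sample's depth
factor, so positive-control scaling is exercised non-trivially; negatives
are low-mean Poisson, and a small ambient background is added to every
probe so background subtraction has something to remove.  Reference genes
are subtype-independent by construction.  Survival is exponential per
subtype — the simplest model in which the Cox hazard ratio has a known
truth — with independent other-cause mortality, exponential random
censoring, and the administrative cap.  Clinical covariates are sampled
independently of subtype: the reference cohort's clinical table shows no
significant subtype association, and the generator reproduces that regime.

The 64-gene panel contains 36 genes with a clean one-subtype block
pattern (16 basal, 8 luminal, 12 p53-like) and 28 genes planted as
**cross-cohort unstable**, among them the late-cell-cycle genes
(AURKA/AURKB/CCNB1/CCNA2/MAD2L1) that are elevated in both basal and
luminal tumors and therefore have no stable single-cluster home.  In
multicohort generation each unstable gene's signature label is rotated
deterministically by the cohort index, guaranteeing discordance across
≥ 3 cohorts; the Venn intersection then provably recovers exactly the 36
stable genes, which the acceptance tests verify end to end through the
real clustering/labeling code.

What the generator does **not** emulate: scanner-level microarray
artifacts, probe-sequence effects, batch structure, treatment-response
mechanisms, intra-tumor heterogeneity, or the correlated background of
real transcriptomes (non-marker genes are independent given subtype).
Passing recovery tests therefore demonstrates the *algorithms* behave as
specified under the planted model — not that real cohorts of this size
would yield equally clean panels.  True effect sizes in real cohorts are
unknown; the defaults were chosen once for realism and testability and are
not tuned per test.

## Problem sizes used by the test and acceptance runs

Subtype recovery uses n = 150 cohorts over 20 seeds (and 20 null cohorts
with `marker_effect = 0`); consensus recovery uses 4 cohorts of 47–61
samples over 20 seeds; Cox recovery uses n = 1000 with a homogeneous
non-luminal group (basal and infiltrated hazard ratios set to 1, so the
luminal-vs-rest hazard ratio has the exact truth 5); calibration uses 500
null replicates for the log-rank (n = 200) and Kruskal–Wallis (3×30)
tests; oracle equivalence uses 100 random instances each for Ward
clustering (5–10 genes) and the enrichment-score running sum (50-gene
lists), and 20 random tables for enumeration-vs-Monte-Carlo agreement at
10⁵ replicates.  The end-to-end pipeline demo (4 cohorts, full chain)
completes in a few seconds on one CPU.

## Known limitations

- The luminal-vs-non-luminal marginal hazard ratio under the *default*
  generator (basal HR 2) is not 5: the non-luminal group is a mixture.
  Parameter-recovery runs therefore use the homogeneous configuration.
- Forward selection inherits the usual instability of stepwise methods at
  small n; the selection trace is reported so users can see entry order
  and p-values rather than trusting the final set blindly.
- The Monte Carlo Fisher fallback estimates the p-value to ~3 decimal
  places at 10⁵ replicates; exact enumeration should be preferred whenever
  the lattice permits.
- Centroid prediction assumes the new cohort's consensus genes are
  measured on a roughly comparable scale after normalization; it is
  rank/correlation based, but severe platform effects are not corrected
  (no cross-platform batch adjustment, by design).
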