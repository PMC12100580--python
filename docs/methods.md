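# Methods

This note documents the statistical models behind each module, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical conventions that affect results.

## Behavioural statistics

The preference index of a valid replicate is the fraction of eggs on the
fresh + blood 37 °C substrate. Replicates with zero total eggs are "no
oviposition" events: they are counted and reported but never enter the
species mean, because a replicate without eggs carries no information
about substrate choice. The species-level summary uses the arithmetic mean
and the sample (n − 1) standard deviation of per-replicate PIs; a species
with a single valid replicate reports sd = 0.0 rather than NA, matching
the degenerate-case convention of the tabulated summaries.

The species mean enters downstream regressions through the modified logit

    logit(PI) = ln((1 + PI) / (2 − PI)),

chosen over the ordinary logit because species-level PIs sit exactly at 0
and 1 (obligate specialists oviposit on one substrate only) where
`ln(p/(1−p))` diverges. The transform is finite on the closed interval,
antisymmetric about 0.5 (`f(p) + f(1−p) = 0`) and strictly increasing; it
maps 0 → −ln 2 and 1 → ln 2. It is exposed as a named function so an
alternative transform can be swapped in.

Survival is `100 · emerged / eggs` per diet. Weight trajectories report
per-timepoint mean and sample sd, ordered by time.

## Differential-expression convergence

Given per-gene tables for the two congeneric comparisons (log₂ fold
change with positive = higher in the parasite, p, BH-adjusted p), genes
adjusted-significant in both are classified by sign agreement; genes
significant in exactly one are exclusive. A significant gene with log₂FC
exactly 0 raises an error instead of being silently binned: on continuous
data its probability is ~0, so it almost always indicates a malformed
input or a generator bug.

The independence expectation for a direction with margins n_A, n_B in a
universe of N genes is E = n_A·n_B/N — the hypergeometric mean of the
overlap of random subsets. The universe defaults to genes with a
non-missing adjusted p in *both* tables (the only set for which joint
significance is defined) and can be overridden. The test statistic is the
one-cell goodness of fit (O − E)²/E on 1 df, which reproduces the
published-scale values (97 vs 28 → χ² ≈ 170; 71 vs 24 → χ² ≈ 92) to
within 0.1%; a 2×2 contingency χ² is available behind the `form`
argument. Both antagonistic sign patterns are pooled into one test, and
no correction is applied across the three direction tests (they are
reported as raw p-values). Under hypergeometric sampling the one-cell
statistic is mildly conservative — its null variance is
E·(N−n_A)(N−n_B)/(N(N−1)) < E — so simulated type-I error sits slightly
below the nominal level (≈ 0.04 at the margins used in the tests).

`call_de_simple` exists so the synthetic pipeline is self-contained. It
is a deliberately minimal two-group caller: total-count library
normalisation, a pooled method-of-moments negative-binomial dispersion
(variance = μ + αμ²), and a delta-method Wald statistic on the
difference of log means referred to Student's t with n₁+n₂−2 df — the t
reference corrects the anticonservativeness of the plain normal at
typical 3 vs 3 designs. It makes no claim to the shrinkage or outlier
handling of production DE callers and is not a substitute for them on
real data.

## Phylogenetic regression

TPM10K = TPM · N_ref / 10⁴ rescales abundances by the species' reference
size (its orthogroup count), making values comparable across
species-specific references; the operation is linear in TPM. "Expressed
in all species" means TPM10K > 0 in at least one sample of every species
(threshold configurable); per-species medians of the surviving genes form
the regression response.

The Brownian-motion covariance of tips i, j is the depth of their most
recent common ancestor (shared root-to-tip path length). PGLS solves
β̂ = (XᵀC⁻¹X)⁻¹XᵀC⁻¹y via a Cholesky whitening, tests the slope with t on
n − 2 df, and computes R² in the whitened space about the GLS mean of y,
adjusted as 1 − (1−R²)(n−1)/(n−2). With C = I this reduces exactly to
OLS (verified to 1e-8 against an independent OLS implementation), and a
star tree with equal tip heights is equivalent to identity covariance by
GLS scale invariance. λ is fixed at 1 (pure Brownian motion); no branch
length transformation is estimated.

The unassayed obligate parasite (*Ch. bezziana*) has no preference
measurement; its logit PI is set equal to *Co. hominivorax*'s through an
explicit substitution rule supplied by the caller (CLI
`--substitute Ch_bezziana=Co_hominivorax`), never silently.

Genes with constant expression across species cannot be fit; they are
reported with NA statistics and excluded from the FDR family rather than
dropped silently.

## Selection-test summaries

The module consumes tabulated codon-model log-likelihoods; it performs no
likelihood optimisation. Each alternative/null pair differs by one free
parameter, so D = 2(ℓ_alt − ℓ_null) is referred to χ²₁; negative D
(optimiser noise upstream) is clamped to zero with a warning. The plain
χ²₁ reference is used for the branch-site comparison as well (no 0.5:0.5
boundary mixture). BH FDR is applied per model-comparison family across
genes. A gene is a selection-shift candidate when the alternative beats
*both* of its nulls at the FDR threshold (the conservative reading;
`null_rule` exposes `any` and `bneut-only`). Shift genes are classified
faster/slower by comparing foreground and background ω, with exact ties
reported as unclassified so that faster + slower + unclassified equals the
shift count.

ω outliers use the Tukey fence Q3 + 1.5·IQR with quartiles by linear
interpolation between order statistics (Q3 at rank position (n−1)·0.75);
the convention is fixed because outlier counts depend on it. The fence is
computed over the selection-shift genes — the set the rule targets — and
needs at least four of them.

## Alignment filtering

Stages: (1) trim terminal columns containing any gap, so every retained
terminal column is sampled in all taxa (the weaker all-gap reading is
available as `trim_mode="allgap"`); (2) keep clusters with aligned length
≥ 300 bp (inclusive); (3) delete all gaps per sequence and exclude
sequences whose ungapped length is < 300 bp, dropping clusters left with
fewer than two; (4) realign through a pluggable external command hook
(the package bundles no aligner; the default identity realigner pads
ragged ends and is intended for already-colinear synthetic fixtures);
(5) remove every column containing a gap, re-applying the ≥ 300 bp check
(disable with `recheck_length=False`). A realigner failure marks the
cluster failed and the batch continues. The pipeline is idempotent under
the identity realigner and never introduces characters.

## Enrichment overlap

Terms are flat gene sets; no ontology graph is consulted, so inputs
should carry ancestor propagation if it is wanted. The p-value is the
upper-tail hypergeometric probability of ≥ k annotated study genes
(matching exhaustive enumeration on all small universes), one-sided for
over-representation only, with BH FDR across terms and a minimum
universe term size of 2 (configurable) to exclude untestable rows.
Because small intersection gene sets are often too small to test, the
overlap strategy tests each comparison separately and intersects the
enriched term sets.

## Synthetic data

The generator produces every pipeline input plus truth tables sufficient
for confusion matrices at each downstream stage. All randomness flows
from `numpy.random.default_rng(seed)` (PCG64, integer state), so a fixed
seed reproduces outputs exactly across platforms.

Defaults encode the study conditions of the blowfly system:

* **Oviposition**: per-species fresh-choice probabilities at the
  tabulated PI values (1.0, 0.634, 0.424, 0.412, 0.059, 0.0),
  no-oviposition probabilities of 0.5–0.6 for the species observed to
  skip half or more of their replicates and 0.2 otherwise, 20 trials per
  species (8 for the species with only eight feasible trials), clutch
  sizes negative-binomial around 120 eggs.
* **DE counts**: 5000 genes, planted shared categories 97 concordant-up /
  71 concordant-down / 46 antagonistic plus 300/100 exclusives, log₂
  effect 3, NB dispersion 0.05, 3 replicates per condition.
* **Expression on the tree**: 5000 genes of which 168 are zeroed in one
  species (so 4832 pass the expressed-in-all filter), 12
  preference-linked genes, Brownian deviations with σ = 1.6 on a 7-taxon
  tree of depth 0.15 (tip sd ≈ 0.62), and log-normal replicate jitter
  (sd 0.05). The planted slope default is −30 on intercepts U(30, 100):
  linked genes in this system show slopes of the same order as their
  intercepts and adjusted R² above 0.95, and this scaling reproduces that
  regime; it comfortably exceeds the 5×BM-sd detectability floor. The
  packaged 7-taxon tree is a synthetic stand-in topology with plausible
  branch lengths, not the published phylogeny.
* **Selection tables**: 6038 genes; 617 and 266 planted shifts for the
  two foregrounds sharing 61; 489/218 of them faster; 548/245 branch-site
  shifts sharing 35; LRT effect +30 added to the null χ²₁ draws. Base
  foreground ω is drawn from a gamma-shaped but *bounded* distribution
  (0.02 + 0.28·Beta(2,2), support ≤ 0.30) with 11 and 5 outliers planted
  in [0.43, 0.70]: the bounded support keeps the Tukey fence (~0.35)
  strictly between the base maximum and the planted range, so the
  planted outliers are exactly the flagged set by construction.
* **Annotations**: 150 background terms with NB-distributed sizes and one
  planted term covering 80% of each study set.
* **Alignment clusters**: 100 clusters with planted fates — 40 pass, 35
  fail the aligned-length filter, 25 lose all but one sequence to
  degapping.

What the generator does **not** emulate: read-level sequencing noise,
mapping ambiguity and isoform collapse; correlated expression across
genes (all genes are independent given the tree, so the DE convergence
null holds exactly by construction); codon-level sequence evolution (the
selection tables fabricate log-likelihood differences directly); GO
ancestor structure; or alignment errors beyond simple gapping patterns.
Passing recovery tests therefore validates the statistical machinery and
its calibration, not robustness to those real-data complications.

## Numerical conventions and edge cases

* TSV everywhere, UTF-8, `NA` for missing, floats printed at 6
  significant digits; writers are byte-stable under a fixed seed.
* BH FDR passes missing p-values through unchanged and never includes
  them in the family size.
* Selection site lists are 1-based codon positions, comma-separated.
* Quartiles: linear interpolation (numpy default); documented above.
* `lrt` clamps negative statistics to 0; `pgls_fit` rejects constant
  predictors/responses and non-positive-definite covariances;
  `species_preference` raises when no replicate has eggs; a significant
  gene with log₂FC = 0 raises a tie error.
* Test-suite and acceptance-script problem sizes (e.g. 200-replicate null
  calibrations, 500-replicate slope recovery, the 100-cluster filter
  fixture) were chosen to give stable Monte-Carlo verdicts at desk scale.

## Known limitations

* The PGLS screen fits one gene at a time with a fixed λ = 1; no
  measurement-error model, no λ/κ/δ estimation, and the adjusted R²
  definition (whitened-space, GLS mean) may differ from other PGLS
  implementations.
* `call_de_simple` is a labelled stand-in, not a production DE method.
* The convergence χ² is asymptotic and mildly conservative; directions
  with expectation 0 are reported untestable rather than tested.
* GO terms are flat sets; results on propagated vs unpropagated
  annotations differ and the package does not resolve that upstream
  choice.
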