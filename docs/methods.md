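# Methods

## Setting and data model

The package analyses taxon-by-sample count tables from two-group
cross-sectional designs: a healthy **reference** cohort (default n = 38)
and a larger **symptomatic** cohort (default n = 126), as in
duodenal-aspirate studies of functional GI disorders. Counts are
non-negative integers with optional 7-rank taxonomy (kingdom → species);
samples carry clinical covariates (age, sex, BMI, recent antibiotics, PPI
use, GI surgery, SIBO culture CFU/mL). Samples with fewer than 1000 reads
are excluded before analysis (strict `<`, so a 1000-read sample is kept);
SIBO positivity is inclusive at 10⁵ CFU/mL.

## Reference-cloud dysbiosis index

Compositions are treated in the Aitchison geometry. For each sample,
relative abundances are made strictly positive by multiplicative
replacement (zeros set to δ, nonzeros rescaled so the row stays on the
simplex) and CLR-transformed, `clr_i = ln x_i − mean(ln x)`. The **cloud
statistic** of a sample is its mean Euclidean (= Aitchison) distance to the
k nearest healthy reference samples (default k = "all", i.e. the whole
cloud); a reference sample is excluded from its own reference set
(leave-one-out). With reference mean *m* and sample SD *s* (n−1
denominator) of the leave-one-out statistics, a sample is **dysbiotic** iff
its statistic is strictly greater than *m* + 2*s*. The dysbiosis index is
DI = ln(statistic) — a strictly monotone transform, so classification is
unaffected by the log.

Choices that matter:

- **δ = 0.5/depth per sample** (half a read at that sample's depth). δ must
  stay below the smallest nonzero proportion; the implementation enforces
  this.
- **One-sided rule.** Distances below *m* − 2*s* are "unusually typical",
  not dysbiotic.
- **Genus-level features by default.** Genus-collapsed tables are more
  stable than OTU tables at aspirate sequencing depths; OTU-level scoring
  is available by passing `level=None`.
- **Joint CLR basis.** The CLR transform is computed on all samples
  together; reference statistics then use reference rows only. Computing
  the basis per group would make query and reference CLR values
  incommensurable when zero-replacement differs.
- **Degenerate references error out** (constant leave-one-out statistics
  give SD 0 and no usable threshold).

On healthy-only synthetic cohorts of n = 38 this procedure keeps ≈ 97% of
reference samples healthy-like — the one-sided 2-SD tail of the
leave-one-out statistic distribution, which is tighter than a normal 2.5%
tail because each sample's statistic is an average over 37 correlated
distances. `scripts/acceptance.py` recomputes this number.

## Symptom index and validation

The SI is the out-of-bag probability of symptomatic membership from a
random forest (500 trees, √p features per split) on normalized abundances.
OOB scoring means a sample is only ever scored by trees whose bootstrap
excluded it, which removes optimism without a held-out set. AUC uses the
Mann–Whitney identity; its CI and the test against 0.5 use the DeLong
structural-component variance (cross-checked against R's pROC in the test
suite).

Shadow-feature selection refits the forest on real features plus
per-feature shuffled copies; a feature scores a hit when its impurity
importance beats the best shadow. Cumulative binomial tests (null
hit-rate ½, Bonferroni-adjusted over features still in play, α = 0.01,
≤ 100 iterations) confirm or reject features; undecided features stay
tentative. Rejected features are dropped from later iterations.

Covariate associations are simple per-covariate linear regressions of the
SI with BH FDR over the seven clinical covariates; the combined model
refits jointly on the covariates passing q < 0.1 and reports R². Missing
covariate values are dropped listwise per analysis, with n logged.

Orthogonal validation: healthy-group SI scores are logit-transformed
(clipped to (10⁻⁶, 1−10⁻⁶)); Shapiro–Wilk normality of the healthy logit
scores is reported descriptively, never used as a gate. The 2-SD rule on
logit(SI) labels samples, a forest refit on those labels yields an OOB
probability-based index, and agreement with the cloud index is summarized
by Pearson correlation plus label concordance.

## Differential abundance

Counts are collapsed per taxonomic rank, normalized by size factors from
the geometric mean of pairwise median count ratios over shared nonzero taxa
(the geometric mean includes the trivial self-ratio so a uniformly scaled
sample receives a proportionally scaled factor; total-sum scaling is the
fallback for samples sharing no taxa, and available as `method="tss"` for
sensitivity analysis). Taxa with prevalence < 10% or maximum per-sample
proportion < 0.2% are excluded (strict `<`; boundary values are tested).
Tested values are square-root transformed; the two-sided permutation test
uses the Welch *t* statistic (robust to the 38-vs-126 group imbalance) with
the add-one estimator p = (1 + hits)/(1 + n_perm), so p is never 0. BH FDR
is applied within each rank, over tested taxa only. Zero-variance taxa get
p = 1 with a warning. For n ≤ 8 per test an exhaustive mode
(`n_perm="all"`) enumerates all group assignments exactly.

## Monte-Carlo power analysis

The generative model is Dirichlet-multinomial: composition ~
Dirichlet(p/θ) (mean p, total concentration 1/θ), counts ~
Multinomial(depth). The default scenario tests 65 genera with a geometric
rank-abundance profile, the genera at abundance ranks 6–15 decreased by 50%
in the symptomatic group (means renormalized), n = 38 vs 126, a two-sided
Wilcoxon–Mann–Whitney test per genus on relative abundances, and BH FDR at
5% across all genera. Per-taxon power is the detection frequency over
replicates; average power averages the ten differential genera;
any-detection power is the fraction of replicates detecting at least one.
At the defaults this yields roughly 75–80% average power and 100%
any-detection power with 200 replicates (a few seconds of compute).

## Diversity statistics

Shannon entropy is reported in **bits** (base-2; `base=e` gives nats);
Pielou evenness is Shannon/log₂(richness), defined as 1 for a single taxon
(both evenness readings the ambiguity allows are thus derivable). Faith's
PD includes the path to the root, matching common amplicon-pipeline
behaviour. Rarefaction subsamples without replacement (multivariate
hypergeometric) and drops too-shallow samples with a log message rather
than erroring. PCoA is classical scaling of the double-centered squared
distance matrix; negative eigenvalues are reported and % variance is
relative to the positive-eigenvalue sum. PERMANOVA uses the standard
pseudo-F partition of squared distances with the add-one permutation p; an
exhaustive mode enumerates all label orderings for small n. Pairwise
ordination-axis tests are Welch *t* tests with BH correction across pairs.

## Synthetic cohort generator

The generator emulates the statistical structure the analyses assume, not
any particular real dataset:

- **Rank-abundance:** geometric decay, rate 0.85 over 65 genera, giving a
  realistic "moderately abundant" regime at ranks 6–15. The true abundance
  profile of small-intestinal aspirates is unknown; the rate is
  configurable.
- **Overdispersion:** θ = 0.02 (total Dirichlet concentration 50), a
  typical amplicon-scale value; configurable.
- **Depths:** log-normal, median 20 000 reads, σ = 0.5 log units, with a
  5% fraction forced below 1000 reads to exercise the depth filter.
- **Dysbiotic subpopulation:** 30% of cases draw from a shifted
  distribution in which 26 moderately abundant genera (abundance ranks
  6–31) are depleted to 10% of their baseline mean — a "relative absence"
  style depletion that lowers richness, evenness, and Shannon diversity of
  dysbiotic samples, as dysbiosis presents in this setting. The
  power-analysis scenario (10 genera halved) is deliberately separate and
  milder.
- **Covariates:** recent antibiotics (prevalence 0.20), PPI (0.35), GI
  surgery (0.214), male sex (0.25 cases / 0.30-style reference), age
  uniform 18–89 with a +8-year shift for dysbiotic samples, BMI ~
  N(27, 5²), SIBO culture positivity 52% among cases with log-uniform CFU on
  either side of 10⁵. Antibiotics/PPI/surgery odds are multiplied by
  2.5/2.0/2.0 for dysbiotic samples so covariate-association analyses have
  signal to recover; all linkages are configurable and can be switched off.
- **Phylogeny:** random bifurcating topology with Exp(1) branch lengths —
  adequate for exercising Faith's PD and UniFrac, with no biological
  signal.
- **Seeding:** one global seed; every stochastic component derives an
  independent child stream, so cohorts are bit-reproducible.

What the generator does **not** emulate: real taxon co-occurrence and
phylogenetic correlation structure, contamination and batch effects,
compositional outliers, or any metabolomic/transcriptomic layer. Passing
recovery tests on synthetic cohorts therefore demonstrates correctness of
the statistical machinery under the stated model, not clinical performance
on real aspirate data.

## Numerical and testing choices

Permutation p-values use add-one estimators except in exhaustive modes,
which report exact enumeration fractions (including the identity
permutation, so p ≥ 1/N). Tolerances in tests follow the source of error:
exact identities at 1e-8–1e-12, Monte-Carlo checks at 3σ bands or
generous fixed bands with frozen seeds. Problem sizes in the test suite
(200 power replicates, 200 coverage cohorts, 40 null cohorts for type-I
calibration, reduced tree counts in forest-based tests) were chosen so the
whole suite exercises every statistical claim in well under an hour on one
CPU while keeping Monte-Carlo standard errors small relative to the bands.

## Known limitations

- The cloud statistic with k = "all" is a mean distance to the reference
  cloud; the cited neighborhood variant (small k) is implemented but the
  field has no consensus default for k.
- The permutation test treats taxa independently within a rank; no
  cross-taxon correlation adjustment beyond BH.
- GMPR-style size factors assume enough shared nonzero taxa between sample
  pairs; extremely sparse tables fall back to total-sum scaling.
- DeLong CIs are asymptotic and can exceed [0, 1] before clipping at very
  small n.
- The forest-based indices inherit scikit-learn's impurity-importance
  biases (toward high-cardinality features); shadow-feature selection
  mitigates but does not eliminate this.
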