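# Methods

`mircog` re-implements, as a reusable and testable pipeline, the
statistical machinery needed to score a small microRNA signature in
blood or brain sequencing counts and to relate it to cognitive
performance: eigen-expression scoring with QC and covariate adjustment,
random-effects meta-analysis with a random-signature permutation null,
ranked-list and gene-set overlap statistics, composite cognitive scoring
of a test battery, and a water-maze trajectory analysis with a weighted
daily cognitive score. This note records the models, the defaults and
why, and what the synthetic-data generators do and do not establish.

## Eigen expression of a signature (`mircog.signature`)

The pipeline order is fixed and enforced through provenance flags:

1. **Filter** — keep features with ≥ `min_reads` in ≥
   ceil(`min_fraction`·n) samples. Defaults 5 reads / 50% (the
   co-expression-analysis filter); differential-style analyses
   conventionally use 100 reads / 50%.
2. **Normalize** — `log2(1 + CPM)`. The pseudocount of 1 keeps zero
   counts at exactly 0 and bounds the transform's derivative.
3. **Adjust** — per-feature OLS on user-supplied covariates (age, sex,
   batch or latent factors supplied as numeric columns); output is the
   residual plus the feature's grand mean. Surrogate-variable
   *estimation* is out of scope; estimated factors can be passed in as
   covariate columns.
4. **QC** — each sample's quality Z is its mean Pearson correlation to
   all other samples, z-scored across samples (sample-network
   connectivity). Samples with |Z| > 2.5 are removed in a single pass.
   With fewer than 4 samples nothing is removed (a Z over 2–3 samples is
   meaningless).
5. **Eigen score** — the signature's rows are z-scored (configurable to
   centering only; z-scoring is the adopted reading since the source
   procedure is not explicit) and decomposed by SVD. Each sample's score
   is σ₁·v₁ (first right-singular vector scaled by the first singular
   value) — the module-eigengene convention, the only reading of
   "eigenvalue of the signature" that yields a per-sample scalar. The
   sign is flipped if the score correlates negatively with the set's
   mean z-expression, so "higher score = higher signature expression"
   always holds. Variance explained is σ₁²/Σσᵢ². An optional second
   screening pass removes samples whose *score* has |Z| > 2.5 and
   recomputes once.

Group comparison uses the unpaired two-sided Wilcoxon rank-sum test:
exact p by enumeration when the combined n ≤ 20 without ties, otherwise
the tie-corrected normal approximation (scipy's implementation; an
independent enumeration oracle guards it in the tests). Phenotype
association is a Pearson correlation with a t-based p. Stratification
scales the score, computes a within-cluster-SS curve for k = 1..k_max by
seeded k-means (25 restarts), picks the k maximizing the WSS curve's
second difference (ties toward smaller k; an all-identical input yields
k = 1), and assigns clusters by cutting a complete-linkage dendrogram at
that k.

## Meta-analysis and overlap statistics (`mircog.meta`)

Per-study effects are Cohen's d with variance
(n₁+n₂)/(n₁n₂) + d²/(2(n₁+n₂)); the Hedges small-sample correction is
available but off by default because d is the declared effect measure.
Pooling is random-effects with the two-step Sidik–Jonkman (SJ) τ²
estimator: τ₀² is the unweighted variance of effects (divisor k), and
τ²\_SJ = Σwᵢ(dᵢ−d̂)²/(k−1) with wᵢ = 1/(vᵢ/τ₀²+1). Study weights are
1/(vᵢ+τ²); the CI is the normal-approximation 95% interval (no
Knapp–Hartung, since a Z statistic is what is reported downstream).

**A calibration caveat that matters.** SJ never returns τ² = 0 and, at
true τ² = 0, estimates τ² ≈ mean(vᵢ); the pooled SE is then inflated by
roughly √2 and the nominal p < 0.05 rate under an exact null is ~0.006,
not 0.05. This conservatism at low heterogeneity is a documented
property of the estimator, not an implementation artifact — the
fixed-effect reduction (τ² forced to 0) and a step-by-step hand
evaluation of the SJ arithmetic are both verified in the tests. Users of
the random-signature null should read its p-values as conservative and
rely primarily on the focal signature's *percentile* among random
combinations, which is calibration-free.

BH adjustment supports an explicit denominator n larger than the list
(as when 1,000 random combinations define the family). The
random-signature null draws seeded k-subsets from a candidate pool
(without replacement within a combo; combos may recur across draws, as
in naive repeated sampling), scores each combo by eigen expression in
every dataset, pools its Cohen's d values, and BH-adjusts across the
family; no per-dataset rescaling is applied before computing d.

RRHO counts overlaps of the two rankings' top-t₁/top-t₂ sets at every
`step`-th threshold pair and reports the one-sided hypergeometric
enrichment tail, −log10-transformed, with a BH-adjusted twin adjusted
jointly over all cells (a configurable choice; the source procedure is
silent). Note that under this one-sided enrichment convention a reversed
ranking produces *depletion* everywhere (overlap = max(0, t₁+t₂−N) ≤
expectation), never a significant cell. Gene-set overlap reports
observed |A∩B|, expected |A||B|/|U|, their ratio as fold enrichment, and
the upper hypergeometric tail; the conventional reporting rule is fold
enrichment > 1.5 at FDR < 0.05.

## Composite cognitive score (`mircog.cognition`)

Each test column is z-scored over the scored cohort (no external norms);
error-count tests are sign-flipped first so higher always means better
(exposed as per-test direction flags, since the treatment of error
scores is not fully specified in the source). Domain scores are means of
member z-scores and the composite is the mean of domain scores, so it
has mean ~0 over the cohort by construction. Zero-variance tests are
excluded with a warning; an empty domain is an error. Domain membership
is accepted as configuration; full exploratory factor analysis with
RMSEA-based fit is deliberately out of scope (standard-package
territory), but Horn's parallel analysis is provided to justify the
factor count: observed correlation-matrix eigenvalues are compared
position-by-position with the 95th percentile of eigenvalues from
same-shape standard-normal data, counting leading exceedances until the
first failure.

## Water-maze analysis (`mircog.maze`)

A trial is a time-ordered (t, x, y) sequence in a circular pool (default
radius 60 cm, i.e. the 1.2 m arena) with an 11 × 11 cm platform. All 17
descriptors are computed from raw samples: proximity statistics to the
platform, perimeter-distance mean/variance, turning-angle sums, quadrant
occupancy, platform entries (outside→inside transitions of the platform
square), convex-hull coverage over pool area, mean pairwise distance of
positions ("local density"), path length, mean velocity, and path
efficiency. Two definitional choices:

* **Path efficiency** is implemented as straight-line distance divided
  by path length, giving a value in (0, 1] with 1 = perfectly straight;
  the verbal definition in the source ("path length over Euclidean
  distance") exceeds 1 and contradicts the word "efficiency", so the
  reciprocal is adopted (and documented here).
* Heading angles are computed over displacement steps longer than
  0.1 cm (configurable) so tracker jitter around a resting animal does
  not dominate; variances are population variances.

Degenerate inputs: a zero-length path reports velocity 0 and efficiency
1 and is flagged; fewer than 3 samples is an error (angle features are
undefined).

Strategy classification is an ordered decision list over the features
with a fixed fallback of "random". The original MUST-C thresholds are
not published, so the shipped defaults are stipulated, expressed
relative to pool geometry, and fully editable: direct (efficiency ≥
0.8), corrected (≥ 0.5), circling (mean perimeter distance ≤ 0.12 r with
sustained turning), then short/long chaining (mean perimeter distance in
the annulus band around the platform's radial distance with low radial
variance, split by trial duration — short chaining terminates early by
definition, which is why `total_duration` joins the default rule
features). Strategy scores are fixed: direct 10, corrected 9.5, short
chaining 9, all others 0. The daily weighted cognitive score is

  score = (1/n) Σᵢ (Sdfᵢ·10 + Sscfᵢ·9.5 + Slcfᵢ·9) / m,

with n trials per day, m mice, and Sdfᵢ/Sscfᵢ/Slcfᵢ the counts of mice
using each scored strategy in trial i ("frequency" is read as a count
divided by the mouse total, the only reading that lands in [0, 10]).

Occupancy maps bin positions on a 50 × 50 grid over the pool's bounding
square, convert counts to densities, smooth with a Gaussian kernel
(σ = 1 cell by default; no kernel is named in the source), and min–max
normalize with the global minimum and maximum across all experimental
groups so maps are directly comparable.

## Synthetic data (`mircog.simulate`)

All generators are pure functions of (spec, seed).

* **Count cohorts** — negative binomial with var = μ + αμ² (default
  dispersion α = 0.15, a typical bulk small-RNA value), log-normal
  baseline composition (σ = 1.5, giving the heavy-tailed abundance
  profile of blood microRNAomes), library sizes uniform on
  0.5–1.5 million reads, and default 20 + 20 samples with 200 features.
  The planted group effect is additive on the log2-mean of the
  signature features in cases. Covariate effects act on the log2 mean of
  a random half of the features (an effect on *all* features is
  indistinguishable from library size and would vanish under CPM). No
  distributional parameters were fitted to real data — the generator's
  world is stipulated, which is exactly why green calibration tests
  establish procedure-level correctness (type-I error, power, coverage)
  and not claims about any real cohort. Real data differ in correlated
  features, batch structure and zero inflation, none of which are
  emulated.
* **Meta-studies** — per-study true effect θᵢ ~ N(SMD, τ²), then
  unit-variance normal groups differing by θᵢ. Calibration defaults
  (k = 15 studies of 30 + 30, SMD = 1, τ = 0.2) mirror a moderate
  multi-cohort meta-analysis.
* **Swim trials** — discrete-time kinematics at 10 Hz, constant speed
  18 cm/s (typical mouse swim speed), heading dynamics per strategy
  (goal-directed, one corrected turn, annular sweeps at the platform's
  radial distance, perimeter hugging, correlated random walk), 0.5 cm
  Gaussian tracker jitter, termination at platform contact or 60 s.
  With `noise_sd = 0` the kinematics are fully deterministic so
  noiseless direct swims are exactly collinear.
* **Cognitive batteries** — scores = latent factors · loadingsᵀ + noise.

## Numerical choices and limitations

* Exact Wilcoxon enumeration is capped at combined n = 20; beyond that
  the tie-corrected normal approximation (with continuity correction)
  takes over.
* k-means uses 25 restarts with a fixed seed; elbow ties break toward
  smaller k (parsimony).
* The quality-Z guard returns all-zero Z when samples are perfectly
  identical (zero connectivity spread) rather than dividing by zero.
* Convex-hull coverage of collinear trajectories is 0 (degenerate hull);
  such trials are flagged rather than rejected.
* The classifier defaults were tuned against this package's own trial
  simulator; on real tracking data the thresholds should be revisited —
  they are configuration, not constants.
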