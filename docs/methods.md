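# Methods

This note records the statistical models implemented in `crosspheno`, the
choices made where the design was genuinely open, and what the synthetic
data can and cannot establish.

## CCMA: the max-of-four statistic

Per variant, the two disease-specific meta-analyses yield signed z-scores
T₁ and T₂ oriented to a common effect allele.  The four components

|T₁|, |T₂|, |T₁+T₂|/√2, |T₁−T₂|/√2

are each standard normal under the global null (the √2 divisor is what
gives the sum/difference contrasts unit variance; without it the
shared/opposing categories would be unreachable, since |T₁+T₂|/2 can never
exceed max(|T₁|,|T₂|)).  T_max is their maximum and the arg-max component
names the category; exact ties (a probability-zero event for continuous
data) break deterministically in the order AD, PSO, shared, opposing.

Null model: T₁ ⟂ T₂.  This holds when the two diseases' control sets do
not overlap; with shared controls the null would be correlated and the
calibration conservative for opposing and anti-conservative for shared
calls.  The package does not model overlapping controls.

The null tail P(Z_max > t) is computed two ways:

* **Monte Carlo** (`simulate_null`): chunked draws of (Z₁, Z₂), default
  10⁷, p-values by the plus-one rule, so the smallest attainable p is
  1/(n+1) and p-values are valid (slightly conservative) at any n.
* **Analytic** (`analytic_tail_p`): {Z_max ≤ t} is the octagon
  |z₁| ≤ t, |z₂| ≤ t, |z₁±z₂| ≤ t√2.  The tail is accumulated directly
  (Φ(lower) + Φ̄(upper) inside the integral, plus the |z₁| > t mass) so
  relative accuracy is preserved to 10⁻¹⁰ and beyond — computing
  1 − P(octagon) would lose everything below ~10⁻¹⁵ to cancellation.
  `quad` is given the octagon's kink abscissae as breakpoints.

Root-finding on the analytic tail gives t(10⁻⁵) = 4.699 and
t(10⁻⁸) = 5.960, i.e. the conventionally quoted 4.7 and 6.0.  Calibration
from an empirical null refuses targets below its resolution 1/(n+1) and
a curve validity bound of 10⁻⁹, pointing the caller to analytic mode.

## Partition-model meta-analysis

All studies enter one model.  A partition P groups the studies into
clusters; under the alternative every cluster k shares one latent effect
b_k ~ N(0, W), so the cluster marginal likelihood is multivariate normal
with covariance diag(se²) + W·11ᵀ — evaluated with rank-one
determinant/Woodbury identities, no factorization.  The Bayes factor
averages over partitions:

BF = Σ_P π(P) Π_k m₁(cluster k) / Π_i N(β_i; 0, se_i²).

This is a deliberate simplification of full transethnic partition
machinery: a fixed-variance conjugate prior (default W = 0.04 ≈ (log 1.22)²,
a modest odds ratio) instead of a hierarchical prior with unknown mean and
scale, and exhaustive enumeration instead of MCMC — exact for ≤ 12 studies,
no convergence concerns.  Under the alternative every cluster carries an
effect; mixed null/non-null clusters are not modelled.

**Distance prior.**  D_Ethnicity is the full matrix of pairwise Euclidean
distances between study MDS centroids (a *diagonal* distance matrix would
be degenerate, so the diagonal is zero and off-diagonals carry the
distances).  D_Disease adds 2·max(D_Ethnicity) to cross-disease pairs and
max(D_Ethnicity) to same-disease pairs that differ in subphenotype.
Candidate partitions come from the center-based scheme: for every cluster
count T and T-subset of studies as centers, each study joins its nearest
center under D_Total (ties to the lowest center index); duplicate induced
partitions merge.

Configuration weights are proportional to
exp(−Σ_s d(s, nearest center)/λ) with λ the mean off-diagonal ethnic
distance.  This is the step that makes the disease inflation effective:
assigning a study across the disease boundary costs several λ, so
partitions mixing the diseases within a cluster get negligible prior mass.
Under uniform configuration weights (available as
`weighting="uniform"`) the induced prior depends on the distances only
through nearest-center geometry, and the all-studies-in-one-cluster
partition retains weight ≥ 6/63 no matter how large the disease inflation
is — the distance prior would then have no mechanism to disfavour
disease-mixing, which defeats its purpose.  The scale-free choice of λ
means the behaviour is invariant to rescaling the MDS coordinates.

**BFDP.**  With prior odds PO in favour of no association,
BFDP = PO/(PO + BF) is the posterior probability of no association,
computed in log space.  PO is *odds in favour of H₀* throughout (so 99 and
999 for 1%/0.1% prior probability of association); thresholds quoted as
"PO = 1/99" elsewhere are read as the same 99:1 odds against association.

## Multinomial model

Three outcome categories with control as baseline; maximum likelihood via
Newton-Raphson (statsmodels MNLogit), covariance from the inverse observed
information.  Default covariates: sex plus whatever principal-component
columns the caller names; age is accepted for the per-study logistic scans
but excluded from the multinomial default.  The 2-df overall test is
computed as the quadratic form βᵀΣ⁻¹β in (β_PSO, β_AD) — algebraically
identical to testing the (sum, difference) pair, since that contrast
matrix is invertible.  Classification takes the minimum of the four 1-df
p-values: the per-disease test is most powerful for a specific effect, the
sum contrast for a same-direction effect, the difference contrast for an
antagonistic one.

Divergent fits (non-finite estimates, |β| > 15, non-convergence) raise and
are excluded downstream rather than silently reported.  When cohorts each
contribute cases of a single disease, per-cohort indicator covariates
would perfectly predict the absence of the other disease and
quasi-separate the likelihood; `pool_panels` therefore defaults to *no*
study indicators, and ancestry-style covariates (MDS components) are the
recommended adjustment for pooled fits.

Stepwise conditional analysis: forward selection on p_MNM with the current
conditioning set (known-mutation dosages plus previously selected
variants) as covariates, stop at p ≥ 10⁻⁵ by default (the suggestive
level; configurable), skip candidates with r² > 0.95 to the conditioning
set, and finish with a joint fit of all selected signals.

## QC

* Exact Hardy-Weinberg test: conditional distribution of the heterozygote
  count given allele counts via the stable ratio recurrence; two-sided p
  sums probabilities ≤ the observed one (with a 1+10⁻¹² tie tolerance).
  Monomorphic variants return 1.
* Variant filters (strict inequalities in the failing direction):
  missingness > 5%, MAF < 5%, HWE p < 10⁻⁸, imputation info < 0.4.  Sample
  screens run first: missingness > 5%, heterozygosity beyond mean ± 3 SD
  (no published bound exists for this screen; 3 SD is the configurable
  default), then relatedness.
* PI_HAT: method-of-moments IBD from IBS counts.  The allele-frequency
  products entering the expected IBS compositions are estimated without
  bias from allele counts via falling-factorial moments; plug-in powers of
  p̂ would inflate PI_HAT noticeably in small panels.  Markers are LD-pruned
  (window r² < 0.2) first.  Of a flagged pair (PI_HAT > 0.1875, halfway
  between second- and third-degree expectation) the member with higher
  missingness is dropped.  PI_HAT estimates need thousands of pruned
  markers to be stable; with a few hundred, clipping of the moment
  estimates biases small values upward.
* MDS: classical Torgerson scaling of (1 − IBS); deterministic up to axis
  sign.  λ_GC: median chi-square over the exact null median
  (`chi2.ppf(0.5, 1)`, computed not hard-coded).

## LD and loci

r² is the squared Pearson correlation of dosages (composite LD, no
phasing), computed from control samples by default.  Clumping is greedy:
best statistic first (ties to smaller position), absorbing variants within
250 kb of the *lead* (closed interval) with r² ≥ 0.5; clumps partition the
passing variants.  A *locus* uses strict r² > 0.5 around a lead — both
inequalities are kept as written because they serve different definitions.
A *shared region* is flagged when AD and PSO clumps fall within a 2 Mb
window.

## Synthetic data

The generator emulates the study design: three AD cohorts (one
childhood-onset) and three PSO cohorts, each with its own small Gaussian
ancestry offset on allele frequencies, cohort sizes defaulting to roughly
one tenth of consortium scale (200–450 cases each) so pipelines run in
seconds to minutes.  Variant classes AD_only / PSO_only / shared /
opposing / null with configurable odds ratios (default 1.4 per active
component).

Three paths:

* `simulate_summary_stats` — β̂ ~ N(true β, se²) with se from the 2×2
  allele-count approximation; fast path for meta/CCMA/partition layers.
* `simulate_cohorts` — individual-level genotypes; LD by a first-order
  haplotype-copying process within blocks (keeps dosages integral and HWE
  exact within cohorts); one causal variant per block drives a logistic
  liability whose intercept is solved numerically to hit the configured
  prevalence (10% AD, 2% PSO); cases/controls sampled prospectively to the
  requested counts.  Tag variants record attenuated marginal truth effects
  (ρᵏ at offset k) and a CAUSAL flag.
* `simulate_retrospective` — per-variant case-control sampling
  (P(g|case) ∝ P(g)·risk(g)); every variant behaves as the sole causal
  variant, which is what per-variant power/agreement harnesses need; LD is
  deliberately absent here.

What passing tests on these data do **not** show: robustness to population
stratification beyond small mean-frequency offsets, to imputation error,
cryptic relatedness between cohorts, overlapping controls, or genuinely
polygenic backgrounds; the marginal-effect bookkeeping for tag variants is
an approximation (exact only at equal allele frequencies); and logistic
marginal effects are mildly attenuated relative to joint effects
(non-collapsibility) when many causal variants segregate — negligible at
the default effect sizes.

## Mutual exclusivity

Each disease follows a log-additive logistic risk model over L ≤ 15 loci
with independent HWE genotypes; intercepts are calibrated so marginal
prevalences match (defaults 10% AD, 2% PSO).  The diseases are assumed
conditionally independent given genotype — the minimal assumption that
lets two marginal risk models combine — giving
P(AD|PSO) = Σ_g P(AD|g)P(PSO|g)P(g)/P(PSO) by exact 3^L enumeration.  The
observed exclusivity benchmark is a 25-fold prevalence reduction
(10% → 0.4%, i.e. 9.6 percentage points); the explained share divides the
genetic reduction by it.  Allele frequencies are user inputs; no published
frequencies exist for the motivating loci, so only the downstream
arithmetic is fixed.

## Numerical conventions

Positions are 1-based (hg19-style), all interval logic closed.  Missing
dosages use the sentinel −1.0, outside [0, 2], and every consumer masks it
explicitly.  Palindromic (A/T, C/G) variants with MAF > 0.4 are dropped at
harmonization (strand unresolvable).  Multi-allelic VCF sites are expanded
into distinct bi-allelic records.  Variant matching defaults to
(chrom, pos, allele-set); id-based matching is opt-in.  All randomness
flows from explicit seeds through `numpy.random.Generator`; the CCMA null
uses two spawned child streams so results are invariant to chunk size.

## Problem sizes used in the checks

The end-to-end suite uses 10⁷ Monte-Carlo null draws for the threshold
cross-check, 10⁴ simulated null variants for p-value uniformity, 500
variants per effect class (odds ratio 1.6, so every active meta component
carries |z| ≳ 6) for the CCMA/MNM agreement check, 100 replicates at
n = 4000 for coverage, 1000 random configurations against the brute-force
clumping reference, and every Hardy-Weinberg configuration up to 200
genotypes against direct log-factorial enumeration.
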