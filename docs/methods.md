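# Methods

This note documents the models and procedures implemented in mobindex, the
parameters that matter, the synthetic-data generator's assumptions, and
the numerical and design choices made where the design was genuinely open.

## Annotation ingest and filtering

Input hit tables (blast outfmt-6 dialect or the package's headered TSV)
are parsed row by row with line-numbered validation. The alignment-quality
filter keeps hits with E-value ≤ 1 × 10⁻⁵ **and** percent identity ≥ 80;
both comparisons are inclusive, matching the operators as usually printed.
After filtering, hits are deduplicated per (sample, contig, gene class,
gene name): the hit with the highest bit score is kept, ties broken by
lowest E-value then lexicographic subclass, so every downstream count is
reproducible regardless of input order. Deduplication can be disabled for
workflows whose upstream already resolves best hits. A "gene" throughout
is one deduplicated (contig, gene class, gene name) record — a count on
assembled sequence, not a read count.

## The three indices

CR, CoR and MP are ratios of counts and are computed as exact `Fraction`s
before the final float conversion; this makes the calibration property
(one extra carrier in 100,000 contigs shifts CR by exactly 1e-5) hold to
the bit rather than to float rounding.

Open choices and how they were resolved:

- **Co-location = same contig, any distance.** No within-contig distance
  rule is applied; hits are contig-level and carry no coordinates here.
- **"Type" in the co-occurrence numerator** means the three gene classes
  MRG/ARG/VFG. Named subsets (each pair, the triple) and a generic
  any-pair variant (≥ 2 distinct classes) are all computed.
- **Denominator policy.** Every contig in the table counts in
  `N_contigs`; an optional minimum-contig-length filter (default 0)
  restricts the universe when desired.
- **Mobility routes.** IS, transposon, integron, ICE and plasmid-gene
  categories are detected from MGE hits on the contig; plasmid- and
  phage-mediated mobility use the contig's upstream mobility-context
  label (PlasFlow/VirSorter2-style callers). "Overall" MP is the union of
  all routes. The two routes mirror how real annotation workflows produce
  these signals: read-level MGE hits versus whole-contig classification.
- **MP counts a gene once**, however many MGE partners share its contig
  (set semantics); the alternative (once per partner) would make MP
  unbounded.
- **0/0 is missing, not zero.** A sample with no ARGs has no measurable
  ARG mobility; imputing 0 would bias the driver regressions, so
  undefined MPs are serialized as empty fields and dropped listwise per
  model.

## Diversity layer

Shannon entropy uses natural log (nats); Pielou's evenness J = H/ln(S)
inherits the base and is base-invariant; J is undefined (missing) at
richness 1. The Wilcoxon rank-sum test enumerates the exact permutation
distribution of the rank sum (average ranks for ties, two-sided via
distance from the null mean) when the combined n ≤ 12 — with 12 samples
this is the common case — and otherwise uses the tie-corrected normal
approximation.

"Horn" dissimilarity is implemented as 1 − Morisita–Horn similarity,

    MH(x, y) = 2 Σ x_i y_i / ((Σx_i²/X² + Σy_i²/Y²) · X · Y),  X = Σx_i,

which is invariant to row rescaling (a relative-abundance measure);
Bray–Curtis is not, and both properties are asserted by tests.

PCoA applies Gower double-centering of −D²/2 and a symmetric
eigendecomposition. Negative eigenvalues (possible for non-Euclidean
dissimilarities) are reported unchanged, never truncated or corrected;
coordinates are returned only for eigenvalues above 1e-10, and axis signs
are fixed by making each axis's largest-magnitude coordinate positive.

PERMANOVA uses the sums-of-squared-distances pseudo-F (one-way,
raw-label permutation). When the number of distinct relabelings is
≤ 10,000 the full set is enumerated and the p-value is the exact tail
fraction (the observed arrangement included, so p > 0 always); otherwise
999 seeded random permutations are used with the add-one convention
p = (1 + #{F* ≥ F}) / (1 + n_perm). The permutation count default of 999
is the standard ecology choice.

## Driver regression cascade

All models regress a per-sample index (or richness/abundance) on raw-unit
covariates — pH units, g/kg for Fe/WS/SOM/N, mg/kg for trace metals — so
coefficients read as per-unit effects.

1. **VIF screen.** Predictors are removed iteratively, worst first, while
   any VIF = 1/(1−R²) ≥ 5 (auxiliary regression with intercept); exact
   duplicates produce infinite VIF and are dropped first. The screen
   never touches an orthogonal design.
2. **OLS** with 95% confidence intervals; Shapiro–Wilk (residual
   normality) and Breusch–Pagan (homoscedasticity) p-values recorded.
3. **Gate.** OLS is kept when both screens pass at α = 0.01 per test.
   The size was chosen so the joint false-alarm probability on data that
   truly meets the assumptions stays near 2% — two independent 5% screens
   would spuriously abandon OLS on ~10% of perfectly Gaussian datasets —
   while gross violations (the kind the robust stage exists for) give
   p-values orders of magnitude below any conventional gate.
4. **Huber M-estimation** (IRLS, tuning constant 1.345 for 95% Gaussian
   efficiency, MAD scale, convergence when coefficients move < 1e-8, cap
   200 iterations). Non-convergence is flagged, not fatal.
5. **Bayesian linear regression** is the terminal fallback (and available
   on request): non-convergence of the robust fit, or n ≤ p + 3, falls
   through. The branch actually taken is recorded in the result.

### Bayesian model

y ~ normal(α + Xβ, σ) with β_j ~ normal(0, 0.5), σ ~ exponential(5), and
α ~ normal(0, 1). **Priors apply on standardized data** (predictors and
response z-scored internally): a normal(0, 0.5) prior is only weakly
informative if variables are on comparable scales — on a raw response of
order 1e-5 it would overwhelm the likelihood entirely. Posterior draws
are back-transformed, so reported coefficients and intervals are
per-raw-unit.

Sampling is blocked Gibbs: the full conditional of (α, β) given σ is
multivariate normal (conjugate) and is drawn exactly via Cholesky; σ has
a non-conjugate full conditional under the exponential prior and is
updated by univariate slice sampling with stepping-out (width = current
σ, capped at 50 step-outs). Chains are independent, seeded from a
spawned `SeedSequence`, and initialized overdispersed around the OLS
solution (coefficient jitter sd 0.5, σ jittered by a log-normal factor).
Because the coefficient block is drawn from its exact conditional, the
sampler's effective sample sizes are close to the nominal draw count.

Reported diagnostics: split R-hat and bulk/tail ESS per parameter (via
arviz), equal-tailed 95% credible intervals, and posterior-predictive
p-values for the mean and sd test statistics (simulated replicates on the
raw scale). R-hat > 1.01 attaches a convergence warning. ESS magnitudes
are reported as outputs; the internal gate is R-hat ≤ 1.01 and ESS ≥ 400.
A `fixed_sigma` mode reduces the model to its conjugate-normal form with
a closed-form posterior, used by the test suite as an analytic oracle.

A calibration note: an equal-tailed credible interval under an
informative prior is not a confidence interval. When the true
standardized effect sits in the prior's tail (≈ 1.6 prior sd in the
recovery study below), shrinkage makes 95% credible intervals cover a
*fixed* truth slightly less than 95% of the time — the suite measures
≈ 90–92% — which is the model behaving as specified, not a sampler
defect.

### Spearman matrices

Rank correlation with average ranks; two-sided p from the
t-approximation for n ≥ 10 and from the exact permutation distribution
(all n! pairings, vectorized) for smaller n. Constant columns give
missing correlations. Benjamini–Hochberg q-values are available but off
by default, mirroring the convention of reporting raw significance in
this literature.

## Synthetic-data generator

The generator emulates the *annotation tables* of a 12-sample soil
study — 8 metal-contaminated (MS), 4 control — not reads or sequences.

- **Covariates** are truncated-normal (≥ 0) group-structured draws. The
  default means/sds are set to plausible mining-area values consistent
  with reported ranges: Fe around 100 (MS) vs 30 (control) g/kg, V around
  120 vs 50 mg/kg (pooled mean ≈ 96.7 mg/kg), N 0.067 vs 0.037 g/kg, EC
  1500 ± 800 vs 300 ± 120 µS/cm, and so on (see
  `synth.DEFAULT_COVARIATES`).
- **Carriage** is a clamped linear-probability model per class:
  p_class(x) = clamp(b0 + Σ_m b_m (x_m − ref_m)), with ref the pooled
  covariate mean. Linear rather than logistic, so every index expectation
  has a closed form; default effects are of order 1e-6–1e-4 per raw unit
  (e.g. +6e-5 per g/kg Fe on MRG carriage), the realistic scale for
  per-unit effects on contig-level rates. Clamping events are counted and
  configs clamping > 1% of draws are rejected.
- **MGE placement**: per-category base probabilities (0.002–0.008) plus a
  +0.03 boost on gene-carrying contigs, which induces a non-trivial
  mobility potential (overall E[MP] ≈ 0.19 at defaults). Plasmid/phage
  contig labels are drawn independently (3%/1%).
- **Gene multiplicity**: carrier contigs get 1 + Poisson(0.3) distinct
  gene names from a fixed 40-name catalog per class.
- **Ground truth** (`truth_indices`) gives the exact per-sample
  expectations by independent-Bernoulli algebra — E[CR] = p_class,
  E[CoR(a,b)] = p_a p_b, E[MP(class, cat)] = p_cat + boost, with
  inclusion–exclusion for the any-pair variant and an optional hotspot
  mixture when the co-selection coupling is switched on. These closed
  forms are the oracles for the Monte-Carlo convergence tests.
- Everything is deterministic under the seed (byte-identical tables on
  regeneration); synthetic E-values are log-uniform in [1e-30, 1e-6] and
  identities uniform in [80, 100] so the quality filter is exercised but
  non-destructive, and a `contaminate` flag injects below-threshold rows
  to test it destructively.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: taxonomic composition, assembly artifacts
(chimeras, fragmented contigs), between-class genetic linkage beyond the
optional hotspot coupling, covariate-dependent MGE placement, and
compositional coupling between samples. Tests against the generator
validate the *statistical machinery*, not ecological conclusions.

## Pipeline

One YAML config drives synth/ingest → filter → indices → diversity →
regressions. Per-stage random streams derive from the run seed as
(seed + crc32(stage name)) mod 2³¹, a fan-out that is documented and
stable across versions; no wall-clock entropy anywhere. Regression models
use collected-error semantics (a singular fit is recorded and skipped, the
run continues), outputs are written atomically, and the manifest records
config hash, input checksums, per-stage status and timings. The markdown
report is a pure function of the manifest.

## Problem sizes in the test suite

The suite exercises the statistics at sizes chosen for tight oracles:
index oracles on 30–50-contig fixtures (exact equality), Monte-Carlo
convergence at 60,000 contigs (3 SE tolerance), recovery studies with 200
replicates at n = 100 samples, and a single high-resolution Bayesian fit
with 4 chains × 2,000 post-warmup draws. The full-study default of 5,000
contigs × 12 samples runs in the examples and pipeline demos.

## Known limitations

- One-way PERMANOVA only; no strata, no distance-based dispersion test
  (a significant PERMANOVA can reflect dispersion as well as location).
- The cascade's "unreliable results" trigger is operationalized as
  robust-fit non-convergence or n ≤ p + 3; other operationalizations are
  defensible.
- MP is a co-localization proxy: it says nothing about transfer rates,
  and plasmid/phage context labels are taken on faith from upstream
  callers.
- The Bayesian sampler targets small linear models (a handful of
  predictors, hundreds of observations) — the regime of per-sample index
  regressions; it is not a general-purpose MCMC engine.
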