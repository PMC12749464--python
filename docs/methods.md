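# Methods

This note documents the models and procedures implemented in `partnerseq`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic-data tests do and do not establish about real survey
data.

## Partnership-state sequences

Each person's marriage records (order, start year, end year, end reason)
are expanded into 36 yearly states for ages 15–50 over the alphabet
N (not married), M (married, first marriage), R (remarried, any marriage of
order ≥ 2 regardless of how the previous one ended), D (divorced),
W (widowed). Conventions:

* **Event-year rule.** The calendar year of an event carries the *new*
  state: the marriage year is M/R, the dissolution year is D/W. If a
  dissolution and a later marriage fall in the same year, the later-ordered
  event wins. Sources rarely state this convention; this one is consistent
  with forward-filling gap imputation (a year married in 1985 with the next
  valid report in 1988 yields M in 1986–1987).
* **Age indexing.** Position *p* ∈ {0..35} is age 15+*p*; age = year −
  birth year, with no birthday-month resolution.
* **Imputation.** Interior missing positions take the most recent observed
  state (LOCF); the imputed mask is retained. Leading missing positions are
  never invented — such persons are excluded. LOCF is idempotent and never
  changes observed positions (property-tested).
* **Legality.** Adjacent states must respect the transition matrix: states
  persist; N→M; M,R→D,W; D,W→R; everything else is illegal. N→D and N→W are
  tolerated only when a marriage occurs earlier in the sequence (a reported
  gap), enforced by `validate_sequence`. A closed marriage with an unknown
  end reason leaves the post-dissolution span missing rather than guessing.
* **Exclusions.** Persons with missing birth year, overlapping marriage
  records, all-missing or leading-missing sequences, or unrepairable
  illegal transitions are excluded and logged with reason codes; analyses
  operate on the retained, fully legal sequence set.

File formats: persons CSV (`person_id,birth_year,gender`), marriages CSV
(`person_id,order,start_year,end_year,end_reason`; blank end year =
ongoing), wide STS-style sequence CSV (`person_id,a15..a50`, one character
per state, `-` for missing in the raw variant), exclusion log CSV.

## Optimal-matching dissimilarities

The distance between two sequences is the minimum total cost of
transforming one into the other by substitutions and single-position
insertions/deletions, computed by the standard O(T²) dynamic program.
Defaults and rationale:

* **Substitution costs** use the transition-rate scheme,
  `sub(a,b) = 2 − p(b|a) − p(a|b)`, with transition probabilities pooled
  over all ages and persons of the sequence set being compared
  (time-invariant pooling is the scheme's common form). States never
  observed as a transition source get the maximum cost 2 — absent evidence
  of commonness, a transition is treated as rare.
* **Indel cost is 1.** Indels let the alignment shift sequences a few years
  when the same spells start at different ages, instead of substituting
  long mismatched stretches; distances therefore emphasize the timing and
  duration of marriage spells.
* **No length normalization** — all sequences are exactly 36 positions.
* Identical sequences are deduplicated before the all-pairs computation and
  distances broadcast back, which is exact and (with the archetypal
  structure of partnership data) often reduces the quadratic work
  substantially. A numba-compiled kernel is used when numba is importable;
  a pure-Python fallback gives identical results.

Verified properties: symmetry, triangle inequality, zero iff identical
(when all off-diagonal costs are positive), the position-wise substitution
(Hamming-style) upper bound, linear scaling in the cost scheme, and exact
agreement with an exhaustive edit-script enumeration on all short sequences
over a 3-state alphabet.

## Ward clustering and quality indices

`ward_linkage` runs agglomerative Ward merges directly on the precomputed
dissimilarity matrix via scipy's Lance–Williams implementation. The default
convention is **ward.D2** (recurrence on squared dissimilarities, heights
reported on the distance scale); **ward.D** (recurrence on the raw values)
is available via `variant="ward_d"` because published analyses do not
always say which convention they used and the two can shift index values.
Merge order is deterministic (scipy's nearest-neighbor chain); ties are
broken by that chain order. `cut_tree` renumbers the k-cluster labels by
descending size, then smallest member index, so labels are stable across
runs. k is a configuration choice (default 6); an index-vs-k scan table is
produced, but no automatic selection is performed.

With squared-dissimilarity discrepancy SS(A) = (1/2|A|) Σ_{i,j∈A} d²_ij,
T = SS(all), W = Σ_c SS(c), B = T − W:

* **R²** = 1 − W/T, **CH** = (B/(k−1))/(W/(n−k)) — the pseudo-variance
  decomposition that Ward's criterion optimizes;
* **ASW**: s(i) = (b_i − a_i)/max(a_i, b_i), own-cluster mean distance
  excluding self, singletons scored 0;
* **HG** (Hubert's Γ): Goodman–Kruskal-style concordance between
  within-cluster and between-cluster pair distances, ties dropped. It is
  counted exactly for any n by sorting the between-pair distances and
  accumulating rank counts, which is algebraically identical to the
  quadratic pair-by-pair comparison;
* **HC** (Hubert–Levin C): (S − S_min)/(S_max − S_min), where S is the
  within-cluster distance sum and S_min/S_max are the sums of the m
  smallest/largest distances overall.

All five indices are invariant to cluster relabeling and to consistent
permutation of the matrix (tested), and all are validated against hand
computations on a four-point fixture.

## Polygenic scores

`PGS_i = Σ_j W_j G_ij` with dosages G ∈ {0,1,2} of the effect allele.
SNPs with negative GWAS weights are flipped (W ← −W, alleles swapped,
G ← 2 − G) so all effect sizes are positive; this shifts raw scores by a
constant and leaves standardized scores unchanged (tested to 1e-10).
Standardization is to mean 0, SD 1 **within the scored sample** — scores
restandardized in a restricted analytic sample will deviate slightly from
zero mean, which is expected. Fractional (imputed) dosages are accepted
with a warning; values outside [0,2] are rejected. LD structure, clumping
and summary-statistic QC are out of scope.

## Outcome models

Four likelihoods, written as model objects whose `fit()` returns a results
object (coefficients, SEs from the inverse observed information,
log-likelihood, McFadden and Cox–Snell pseudo-R², convergence diagnostics,
`summary()`/`tidy()` tables with two-sided Wald stars at 0.05/0.01/0.001):

* **Multinomial logit** for cluster membership, reference category
  *married in 20s and continuously married* (its coefficients fixed at 0).
* **Ordered logit** (proportional odds) for self-rated health coded 1 =
  poor … 5 = excellent: P(Y ≤ m|x) = logistic(κ_m − x′β); cutpoints are
  estimated directly (the ordered-logit log-likelihood is concave in
  (β, κ), so the fitted cutpoints are strictly increasing); odds ratios =
  exp(β). Empty outcome categories are collapsed with a warning.
* **NB2 negative binomial** for the CESD symptom count: mean μ = exp(x′β),
  variance μ + αμ², dispersion reported as lnα; incidence-rate ratios =
  exp(β). A fitted lnα below −12 is flagged as the Poisson boundary.
* **Logistic regression**, used for the IPW inclusion model.

Estimation is Newton–Raphson with backtracking line search (analytic
gradients everywhere; analytic Hessians for logistic/multinomial,
finite differences of the analytic gradient otherwise), falling back to
BFGS with Newton polishing; convergence is max|gradient| < 1e-6. These
tolerances are implementation choices. All families accept positive
analytic weights (integer weights reproduce duplicated-row fits exactly).
Quasi-separation — e.g. an all-zero count cell behind a dummy in a tiny
stratum — drives coefficients toward ±∞; such fits are returned with a
`separation_suspected` flag rather than silently or fatally. Analytic
gradients are verified against finite differences, and every family is
cross-checked against an independent reference implementation and
calibrated: 95% Wald intervals cover the generating parameters in 93–97%
of replications at n = 5000.

**Specification series.** For each health outcome and stratum (pooled,
men, women) five stages are fitted: clusters only; PGSs only; clusters +
PGSs; clusters + SES + controls; clusters + PGSs + SES + controls. SES =
own/mother's/father's years of education plus childhood financial situation
(poor [reference] / average / well off / varied-or-missing, the last
merging "don't know" and "it varied"). Controls = gender (pooled models
only), birth year, birth cohort grouped as before 1948 / 1948–1959 / 1960
or later, and the years between age 50 and the outcome's measurement. The
ten ancestry principal components enter every stage that contains PGSs
(whether they belong in PGS-free stages is ambiguous in practice; this is
the package default and a spec toggle). Missing data are handled by
listwise deletion; design columns that are constant within a stratum
(absent categories) are dropped with a warning.

**Interactions.** Gender×cluster and gender×cluster×PGS terms can be added
with all lower-order terms included; rank deficiency is detected by pivoted
QR and reported with the aliased column names. For three-way ordered-logit
models, predicted probabilities of each outcome category are emitted over a
PGS grid by gender and cluster with other covariates at sample means (each
row of probabilities sums to 1).

**IPW.** Inclusion in an analytic subsample is modeled by logistic
regression on birth year, birth cohort, and gender; included persons get
weight 1/p̂, winsorized at p̂ = 0.01 with a warning, normalized to mean 1.
The weights plug into any family as analytic weights. IPW corrects
selection on the modeled covariates only — not on covariates excluded from
the weight model.

## Synthetic cohorts and what the tests show

The generator draws, in order: covariates (gender 60% female; birth years
≈ N(1944, 10) truncated to 1914–1968; education ≈ N(13.8, 2.3) years;
parental education; childhood SES with shares 21.2/68.9/8.6/1.3%; ten PCs;
measurement-age offsets), genotypes (independent binomial(2, f_j), f_j ∈
[0.1, 0.9], signed weights) from which the educational-attainment PGS is
computed through the scoring pipeline (the other three PGSs are drawn
standard normal); latent class from a multinomial logit whose baseline
log-odds equal the configured class shares (5.7/5.5/3.7/36.0/44.2/4.8% for
never married / married-30s-widowed / married-divorced /
married-20s-continuous / married-by-20-continuous / married-remarried), so
zero coefficients reproduce the shares exactly; event ages from per-class
truncated normal timing laws (first marriage ≈ 18 for the by-20 class,
mid-20s for the 20s classes, early 30s for the widowed class; dissolutions
and remarriage gaps bounded inside ages 15–50); and outcomes from an
ordered logit (cutpoints −0.8/0.6/2.1/3.8) and an NB2 (lnα = 0.45, mean
symptom count ≈ 1) whose coefficient sign patterns follow the
substantively expected directions (e.g. education lowers early-marriage
odds, the well-being PGS raises self-rated health, the depression PGS
raises symptom counts) at magnitudes detectable at n = 5000. Every default
is configuration, serialized with the outputs, and the latent class, state
matrix and linear predictors are stored so any estimand can be computed
exactly.

Deliberate idealizations — what passing tests do **not** show about real
data: genotypes have no LD; the three non-EA PGSs are exogenous normals;
trajectory classes are well-separated truncated-normal archetypes, so the
near-perfect cluster recovery (ARI ≈ 1) is an upper bound, not a forecast
for survey data where cluster boundaries are genuinely fuzzy; simulated
symptom counts follow NB2 without the 0–8 truncation of the real
instrument; recall error, cohabitation, month-level timing and survey
design weights are absent. Interior missingness is injected into the
observed yearly states (never at age 15), which by construction is always
repairable by LOCF; real leading missingness forces exclusions.

## Problem sizes used in the checked runs

The test suite exercises the oracle equivalence on the complete set of
length ≤ 4 sequences over a 3-state alphabet under five random cost
schemes; metric properties on 80 random full-length sequences with 10⁴
random triples; cluster recovery on ten n = 1000 cohorts; and calibration
with 200 replications per family at n = 5000. `scripts/acceptance.py`
defaults to an n = 2000 cohort for the sequence/distance/cluster stages and
n = 5000 for regression recovery; both are package choices that can be
raised via command-line options.

## Known limitations

* Only legal marriage states are modeled; cohabitation and nonmarital
  partnerships are out of scope.
* Alternative sequence dissimilarities (Hamming, LCS, spell-based OM) are
  not implemented beyond the cost-scheme hooks.
* The Ward-variant and squared/raw-distance conventions materially affect
  R²/CH magnitudes; comparisons across software must fix the convention
  (both are exposed).
* SEs under analytic weights come from the weighted information matrix;
  no sandwich/robust covariance is provided.
* PGS computation reproduces the weighted-sum definition only; it makes no
  attempt to match any released score values, whose SNP-inclusion rules are
  proprietary to the release.
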