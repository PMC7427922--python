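# Methods

This note documents the statistical procedures, the conventions that pin
their behaviour, the synthetic-cohort generator, and the numerical choices
made where the analysis recipe left the design open.

## Cohort model

A cohort is a patients × variables grid of mixed numeric and categorical
values with missing entries, carried together with — but structurally
separate from — the binary progression outcome (HFpEF vs asymptomatic) and
two right-censored event times (years from diastolic-dysfunction diagnosis
to HFpEF and to death, with observation flags). Keeping outcome and
survival columns outside the variable grid makes it impossible for the
clustering stage to see them; the pipeline additionally asserts that no
encoded column's provenance is an outcome or event-time variable, and a
config that lists one among the clustering variables is a hard error.

## Preprocessing

**Outlier screen.** A patient is removed when any numeric variable lies at
least `z_threshold` (default 8) standard deviations from its column mean,
with mean and SD computed over the observed values *including the
candidate*. The screen runs before encoding, on numeric variables only,
and removes whole patients. Zero-dispersion columns are skipped with a
warning. The screen is idempotent at a fixed threshold.

**One-hot encoding.** Every L-level categorical variable becomes L
indicator columns (full encoding, not L−1). The redundancy is deliberate:
for squared-Euclidean distances, full encoding makes every categorical
disagreement contribute the same amount regardless of which level is the
"reference". A missing source value propagates missingness to all of its
indicator columns; observed rows satisfy Σ indicators = 1 exactly.

**SVD imputation.** Missing entries are completed by iterated truncated
SVD: start the missing entries at the observed column mean, then repeat
(rank-`rank` SVD of the filled matrix; overwrite missing entries with the
reconstruction) until the relative Frobenius change of the imputed entries
drops below `tol` or `max_iter` is reached. Defaults: rank 5, tol 1e-6,
max_iter 100. Non-convergence is flagged, not fatal — on the default
study-scale cohort some seeds stall slightly above 1e-6; the filled values
are still stable to ~1e-5 and the flag is surfaced in the run manifest.
Columns are scaled internally by their observed SD so indicator columns
and raw-scale biomarkers are comparable inside the SVD, but they are *not*
centered: centering would raise the rank of the raw matrix by one and
break the exact-completion property for exactly low-rank inputs (an
exactly rank-r matrix is completed exactly at rank r; this is tested).
Observed entries are returned bit-identical; the pre-imputation mask is
retained as provenance.

**Standardization.** Before distances, numeric-provenance columns are
scaled to mean 0, SD 1 (population convention, divisor n); indicator
columns are left at 0/1 (`numeric_only`, the default). Without this, a
biomarker measured in thousands would dominate every squared distance.
`all` and `none` policies are available; `none` reproduces a literal
unscaled analysis. Parameters are recorded so the transform inverts
exactly.

**Clinical grading rules.** Diastolic-dysfunction severity is graded from
the mitral E/A ratio and average e′ (cm/s): for e′ ≤ 9, severe when
E/A ≥ 2, moderate when 1 ≤ E/A < 2, mild when E/A < 1; for e′ > 9 the rule
does not apply and `indeterminate` is returned rather than guessing. CKD
stages follow half-open GFR intervals (mL/min/1.73 m²): ≥ 60 → stage 1–2,
[45, 60) → 3a, [30, 45) → 3b, [15, 30) → 4, < 15 → 5. The half-open
convention resolves the boundary overlap/gap that occurs when the interval
endpoints are quoted inclusively.

## Phenomapping

Pairwise dissimilarity is the squared Euclidean distance on the encoded,
imputed, scaled matrix. Agglomeration uses Lance–Williams updates applied
directly to the squared-distance matrix; with Ward's coefficients this is
exactly Ward's method (merge heights equal twice the increase in
within-cluster sum of squares), and complete/average/single linkage are
available. The implementation is a deliberate O(n³) loop with a
deterministic tie-break — exact distance ties merge the lexicographically
smallest pair of cluster indices — so runs are bit-reproducible; the test
suite checks the full merge sequence against an exhaustive reference that
recomputes inter-cluster distances from raw points, and cross-checks
partitions against scipy's linkage. For cohort sizes in the hundreds the
cubic cost is negligible.

Cutting the dendrogram at k undoes the last k−1 merges. Cluster labels are
renumbered by decreasing outcome frequency when outcomes are supplied
(cluster A = highest HFpEF frequency, matching the usual presentation) and
by decreasing size otherwise; ties break by size, then first appearance.

**Cluster-count selection.** Each cut in k = 2…5 is scored by a Pearson
chi-square (no continuity correction, df = k−1) on the k×2
cluster-by-outcome table, plus the purity
`(1/N) Σₖ nₖ` (nₖ = majority-outcome count in cluster k; purity is bounded
below by the overall majority fraction and is non-decreasing along nested
cuts). The selected k minimises the homogeneity p-value with ties going to
the smaller k. This operationalises what is in practice a partly
qualitative choice, so all candidate evaluations are returned and the
summary prints every cut — a user can override the selection.

A density-based alternative (DBSCAN on the squared-distance matrix, `eps`
on the squared scale, noise reported as unassigned) is provided for
comparison but is not on the default path.

## Comparative statistics

Two printed-convention details are pinned by worked examples in the test
suite because they silently change p-values:

- **Continuity correction**: Yates' correction (|O−E| shrunk by 0.5,
  clamped at zero) is applied to 2×2 tables only; r×c tables are never
  corrected. The `auto` default encodes exactly this.
- **No minimum expected count**: tables with expected cells below 5 (even
  below 1) are tested as-is with a warning, never refused.

One-way ANOVA is the classic F test; groups with fewer than two
observations are dropped with a warning. When ANOVA is significant at α
with ≥ 3 usable groups, both Newman–Keuls and Duncan stepwise
studentized-range procedures are reported side by side (which one is
"appropriate" is a judgement call; providing both avoids making it
silently). Both sort the group means, test ranges from widest span
inward with critical value q(α_span, span, df_within), use the harmonic
mean of group sizes for unbalanced data, and let a non-rejected range
block all inner comparisons (stepwise consistency). Newman–Keuls uses
α_span = α; Duncan uses the protection level 1−(1−α)^(span−1), so its
rejections are a superset of Newman–Keuls' (tested as a property).
Studentized-range quantiles come from `scipy.stats.studentized_range`
(numerical integration of the range distribution), spot-checked against
published q-tables. With two groups the procedures fall back to a pooled
t test with a warning.

Group comparison reports are complete-case per variable with per-cell n;
continuous cells are "mean ± 95% CI half-width (n)" with the half-width
t₀.₉₇₅,ₙ₋₁·SD/√n. **No multiple-testing adjustment is applied across
variables**; the report states this prominently.

## Risk modelling

Logistic models are fitted by iteratively reweighted least squares
(tol 1e-8 on the coefficient change, max 50 iterations; the log-likelihood
trace is recorded and tested non-decreasing; coefficients are cross-checked
against statsmodels). Rank-deficient designs are rejected naming the
aliased columns; |coefficient| > 15 raises a separation warning.

The clinical display convention
`P = 1/(1 + e^(a − Σ binary terms + Σ signed continuous terms))` is a
reparameterisation of the standard log-odds scale with a = −b₀; binary
history coefficients equal their standard slopes, continuous display
multipliers are the negated slopes. Both parameterisations agree to
machine precision (tested). Three published prediction equations ship as
evaluable fixtures, including the whole-cohort four-factor model whose
decision rule — ≥ 2 of {diabetes, CKD, atrial fibrillation, diuretic use}
implies P > 53% — is verified by enumerating all 16 covariate patterns.

**Predictor selection** mirrors the progressive procedure: (1) univariate
logistic screen keeps candidates with Wald p < α; (2) survivors enter in
order of univariate significance; (3) after each addition, an included
variable whose adjusted p exceeds α while correlating with the newcomer
beyond |r| = 0.5 (Pearson; for 0/1 columns this is the phi coefficient)
loses to the more significant of the pair; (4) a final backward prune
leaves only variables significant while adjusting for the others. The
collinearity threshold and α are configurable; the addition order and the
backward-prune mechanism are this package's operationalisation of a
procedure whose details are conventionally left unstated.

**Classification** predicts HFpEF iff P strictly exceeds the cutoff, which
defaults to the complete-case outcome prevalence. **Odds ratios** are
exp(coefficient magnitude) per binary factor and exp(standard slope) per
unit of a continuous term.

**Two-fold cross-validation**: within each outcome stratum patients are
ordered by identifier and dealt alternately into two folds, with the
alternation parity continuing across strata so the folds balance; the
model (variables fixed to the whole-cohort selection, as appropriate for a
small cohort) is refitted on each fold in turn and prevalence-cutoff
accuracy reported on both folds in both directions. On cohorts generated
from the fixture coefficients both discovery and validation accuracies
exceed chance, and validation does not beat discovery on average
(optimism, tested as a mean inequality over seeds).

## Survival trajectories

Kaplan–Meier estimation and log-rank tests are delegated to lifelines.
Conventions: at tied times events are processed before censorings; the
median is the first time S(t) ≤ 0.5 and is undefined when S never reaches
0.5; patients who never develop HFpEF are right-censored for the HFpEF
endpoints at their last-known-alive time; the HFpEF→death interval is
defined only for progressors; "age at" endpoints add the age at
diastolic-dysfunction diagnosis. The between-group test is the log-rank
chi-square (the usual choice where the comparison test is unnamed);
curves, medians, the overall test and all pairwise tests are reported per
cluster × stratum (all / gender / LV hypertrophy / outcome), with empty
strata reported as absent rather than erroring. Published median times are
data-specific and are not asserted; only hazard *orderings* are checked on
synthetic cohorts with planted per-cluster rates.

## Synthetic cohort generator

The generator is the package's test bed and demonstration data source. Its
default (`default_spec()`) emulates the scale and shape of a subclinical
diastolic-dysfunction study cohort:

- 162 patients in three latent phenogroups of 7/59/96. The 162nd patient
  carries four LVOT measurements planted 20 within-cluster SDs high (≈ 10
  pooled-cohort SDs, comfortably beyond the ≥ 8-SD screen even after the
  outlier inflates the pooled SD), so screening removes exactly one
  patient and leaves the 7/59/95 analysis population.
- 46 numeric variables (echocardiographic dimensions, volumes, gradients,
  vitals, labs) with per-cluster Gaussian means/SDs graded across clusters
  — the small group carries severe hypertrophy and aortic-stenosis-range
  gradients, the large group neither; the NT-proBNP-like biomarker is
  log-normal (location/scale on the log scale) with cluster medians from
  ~20,000 down to ~3,800 pg/mL.
- 19 categorical variables (gender, race, comorbidity and medication
  histories, two ordinal severity grades) drawn per-cluster multinomially.
- MCAR missingness per variable, heaviest on the biomarker (rate 0.556,
  leaving ~72 of 162 observed) and the volumetric/vascular measurements.
  MAR/MNAR mechanisms are out of scope.
- Outcome drawn Bernoulli from a logistic model on the pre-masking values
  (default: intercept −1.94 with log-odds 1.14/1.37/1.08/1.39 on diabetes,
  CKD, atrial fibrillation and diuretic use — prevalence lands near one
  half).
- Event times Weibull (shape 1 = exponential by default) with per-cluster
  rates; the default HFpEF rates give median progression times of roughly
  1.7/5.3/9.4 years across clusters. For progressors the HFpEF time is
  drawn truncated to the 15-year administrative horizon (so outcome = 1
  exactly when the event is observed) and death follows the HFpEF event by
  an independent draw; non-progressors are censored at the horizon.

Everything is deterministic given the seed (bit-identical regeneration is
tested, as is byte-identical reproduction of all pipeline artifacts).

**What the generator does not emulate** — and hence what passing tests do
not show about real data: within-cluster variables are independent (real
echocardiographic measurements are strongly cross-correlated beyond what
cluster membership induces), missingness is MCAR (clinical missingness is
usually informative), the outcome model is exactly logistic in four binary
factors, and event times are exactly Weibull. The mixture across clusters
does induce realistic marginal correlations between comorbidities, but a
prospective logistic cohort still cannot reproduce classification
operating points that arise from a matched case-control design; the
classification-regime test therefore draws covariates per outcome arm at
the published group-specific comorbidity rates.

## Numerical and design choices

- Linkage default Ward (customary in clinical phenomapping); all four
  linkages exposed. Merge tie-break lexicographic for reproducibility.
- SVD imputation defaults (rank 5, tol 1e-6, max_iter 100) and the
  scale-only internal normalisation are this package's choices; none are
  dictated by the analysis recipe.
- The k-selection rule (minimum homogeneity p, ties to smaller k) is an
  operationalisation; all evaluations are reported for override.
- Wald tests for per-coefficient significance; collinearity threshold
  |r| > 0.5, both configurable.
- Diastolic wall strain, when not supplied, is derived as
  (LVPWs − LVPWd)/LVPWs from the posterior-wall measurements (its standard
  definition).
- The prevalence cutoff is strict ("greater than"), so a patient exactly
  at the cutoff is predicted asymptomatic.
- Problem sizes in the test suite (e.g. coefficient recovery at n = 5000,
  selection benchmarks at n ≈ 160 with 200 replicates, Monte-Carlo
  family-wise error at 2000 replicates) were chosen to make sampling error
  small relative to the asserted tolerances while keeping the whole suite
  fast on a single CPU.

## Limitations

- No consensus clustering, gap statistic or silhouette-based selection; no
  Cox regression or competing risks; no penalized regression or ROC-based
  cutoff optimisation; no nonparametric ANOVA alternatives. These are
  deliberate scope boundaries, not oversights.
- The per-cluster risk models inherit all small-sample caveats of logistic
  regression; on a 7-patient cluster nothing is estimable, and the
  pipeline skips clusters with fewer than 20 patients or a single outcome
  class.
- Purity and the homogeneity test use the outcome only for *evaluation*
  of an unsupervised clustering; they do not make the clustering
  supervised, but they do mean the reported k is outcome-aware.
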