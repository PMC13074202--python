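# Methods

This note documents the models and procedures implemented in `htncds`,
the calibration of its synthetic cohort, the numerical conventions, and
the design choices made where the design was genuinely open.

## Problem setting

The package targets non-pharmacological management of arterial
hypertension in primary care. Input is a flat cohort table — one row per
patient, mixed numeric/categorical/multi-select variables, missing cells —
and output is, per patient, one intervention level in each of six
lifestyle domains (physical activity, stress management, nutrition, sleep,
therapeutic adherence, general health behaviors), plus cohort-level
distribution matrices and agreement statistics against expert raters.

The system is deliberately hybrid: unsupervised stratification discovers
latent cardiometabolic phenotypes, and a declarative rule base turns
individual values *and* phenotype context into auditable recommendations.
Nothing is learned end-to-end; every decision is traceable to fired rules
and cluster descriptors.

## Preprocessing

Stages run in a fixed order; each emits a structured report.

1. **Record filter.** A row is removed when its missing fraction strictly
   exceeds 0.5 ("more than 50 %"): a row missing exactly half its cells is
   kept. Strictness matters at the boundary (26/52 kept, 27/52 dropped).
2. **Unit repair.** Heights below 3.0 are interpreted as meters and
   multiplied by 100. No adult height is ambiguous across that cutoff in
   either unit. Repair precedes imputation so KNN distances are not
   distorted by two-orders-of-magnitude outliers.
3. **Plausibility flags.** Values outside each variable's declared
   clinical range are flagged with row/column addresses but never deleted
   (correction-over-deletion policy).
4. **Numeric KNN imputation.** A missing cell is replaced by the
   unweighted mean of that variable over the k nearest rows, with
   Euclidean distance on z-scaled, mutually observed numeric coordinates
   rescaled by √(total/observed) — the standard partial-distance
   convention (scikit-learn's `nan_euclidean` + `KNNImputer`, applied to
   pre-scaled values). Rows missing the target variable never donate.
   Default k = round(√n) (25 at n = 615). Observed cells are never
   altered (asserted, not assumed). A median-substitution imputer is kept
   as the sensitivity comparator; on the default cohort swapping it in
   changes fewer than 10 % of downstream cluster assignments.
5. **Categorical mode imputation**, ties broken by schema category order
   and logged. **Checklist zero-fill**: a blank multi-select entry means
   "nothing selected", so the mask is cleared and the cell becomes an
   empty selection rather than an imputed guess.
6. **Standardization and encoding.** Z-scores use the population (n)
   denominator — the transform is a rescaling, not a variance estimator;
   either convention is defensible, one had to be fixed. Constant columns
   map to zeros with a warning. One-hot encoding emits one indicator per
   declared (variable, category) pair, so the encoded width is
   reproducible from the schema alone.

## Stratification

PCA is fit on the 15 standardized clustering features (age, weight,
height, systolic/diastolic pressure, sleep, activity frequency, smoking,
screen time, hemoglobin, glucose, cholesterol, triglycerides, creatinine,
eGFR). Components are retained up to cumulative explained variance ≥ τ
(default 0.90; the boundary is inclusive, so ratios 0.9/0.1 retain one
component). Sign convention: each component's largest-magnitude loading is
positive, making the decomposition deterministic.

Candidate partitions come from a grid: k-means (k-means++ initialization,
10 restarts, best inertia), Ward-linkage agglomerative clustering, and
full-covariance Gaussian mixtures (labels by maximum responsibility), for
k = 3..6 (the wider k ≤ 10 range is a config option). Every cell is scored
with three internal validity indices implemented from their definitions
(library implementations are used only as independent cross-checks in the
tests):

- **Silhouette.** a(i) excludes the point itself; singletons score 0;
  a = 0 with b > 0 scores 1; a = b = 0 scores 0.
- **Davies–Bouldin.** Cluster dispersion is the mean member-to-centroid
  distance; coincident centroids propagate +∞ with a warning.
- **Calinski–Harabasz.** Standard (k−1, n−k) degree-of-freedom
  normalization of the between/within scatter traces; zero within-scatter
  propagates +∞.

Selection is lexicographic — maximize silhouette, tie-break (at 1e−12) by
CH, then by minimal DB. The indices are conceptually weighed jointly, but
a deterministic total order is required for reproducibility; silhouette
leads because it is the only one of the three with a scale-free range.
Stability is assessed by re-fitting under multiple seeds and reporting
pairwise adjusted Rand indices.

Profiling computes per-cluster means/SDs and category frequencies,
ranks clustering variables by one-way ANOVA F statistic, and names
clusters by matching centroid z-deviation signatures (glucose-elevated →
"metabolic-hypertensive"; cholesterol-elevated with low hemoglobin →
"dyslipidemic-anemic"; tall-stature → "constitutional-atypical") via
one-to-one assignment.

## Rule base and dual-weighted inference

Rules are pure conjunctions of atomic predicates (`<, ≤, >, ≥, =,
set-membership, checklist-contains`) mapping to one intervention level of
the rule's domain; alternation is expressed as multiple rules, keeping
traces legible. Every domain declares a fallback level, so the engine is
total. All thresholds live in the YAML rule file. The shipped defaults
anchor on common clinical guidance — blood-pressure control target
<130/80 mmHg, severe elevation ≥160/≥100 for urgent stress intervention,
WHO impaired-fasting-glucose 110 mg/dL, total cholesterol 200 mg/dL,
triglycerides 150 mg/dL, BMI bands 18.5/25, sleep 7–9 h, activity bands
0 / 1–2 / ≥3 days per week — and are explicitly local-calibration
defaults, not a validated clinical rule set. The glucose cutpoint uses
the WHO convention (110) rather than the ADA one (100) so that dietary
recommendations differentiate the glucose-elevated profile (whose mean
sits at the cutpoint) from near-universal firing.

Scoring: each satisfied rule adds its weight to its target level;
per-domain scores are normalized to sum to 1 (a config switch disables
normalization); if nothing fires the fallback holds score 1. The engine
evaluates twice — on the patient's values (individual) and on a *virtual
patient* assembled from the cluster centroid means and modal categories
(context) — and combines convexly, `α·individual + β·cluster`, α = 0.85,
β = 0.15. The chosen level is the argmax; exact ties break toward the
clinically more urgent level, then alphabetically. Limits behave as
required: α = 1 is a rules-only system, β = 1 makes recommendations
constant within clusters, and within-cluster homogeneity is weakly
increasing in β. A β-sweep report quantifies robustness as the fraction
of (patient, domain) decisions that flip between consecutive β values.

The convex combination of normalized score vectors is itself a design
choice: the dual α/β weighting admits several mechanizations, and this is
the simplest one consistent with both limiting behaviors.

## Expert-agreement validation

Cases are sampled proportionally to cluster sizes by largest-remainder
rounding (sizes 352/264/7 at n = 120 allocate 68/51/1), uniformly without
replacement within strata. Panels are 5 raters; consensus is simple
majority (≥ 3), falling back to plurality, with full plurality ties broken
toward the more urgent level and flagged. A simulated panel (each rater
echoes the system's label with probability p, else a uniform other level)
provides a calibration oracle: at p = 0.8 the binomial majority recovers
the truth with probability ≈ 0.942.

Statistics per domain and pooled: percent agreement (per-level breakdown
divides matches by the *system's* count for that level); unweighted
Cohen's κ with the asymptotic 95 % interval (statsmodels' variance);
Pearson chi-square homogeneity on the 2 × L source-by-level table with
df = L − 1, no continuity correction, restricted to levels present in
either distribution. The pooled κ treats (domain, level) pairs as distinct
categories of a block-diagonal confusion table; κ is reported as undefined
(flagged, not raised) when both marginal distributions are constant and
equal.

## Synthetic cohort calibration

The generator emulates the study conditions end to end: 623 records, 52
variables (one identifier, 19 numeric of which 15 are clustering features,
28 categorical, 4 checklists), three planted profiles of sizes 352, 264
and 7. Reported per-profile means are set verbatim (e.g. glucose
110.24 / 93.40 / 111.03 mg/dL; cholesterol 191.72 / 214.85; hemoglobin
14.08 / 12.67 / 14.70; height 181 cm for the atypical profile). Reported
*qualitative* contrasts receive documented values: shorter sleep 5.8 h and
lower smoking (1 cigarette/day mean, 15 % current smokers) for the
dyslipidemic profile against a 6.4 h / 2 cig/day / 35 % baseline, and
prolonged sleep 9.5 h for the atypical profile. All genuinely unreported
means are shared across profiles (height baseline 155 cm for a
female-majority short-stature cohort; BMI 24; screen time 4 h; ...), so
cluster separation arises only from reported features. Noise is Gaussian,
SD = 5 % of each profile mean, independent across variables.

Corruption is missingness plus unit errors. Masking is MCAR per cell but
**differential by kind**: numeric cells at 3.5 % and categorical/checklist
cells at the rate (≈ 47 %) that brings the overall fraction to the 30 %
target. The differential split follows the study's own accounting — only
~416 numeric cells were imputed although ~8,800 cells were missing
overall, i.e. real missingness concentrated in questionnaire and checklist
items, not in laboratory values. This matters mechanically: uniform 30 %
masking of the clustering features lets k = 25 KNN imputation fill the
7-patient cluster's cells from majority-cluster donors, collapsing its
separation and making recovery seed-unstable. Under the differential
default the preprocessing report shows ~380–450 imputed numeric cells.
Uniform masking remains available (`numeric_missing_rate=None`) for
sensitivity work. Unit errors pick exactly round(314/623 · n) *observed*
height cells and divide them by 100; sampling among observed cells keeps
the planted count identifiable after masking.

What the generator does **not** emulate: variables are independent within
profile, so physiological couplings (BMI with weight and height, hemogram
internal consistency, renal markers) do not hold across columns — BMI is
its own marginal and can disagree with weight/height²; categorical
distributions except smoking are identical across profiles; missingness
has no informative mechanism. Passing tests therefore demonstrate the
pipeline's correctness and its behavior under the calibrated separations,
not performance on real clinical data, where correlated noise, informative
missingness and non-Gaussian tails all make stratification harder.

## The recovery experiment and the role of model selection

The headline check (`scripts/acceptance.py`, `tests/test_acceptance.py`)
generates the default cohort, runs the full pipeline, matches recovered
clusters to planted profiles by minimal standardized centroid distance,
and requires matched glucose/cholesterol/age centroids within 2 % and the
two dominant cluster sizes within ±5 members on at least 8 of 10 seeds.

A finding worth recording: plain k-means with k = 3 cannot perform this
recovery, regardless of restarts. With a 7-point cluster at the calibrated
separation, splitting the 352-point cluster costs k-means *less* inertia
than isolating the atypical group, and k-means++ essentially never seeds
it — the planted partition is not the k-means optimum and not reachable
from its initializations. Ward linkage, by contrast, recovers it exactly,
and the lexicographic validity selection over the full grid picks Ward at
k = 3 decisively (silhouette ≈ 0.31 vs ≈ 0.24 for the next cell on clean
numerics). The pipeline therefore reports whatever the grid selects; on
the default cohort that is HAC k = 3, occasionally k-means k = 3 when an
initialization lands on the planted optimum. This is a genuine property of
small-cluster recovery, not an implementation artifact, and is the reason
the acceptance experiment is defined over the *selected* model rather than
a fixed algorithm.

## Numerical conventions and degenerate inputs

- Tie tolerances: 1e−12 for selection and argmax ties; mask/report counts
  are exact integers.
- Silhouette singletons → 0; coincident centroids → DB +∞ (warned); zero
  within-scatter → CH +∞ (warned); single-cluster partitions raise.
- Mode ties → schema order; plurality ties → urgency; argmax ties →
  urgency then alphabetical. All deterministic, all logged where they
  occur.
- Every stage seed derives from one global seed via SHA-256, keeping seeds
  below 2³¹ and reruns byte-identical.

## Problem sizes

Default experiments run at the study scale (623 × 52, grid of 12 cluster
fits, 120 validation cases, 10 stability seeds); the full test suite and
the acceptance script each complete in well under a minute on one CPU, so
no down-scaling was needed.

## Known limitations

- The shipped rule thresholds are structural defaults, not the original
  clinical system's calibrated values, which are not public; agreement
  statistics on simulated panels validate the statistical machinery, not
  clinical quality.
- The generator's independence assumptions (above) bound what recovery
  results say about real data.
- The 7-patient profile is at the edge of identifiability by design; with
  uniform heavy missingness on numerics it is not recoverable by any of
  the three algorithms, and results for such micro-clusters should always
  be read alongside the stability report.
- Pooled κ across domains depends on the pooling convention (block
  confusion across (domain, level) categories here); alternative poolings
  give different overall values.
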