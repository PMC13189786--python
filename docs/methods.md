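# Methods

## Scope and model

`sonopattern` analyzes cohorts of breast-cancer patients described by J = 23
categorical ultrasound features, clinical covariates, and a rare binary
outcome (pathological non-response to neoadjuvant chemotherapy). The central
model is a latent class analysis (LCA): conditional on a latent pattern
c ∈ {1..C} with mixing proportions π, features are independent with
item-response probabilities ρ_jck (the local-independence assumption). The
selected pattern labels then enter a Firth-penalized logistic regression for
the outcome. Nothing in the package touches images; features arrive already
coded against a data dictionary.

## Synthetic cohorts

The generator is the package's substitute for the original (non-public)
patient data and defines the conditions every statistical claim is tested
under:

- N = 509 patients; two classes at π = (0.505, 0.495).
- 18 binary + 5 three-level features, i.e. Σ_j (K_j − 1) = 28 free category
  parameters per class. The 18/5 split is forced by the published
  fit-index arithmetic (the BIC−AIC gaps are consistent only with 28); which
  *specific* features are three-level is not recoverable and the default
  assignment (echo pattern, vascularity, size, echotexture, resistance
  index) is an explicit, documented choice.
- Eight binary features carry the published class profiles (irregular shape
  1.00, blurred edges 0.96, lateral shadowing 0.76/0.07, posterior
  attenuation 0.49/0.07, angular margins 0.94/0.55, spiculated margins
  0.73/0.58, micro-lobulation 0.95/0.39, fat-layer invasion 0.84/0.30); the
  unanchored features get moderate separations (0.05–0.25) chosen once for
  plausibility.
- Covariates: age ~ Normal(50, 10) truncated to the 18–80 inclusion window,
  BMI ~ Normal(23, 3) kg/m², binary covariates with typical prevalences
  (e.g. family history 12%, childbirth history 85%), regimen uniform over
  taxane/anthracycline/combined. The covariate log-odds effects are signed
  so that the literature-defined high-risk stratum (age ≥ 50, BMI ≥ 24,
  family history, no childbirth history) carries a higher baseline risk;
  magnitudes are modest (|β| ≤ 0.8, age 0.04/yr, BMI 0.08/unit).
- Outcome: logistic in the pattern-B indicator (log OR = ln 2.5 by default)
  plus covariates. The intercept is solved numerically (Brent's method on a
  fixed 200,000-draw Monte-Carlo average) so the marginal non-response rate
  is 4.32%; the calibration draw is internally seeded, making the intercept
  a deterministic function of the configuration.
- 48/509 cases are tagged Miller–Payne-assessed; exactly 2 non-responders
  are planted among them, mirroring the sensitivity-analysis composition.
  `exact_n_events` optionally fixes the total event count (22 at N = 509) by
  weighted sampling without replacement proportional to each patient's model
  probability.

What the generator does *not* emulate: inter-rater disagreement, missing
data, residual feature dependence within class, covariate–feature
correlation (e.g. age with menopausal status), and site effects. Passing
tests therefore demonstrate correctness of the machinery under the stated
generating model, not clinical validity on real cohorts.

## Feature screening (MCA)

Indicator-matrix correspondence analysis: one-hot table Z, standardized
residuals S = D_r^{−1/2}(P − rcᵀ)D_c^{−1/2}, SVD. Principal inertias are the
squared singular values; total inertia is (Σ_j K_j)/J − 1 (= 28/23 here). A
variable's contribution to a dimension is the sum of its categories'
squared right-singular-vector loadings (per-dimension contributions sum to
100%). The screen retains a variable whose contribution exceeds 2% in *at
least one* of the first five dimensions — the only reading under which a
2% screen can retain all 23 variables — with a `require_all_dims` toggle for
the stricter reading, a manual `force_keep` override standing in for expert
review, and an optional Benzécri correction affecting explained percentages
only.

## Latent class engine

EM on the one-hot representation, duplicate response patterns collapsed
with multiplicity weights. Defaults: 50 random starts (π and each ρ block
~ Dirichlet(1)), relative log-likelihood tolerance 1e-8, at most 5,000
iterations; a 1e-10 floor on ρ inside EM prevents log(0) lock-in, and
boundary estimates are reported as exact 0/1 after convergence with the
log-likelihood and posteriors recomputed at the reported parameters. The
one-class model uses the closed-form MLE. Parameter count
p = (C−1) + Σ_j C(K_j−1); criteria: AIC = −2LL + 2p, BIC = −2LL + p ln N,
aBIC = −2LL + p ln((N+2)/24). Relative entropy
E = 1 − Σ_i Σ_c (−p_ic ln p_ic)/(N ln C) is reported for C ≥ 2 and undefined
("/") for C = 1.

Class enumeration: the BLRT simulates B datasets from the fitted
(C−1)-class model, refits both models to each with the same settings as the
observed-data statistic, and reports p = (1 + #{bootstrap ≥ observed})/(B+1);
near-zero statistics (within 1e-8) are treated as exact zeros so a saturated
null gives p = 1. The adjusted LMR test is implemented as the ad-hoc
corrected statistic LR/(1 + ((Δp)·ln N)^{-1}) referred to χ²(Δp); this is an
acknowledged approximation of the adjusted LMR procedure (the exact null is
a weighted chi-square mixture), is conservative for enumeration, and the
BLRT is the authoritative test wherever the two disagree. Two-class
solutions are named so that "Pattern A" is the class with the higher
angular-margin prevalence, giving stable A/B semantics across seeds.

## Distance-based comparators

K-modes minimizes total simple-matching distance to cluster modes (default
20 initializations from distinct rows; assignment ties to the lowest cluster
index, mode ties to the lowest category code, empty clusters re-seeded with
the point farthest from its mode). Gower dissimilarity for all-categorical
data is the mismatch fraction. Hierarchical clustering uses scipy's
agglomerative linkage (average by default — the common companion to Gower —
with the linkage method exposed). Silhouettes come from scikit-learn on the
precomputed dissimilarity, singletons scoring 0.

## Model selection

Candidates are screened in order: (i) LCA candidates need significant LMRT
and BLRT versus C−1 (α = 0.05) and entropy > 0.7; a criterion whose
statistic was not computed is not applied; (ii) any candidate with a class
share below 2% of N is rejected as degenerate; (iii) distance-based
candidates need silhouette ≥ 0.30 (a standard "weak structure" floor — the
published analysis rejected 0.14/0.26 without naming a cutoff, so the value
is configurable and logged); (iv) among survivors, candidates with
significant external validity (Pearson chi-square of labels × outcome,
df = groups − 1) are preferred, ties broken by lowest BIC, then fewer
classes. Every candidate appears in the audit trail with machine-readable
rejection reasons; an empty survivor set is an explicit "no admissible
solution" outcome. Clinical interpretability is inherently manual and is
represented only by the config override list.

## Firth regression

Newton iterations on the modified score U*_r = Σ_i (y_i − p_i +
h_i(½ − p_i)) x_ir with hat values from the penalized weights, step-halving
on any decrease of the penalized log-likelihood, convergence at max
|U*| < 1e-6 or 200 iterations; covariance is the inverse penalized
information. Coding: age and BMI continuous, binaries 0/1, chemotherapy
regimen a single ordinal 0/1/2 column — one odds ratio per variable, as the
published table reports; Wald CIs by default with penalized-likelihood
profile CIs available (`profile_ci`). Rank-deficient designs raise with the
aliased columns named. VIFs are computed by least squares per column
(1/(1−R²)), with exact collinearity reported as infinite.

## Resampling validation

The rare-event-preserving bootstrap keeps every non-responder in every
replicate and draws responders with replacement to their original count
(replicate size = N); each replicate's draw is reproducible from
(seed, replicate index); replicates whose Firth fit fails are dropped and
counted. The summary mirrors the published bookkeeping: a replicate is
"significant" when the pattern term has p < 0.05, per-variable "%
significant" is computed among those significant replicates, and the mean
(β/SE)² column is reported as this package's definition of the average Wald
statistic (the published column's definition is not reproducible). Two
interval summaries are carried per term: the mean of the per-replicate Wald
CI bounds — the reading matching the published "OR (95% CI)(mean)" layout,
and the one used for stability comparisons — and the 2.5/97.5 percentile
interval of the replicate ORs, which is markedly narrower because the
resampling scheme holds the events fixed.
Cross-validation stratifies folds by outcome — with 22 events over 10 folds
unstratified splits risk event-free training sets — and reports the pattern
term's OR/CI/p per fold.

## Subgroup risk differences

The estimand is a model-based standardization: predicted non-response risk
at a profile-representative covariate vector (age/BMI at subgroup-conditional
cohort medians, profile binaries set directly, remaining covariates at cohort
modes/medians) with the pattern set to B minus the same with pattern A, in
percentage points. Under a common odds ratio this grows with baseline risk —
closed form: baseline 20% at OR 2.5 gives +18.46 points, baseline 1% gives
+1.46 — which is the entire mechanism separating high-risk from
non-high-risk subgroups; no interaction terms are fitted. Uncertainty comes
from refitting the model on rare-event-preserving replicates (percentile
2.5/97.5 CIs). An empirical g-computation mode (averaging predictions over
actual subgroup members) is available as a config switch.

## Pipeline and sensitivity rerun

`run_pipeline` executes load → QC → MCA screen → LCA for C ∈ {1..5} plus
K-modes/hierarchical for k ∈ {2..5} → selection → pattern naming → VIF +
Firth → CV + bootstrap → risk-difference table, with every stage's seed
derived by stable hashing of (master seed, stage name) so toggling one stage
leaves the others' streams untouched; fixed-seed reruns are byte-identical
and the report validates against the shipped JSON schema. Disabled stages
emit explicit `{"skipped": true}` markers. The sensitivity rerun restricts
to RCB-assessed cases (dropping the 48 MP cases with their 2 events,
N = 461 with 20 events under the default generator), re-clusters at the
selected class count, repeats the regression and validation stages, and
reports the maximum class-profile probability shift against the main run; a
cohort with no MP cases yields a flagged no-op.

## Problem sizes used in the test suite

Simulation-backed tests run at deliberately chosen scales: BLRT type-I
calibration uses 100 replicate experiments of B = 99 on one-class data
(N = 200, six binary features) with 2 EM starts per fit — valid because the
observed and bootstrap statistics are computed by the identical procedure;
bootstrap contracts at B = 500 and coverage/monotonicity spot-checks at
B = 100–200; sensitivity robustness across 10 generator seeds at B = 200;
null-effect and OR-recovery simulations at 40–50 cohorts. The `fast`
pipeline configuration (10 starts, BLRT B = 39, bootstrap B = 500, risk
differences B = 200) exists for the same reason and is reported as such in
run metadata.

## Known limitations

- The LMR test is approximate (see above); enumeration decisions should
  lean on the BLRT, as the selection rule does when both are present.
- Wald CIs can be optimistic at ~20 events; profile-penalized-likelihood
  intervals are provided but not the default, matching the reporting style
  the package emulates.
- The rare-event-preserving bootstrap conditions on the observed events, so
  its CIs understate variability attributable to the events themselves;
  perturbations that remove events (as the sensitivity rerun does) can fall
  outside them in a minority of seeds.
- Silhouette and share floors in the selection rule are conventions, not
  estimated quantities; both are config-exposed and logged.
- The generator's conditional-independence structure matches the LCA model;
  real ultrasound features are likely residually dependent within class, and
  entropy/recovery results on synthetic data are accordingly optimistic.
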