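# Methods

This note records the modelling assumptions, parameter choices and known
limitations behind `strokerisk`. Everything quantitative stated here is
computed by the test suite or the acceptance script at run time.

## Synthetic cohorts: what they emulate and what they do not

The generator stands in for three kinds of clinical sources: ICU-style
laboratory/vital panels, a public imbalanced stroke registry, and small
nursing-home samples. It reproduces their *structure* — feature families,
value ranges, severe class imbalance rebalanced to fixed counts — not their
joint distributions.

* **Negatives** (physiological family) are uniform inside standard adult
  reference intervals. The intervals ship as a versioned table
  (`schema.DEFAULT_REFERENCE_RANGES`; e.g. SpO₂ 95–100%, systolic BP
  90–120 mmHg, fasting glucose 3.9–6.1 mmol/L) and are fully overridable.
  Uniformity is the least-informative choice given only interval bounds.
* **Positives** are truncated normals per indicator, mean displaced from
  the interval midpoint by a shift expressed in pooled-SD units
  (SD = interval width/√12, matching the uniform negatives). Defaults:
  +1.5 SD on glucose, systolic/diastolic BP, cholesterol, LDL,
  triglycerides; −1.0 SD on HDL and SpO₂. Truncation bounds are the
  plausibility intervals (3× the reference width). A configurable minimum
  fraction of positive rows (default 0.3) is guaranteed to carry at least
  one out-of-range value; under the default shifts the natural rate is
  already higher.
* **Pathogenic factors** use Bernoulli flags and categorical frequency
  tables with elevated prevalence among positives, plus shifted age,
  glucose and BMI. The frequencies are fixed, configurable constants
  chosen to resemble published registry marginals.
* **Rebalancing** expands registry-scale positive counts (836
  physiological / 783 pathogenic source rows) to 5,000 against 6,000
  generated negatives per family — an imbalance rate of
  100·neg/pos = 120%. The pathogenic negatives are generated directly at
  the target count rather than generating the full registry-scale pool and
  subsampling; for i.i.d. draws the two are distributionally identical.

What passing tests on these cohorts show: the pipeline's mechanics
(balancing, preprocessing, training, thresholding, fusion) behave as
specified under controlled distribution shift. What they do not show:
performance on real clinical data, whose correlations, measurement error
and missingness mechanisms the generator does not model (missingness is
injected MCAR only).

## Fuzzy-cluster-guided SMOTE

The cited oversampling family combines fuzzy c-means with SMOTE; its exact
internals are not public in a form we could adopt, so the implementation is
a documented approximation: standardise the minority block, run plain FCM
(3 clusters, fuzzifier 2.0), hard-assign by maximal membership, and
interpolate each base row with one of its k = 5 nearest within-cluster
neighbours using u ~ U(0,1). Boolean/categorical coordinates take the
nearer parent's value (u < 0.5 keeps the base row), which preserves
coordinate-wise betweenness. Original rows are kept verbatim; an
all-identical minority degenerates to duplication with a warning.

## Preprocessing

Order: interval trimming → chained-equation imputation → Boolean/
categorical filling → ordinal encoding → z-scoring.

* Plausibility intervals default to 3× the reference width (same centre);
  columns without a reference range fall back to median ± 5·IQR. Zeros in
  continuous vitals/labs are treated as instrument placeholders and marked
  missing.
* MICE uses ridge-regularised chained equations (scikit-learn's iterative
  imputer with a Ridge estimator), 10 iterations, seeded, clipped to the
  plausibility interval. An all-missing column falls back to the
  label-stratified median (stratum = outcome label) with a warning.
* Missing Boolean flags default to 0 where zero means "factor absent";
  missing categoricals become an explicit `Unknown` level. Ordinal codes
  are lexicographic; unseen categories at transform time map to a dedicated
  Unknown code with a warning.
* Z-scoring fits on training rows only; a zero-variance column maps to
  all-zeros (the information-free choice).
* At predict time the fitted chain is applied without refitting; continuous
  gaps in new rows are filled with stored training medians rather than
  re-running MICE, so predictions are a pure function of the artifacts.
* Longitudinal alignment is reduced to a per-subject median collapse
  utility; no event-time modelling.

## Focal boosting and the decision threshold

The focal loss uses the standard two-class form with γ = 2, α = 0.25 (the
detection-literature defaults; the method only names the loss). Gradient
and Hessian with respect to the raw score are analytic; because the focal
loss is genuinely non-convex in the raw score, the Hessian is floored at
1e−12 — the floor, not the signed value, is what the boosting library
receives. Probabilities are clipped at 1e−12.

The decision threshold τ = 0.327 is a configuration default with a sweep
utility over {0.2, 0.3, 0.327, 0.4, 0.5}; re-deriving its optimality on the
original clinical data is out of scope. The boundary is inclusive: p = τ
maps to the positive class.

Feature reweighting: per-feature mean |TreeSHAP| (LightGBM's exact
`pred_contrib`, which satisfies local accuracy to machine precision) is
normalised to mean 1 and blended with damping η = 0.3,
w ← (1−η)w + η·ĉ; with constant contributions the weights converge to ĉ
geometrically at rate (1−η). Weights multiply standardised feature
columns. Two consequences worth recording: tree models are invariant to
positive per-column rescaling (bin edges rescale with the data), so the
loop provably cannot degrade the boosting head — this is asserted as a
regression test; and the attention head consumes the weighted numeric
stream by default (a pipeline option), where the sign-based Lion update
makes the effect mild.

Grid search: the full 8-axis product would be 576 points; the default
*active* grid varies num_leaves {32,64,128} × learning_rate {0.05,0.1} ×
feature_fraction {0.8,1.0} × λ₁ {0,0.1} × λ₂ {0,0.1} = 48, holding
max_depth = 6, min_gain_to_split = 0, max_bin = 255 fixed (all
configurable). Selection keeps the fastest quartile by fit time — the
pipeline targets real-time screening — then maximises mean validation AUC,
breaking ties toward smaller num_leaves then smaller learning_rate.

## Attention classifier

Layer counting convention: each attention map and each linear map counts
as one trainable layer — embed (1) + 4 self blocks × (attention + 2 FFN
linears) (12) + cross block (3) + head (3) = 19. The convention reproduces
the architecture's printed totals and scales linearly in the block count.

Defaults: embed_dim 32 (16 in the desk-scale demo), 4 heads, FFN inner
width 4×embed_dim, GELU (exact erf form), Dropout 0.1, DropPath 0.2
applied per sample to every residual branch with survival scaling
1/(1−p) at train time only. Pre-LN placement normalises inside the
residual branch. The cross-attention direction is numeric-queries-over-
categorical-context, and tokens are mean-pooled before the head; both are
configurable since the design here was genuinely open. With no categorical
columns the token path is empty and the model runs on the numeric stream
alone (cross-attention passes through with a warning).

The engine is a purpose-built reverse-mode autodiff over NumPy arrays
(broadcast-aware elementwise ops, batched matmul, reductions, gather,
concat); every composite, including LayerNorm, softmax and the full
model, is gradient-checked against central finite differences (tolerance
1e−7 in the op tests, observed error ~1e−10 through the full network).

Training: cross-entropy, Lion with β₁ = 0.9, β₂ = 0.99, weight decay 0.01
(the published defaults) and momentum refreshed after the parameter step;
default lr 1e−3 for the desk-scale runs — the sign-based update at larger
rates (≥3e−3) visibly destabilises the regularised 19-layer stack on
small cohorts. One integer seed controls initialisation, batch order and
drop masks. Divergent (non-finite) loss aborts with a diagnostic. The
stopping rule checks all six validation metrics each epoch against the
preset thresholds; if they are never met, the epoch budget bounds the run,
and the best-validation-AUC checkpoint is restored either way.

## Spider-wasp optimizer

The five-phase population loop is the contract; beyond it, choices were:
role assignment by fitness rank (worst 70% search, best 30% follow,
ties by agent index); follow step pos ← pos + r(best − pos) with scalar
r ~ U(0,1), which never increases distance to the best; search steps
uniform in ±0.25× the per-dimension range (the phase only asks for "large"
steps; 0.25 balanced exploration against convergence on the sphere/
Rosenbrock development benchmark); Cauchy elite perturbation of a single
random dimension at scale 1% of the range; fitness-proportional parent
selection with weights (worst − f + ε); per-dimension inheritance with
probability 0.5; differential mutation x + 0.5(a − b) applied to
max(1, 10% of the population) offspring — at the initially tried 5% the
mutation pressure was too weak to track curved valleys; elitism re-inserts
the best-ever agent after culling, which also guarantees the monotone
best-ever trace. Termination: best-ever unchanged within 1e−8 for 10
generations, or the generation budget. Non-finite objective values are
assigned worst fitness with a warning.

Exposed attention hyperparameters for the search: log₁₀ learning rate,
dropout, droppath, embed_dim (integer-rounded), weight decay; the
objective is negative validation AUC.

## Evaluation and fusion

Specificity is TN/(TN+FP); an alternative printed form with denominator
(TP+FN) is available behind a `printed_eq5` flag for comparison because it
conflicts with the standard definition and with how the quantity is used.
Zero-denominator metrics are reported as explicit `None`, never silently 0.
AUC is the rank-based (Mann–Whitney) estimator, exact under ties; KS is
max|TPR−FPR| over observed thresholds.

Fusion maps the two heads' decisions (both at τ = 0.327 by default,
per-head thresholds configurable) through AND/OR logic to
{no, low, high} risk; the map is total over {0,1}² and monotone in each
head. Cross-family subject pairing in the synthetic demo is by row index —
an artifact of having two independently generated cohorts; with real data
the pairing key would be the subject identifier.

## Problem sizes

The shipped configurations are deliberately desk-scale: the demo pipeline
uses 1,100 rows per family, 40–80 boosting rounds, 2–3 reweighting epochs
and ≤15 attention epochs at embed_dim 16, completing in a few seconds on
one CPU; the full-size generator (11,000 rows per family) is used where
only counting is required. The behavioural ablation tests train the
attention model for 25 epochs on 4,000 rows.

## Known limitations

* The synthetic positives are unimodal per indicator; real at-risk
  populations are mixtures.
* The two heads are fused at the decision level only; no calibrated
  probabilistic risk is produced (the design outputs discrete levels).
* The feature-weight loop is provably neutral for the tree head and mild
  for the sign-updated attention head; its value is interpretability
  (contribution tracking) more than accuracy on these cohorts.
* The metaheuristic follows the five-phase description, not every operator
  of the originally published algorithm.
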