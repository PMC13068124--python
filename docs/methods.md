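# Methods

## Data model

A cohort is a subjects × features table of integer category codes plus a
manifest assigning each column a modality (`genetics`, `lifestyle`,
`phenotype`) and a scale (`nominal`, `ordinal`, `binary`) with an explicit
level set. Genetics columns hold per-gene mutation burden: genotype pairs
collapse at ingest to 0 (wild type), 1 (heterozygous — either single-allele
configuration), or 2 (homozygous or compound heterozygous). Phenotype
columns are ordinal severity grades starting at 0. All analysis operates on
this single canonical integer coding; string labels live only in the
manifest.

Missing cells fail validation by default; the opt-in `drop_rows` policy
removes affected rows and logs the count. No imputation is implemented —
for questionnaire-derived categorical data there is no defensible generic
imputation rule, and silently inventing categories would contaminate the
downstream counts-based methods.

## k-modes clustering

Lloyd-style alternation for categorical data: assign each row to the
prototype (mode) with the fewest mismatching positions, then recompute each
mode as the column-wise most frequent category among its members. Design
choices that the algorithm itself leaves open are fixed for exact
reproducibility:

- assignment ties go to the lowest cluster index; mode-update ties to the
  smallest category code;
- convergence is an unchanged assignment vector, capped by `max_iter`;
- an empty cluster is repaired by reseeding its mode with the point
  farthest from its currently assigned prototype (this cannot increase the
  objective);
- Huang initialisation samples each mode coordinate from the column's
  empirical category distribution, then snaps each mode to its nearest
  distinct data row; Cao initialisation greedily picks distinct rows
  maximizing density × dissimilarity to already-chosen modes and is fully
  deterministic, so restarts collapse to a single run;
- restarts use `default_rng(seed + restart_index)` so any restart is
  re-runnable in isolation; the best restart by total cost wins, ties to
  the lowest restart index.

Per-iteration total cost is non-increasing (assignment and mode update each
minimize the objective given the other), and one extra iteration after
convergence is a no-op; both properties are asserted in the test suite and
recomputed by the acceptance script.

**Local optima.** Cao's deterministic greedy start occasionally places two
initial modes inside one large cluster on imbalanced mixtures and converges
to a visibly higher-cost merge/split solution. The restart-best-cost rule
resolves this: on well-separated 4-cluster cohorts, Huang with 20 restarts
recovered the planted partition in every seeded trial, with roughly a 9%
cost gap separating the planted optimum from the bad local optima. Checks
that require recovering a planted partition therefore use Huang with
`n_init=20`, a value inside the standard candidate grid.

## Stability-penalized selection

For each candidate hyperparameter setting, R = 10 subsamples of 80% of the
training rows (without replacement) are clustered; each fitted model labels
the *full* training set via its prototypes, making the R labelings directly
comparable. Stability is the mean pairwise Adjusted Rand Index over the
C(10,2) = 45 pairs. Candidates are ranked by the penalized score

    Score(k) = ARĪ − α·k/k_max,   α = 0.01, k_max = 5,

so the penalty term is 0.002·k — mild enough that it only matters between
near-equivalent candidates, discouraging over-fragmentation. "Similar
scores" is operationalized as |Δscore| ≤ 1e−6 (exposed as `tie_tol`), within
which the lower mean mismatch cost wins, then grid order. The mismatch cost
reported per candidate is the mean over the R subsample models of their
cost on the full training set (rather than from a separate refit), which
matches the stability framing and is recorded in selection output.

The ARI uses the Hubert–Arabie contingency-table form; when both labelings
are single-cluster the chance-corrected denominator vanishes and 1.0 is
returned (the partitions are identical). This cannot arise with the
standard grid (k ≥ 3) but guards generic use. The implementation is checked
against both a brute-force pair-counting oracle and scikit-learn.

The full selection grid is k ∈ {3,4,5} × init ∈ {Huang, Cao} × n_init ∈
{5,10,20} × max_iter ∈ {100,300,500} (54 candidates). Routine runs in this
repository use the 6-candidate sub-grid k × init with n_init = 5,
max_iter = 100: n_init beyond 5 rarely changes the selected candidate on
cohorts of a few thousand rows, and k-modes on such data converges in well
under 100 iterations, so the larger values only add compute. The stability
constants (R = 10, 80% subsampling, α = 0.01, k_max = 5) and the 5-fold
outer loop are never reduced.

## Nested protocol

Outer 5-fold loop from a seeded shuffle (unstratified — labels are
fold-specific surrogates, so there is nothing to stratify on). Per fold:

1. hyperparameter selection on the training split only, clustering over all
   three modalities;
2. k-modes refit on the full training split;
3. surrogate labels for train and test via the training prototypes only —
   held-out rows are never read before this point, so selection and the
   training model are invariant to arbitrary mutation of the held-out rows
   (asserted fold-by-fold in the tests and the acceptance script);
4. an XGBoost classifier per feature configuration (genetics-only,
   lifestyle-only, integrated), trained on the training split and evaluated
   on the held-out split. Phenotypes never enter the classifier: clusters
   are partly phenotype-driven, and predicting them from phenotypes would
   be circular as well as clinically uninteresting;
5. attribution (gain, permutation, SHAP-style) on the held-out split for
   the integrated configuration.

Classifier defaults: 300 boosting rounds, depth 6, learning rate 0.1,
histogram tree method, single thread, seeded — fixed and recorded since the
categorical inputs are small integer code sets that gradient-boosted trees
split natively. Metrics are accuracy and macro-averaged precision, recall
and F1 over the classes present in y_true ∪ y_pred, with 0/0 ratios defined
as 0. Fold aggregation uses the population (n=5) standard-deviation
denominator, recorded in the summary. Cluster labels are fold-local; no
cross-fold label alignment is attempted, since no metric ever compares
labels between folds.

A final full-data refit at the modal k across folds produces cluster
prevalences and per-cluster modal profiles for descriptive reporting only;
its output is flagged `descriptive_only`.

## Statistical tests

Ordinal severities are analysed as equally spaced numeric scores — a
modeling assumption, adequate for grades with a logical progression but a
known simplification versus proportional-odds models (out of scope).

- One-way burden ANOVA (scipy) across none/single/double groups; empty
  groups are dropped with a warning. Post-hoc pairwise t-tests are
  two-sided with pooled variance and no multiplicity correction; outputs
  carry an `uncorrected` flag. The identical-constant-samples edge case is
  defined as t = 0, p = 1.
- Two-way Type II ANOVA on binarized genotype (carrier = burden > 0) ×
  median-binned lifestyle (values equal to the median bin Low; binary
  columns pass through; constant columns are an error). Each term's sum of
  squares comes from explicit nested least-squares model comparison —
  main effects adjusted for the other main effect, the interaction adjusted
  for both — with F on (1, n−4) degrees of freedom, validated against
  statsmodels' Type II table to 1e−10. A noiseless saturated fit reports
  F = 0 with a `residual_zero` flag; an empty design cell raises a
  sparse-subgroup condition that the battery reports as a flagged row.

The default interaction battery holds the five hypotheses:
FLG × scrub usage → sensitivity; MMP-3 × city living → redness;
SOD2 × stress → acne; AQP3 × winter exposure → dryness;
GPX × medication → pigmentation.

## Synthetic cohort generator

The generator defines the study conditions for every test; real cohorts of
this kind are proprietary. Schema: six burden-coded genes, 20 lifestyle
features (11 binary, 9 four-level ordinal), six four-level phenotype
severities, n configurable (the `paperlike` preset uses 5,254 subjects and
a 95%-female binary proxy, with menopause/pregnancy as life-stage proxies
and no age variable).

Latent clusters form a 2 × 2 cross of a genetics factor and a lifestyle
factor (cluster z → gene group z÷2, lifestyle group z mod 2 for four
clusters), so *neither modality alone identifies the cluster* — exactly the
joint-determination condition under which multimodal integration should
dominate unimodal baselines. A `separation` dial in [0,1] mixes each
feature's baseline distribution with a point mass on a cluster-preferred
level; the baseline burden distribution is (0.50, 0.35, 0.15), giving a
carrier probability of 0.5 so interaction designs are balanced.

Phenotype severities come from a latent-Gaussian threshold model: for each
phenotype, a score sums a burden dose effect (β_g = 0.3 per allele) for its
driving gene, a double-mutation threshold bonus (τ = 0.5), lifestyle main
effects (β_l = 0.2), planted interaction terms (δ per spec, default 0.5,
added for carrier × high-exposure subjects), a per-cluster offset, and
Normal(0, σ = 1) noise. The score is cut into four grades at fixed
population quantile fractions (0.35 / 0.70 / 0.90), which mimics
relative-to-cohort self-report grading and keeps the marginal severity
distribution realistic while effects manifest as reordering. Effect sizes
were chosen so that the planted δ = 0.5 interaction at n = 2,000 is
detectable with high power while the null calibration stays nominal; both
are measured, not assumed (type-I rate ≈ 0.05 over 1,000 null replicates,
power ≈ 1.0 over 200 planted replicates).

What the generator does **not** emulate: linkage between variants,
correlated questionnaire responses beyond cluster structure, free-text
phenotype reporting, reporting bias, or demographic confounding. Passing
tests therefore demonstrate algorithmic correctness and the designed
statistical properties under a known generative model — not performance on
real consumer-genomics cohorts, whose headline metrics are not reproducible
without the original data.

Ground truth (latent clusters, planted effect sizes, full generating
config) is returned and serialized separately from the cohort so blind
runs are possible.

## Problem sizes and determinism

Tests and the acceptance script exercise the pipeline at n = 400–2,000
subjects with the 3- or 6-candidate grids: large enough that every
statistical property is measurable at its stated tolerance, small enough
that the whole suite runs in about a minute per nested-CV run on one core.
All randomness derives from a single master seed through
`numpy.random.SeedSequence` children keyed by (fold, candidate, repeat)
indices, so every sub-computation is independently re-runnable and two runs
with the same seed produce byte-identical summaries (asserted).

## Known limitations

- k-modes finds local optima; restart count is the only mitigation offered.
- Stability selection on well-separated but imbalanced 4-cluster mixtures
  tends to prefer k = 3 (merging the two smallest clusters is more stable
  under subsampling than splitting them, and the k-penalty is mild); this
  is a property of the criterion, not a defect of the implementation.
- Analysing ordinal grades as numeric scores and median-binning ordinal
  exposures both discard information.
- The interaction battery tests five prespecified hypotheses without
  multiplicity correction by design; it is not a screening tool.
- The profile report's driver → intervention mapping is a static editable
  lookup, not a learned or clinically validated rule.
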