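# Methods

## The problem

After curative treatment of prostate adenocarcinoma, a substantial
minority of patients relapse; time-to-biochemical-recurrence (flagged by
rising PSA) is the survival endpoint of interest.  The pipeline asks
whether patient subgroups with distinct recurrence risk can be recovered
by integrating three molecular views of each patient — gene expression,
DNA methylation (beta values per CpG probe) and miRNA expression — and
whether a small panel of features selected by two independent integration
methods carries a reproducible prognostic signal.

## Synthetic cohort

All analyses run on cohorts from `omisurv.synthetic`, which plants a known
two-subgroup structure:

* subgroup `z_i ~ Bernoulli(π)` (default π = 0.35; `z = 1` is high risk);
* per omics block, a fraction of features (default 10%) is informative:
  the high-risk subgroup's mean is shifted by δ standard deviations
  (default δ = 1) on the latent scale;
* expression and miRNA blocks are log-normal (signal on the log scale),
  methylation is normal on the logit scale squashed to (0,1) to resemble
  beta values — plausible marginals, irrelevant to method correctness
  because preprocessing z-scores everything;
* recurrence times are exponential with the high-risk hazard multiplied
  by the hazard ratio (default 4).  Exponential rather than Weibull: it is
  the simplest model satisfying proportional hazards, which every Cox step
  downstream assumes.  Censoring is independent exponential; observed time
  is the minimum, with an event indicator;
* clinical covariates correlate with the subgroup: Gleason (6–10) and
  stage (I–IV) are drawn from subgroup-tilted categoricals (log-odds shift
  `log(clinical_assoc)` per level), age is N(61, 7²), PSA log-normal.

Time is measured in months throughout.  The generator is fully seeded:
equal seeds give bit-identical cohorts.

The **bundled cohort** (`prad_preset`) has 494 samples and exactly 60
recurrence events, matching the emulated cohort's censoring regime
(~88% censored).  The event count is forced deterministically: after
drawing survival, the minimal number of indicators is flipped (candidates
ordered by longest observed time — the least informative events, or the
longest-followed censored records), leaving observed times untouched, so
"exactly 60" is a structural property rather than a lottery.  Block widths
are 400 expression genes, 400 methylation probes and 200 miRNAs — a
deliberately scaled-down stand-in for genome-wide panels, chosen so the
full two-arm study runs in about a minute on one CPU while keeping the
informative-feature fraction realistic.

What the generator does **not** emulate: co-expression modules and other
correlation structure among features, batch effects, missingness, copy
number or mutations.  Passing tests therefore demonstrate the machinery's
correctness and its behaviour under a clean planted-signal model, not
performance on real multiomics data, where correlated features and weaker
effect sizes change the power of every step.

## Preprocessing

Features are dropped if they contain a missing value, are identically
zero, or have zero variance (the last so z-scoring is defined).  "Zero"
features are interpreted as all-zero columns — dropping any feature that
ever touches zero would annihilate count-derived data.  Normalization is
per **feature** (mean 0, sample SD 1): per-sample scaling would destroy
the cross-sample distances every downstream step consumes, and per-feature
z-scoring is the reference semantics of the standard-normalization step in
the similarity-network tooling this pipeline mirrors.  Samples are aligned
by ID intersection across all three blocks and the clinical table, ordered
as in the clinical table.

## SNF arm

Distances are squared Euclidean on the z-scored features.  The affinity
kernel is self-tuning: `W(i,j) = exp(-d(i,j) / (σ·ε_ij))` with local scale
`ε_ij = (mean_K(d(i,·)) + mean_K(d(j,·)) + d(i,j)) / 3`, where `mean_K` is
the mean distance to the K nearest neighbours.  Defaults K = 20, σ = 0.5,
T = 20 iterations.  Fusion uses the two-kernel cross-diffusion scheme:
a full status matrix `P` (off-diagonal rows sum to 1/2, diagonal 1/2) and
a row-normalized K-nearest-neighbour kernel `S`; each iteration updates
`P_v ← S_v · mean_{u≠v}(P_u) · S_vᵀ`, renormalizes and symmetrizes; the
fused network is the average of the final per-view status matrices.  A
distance floor (1e-12) guards duplicate-heavy degenerate inputs.

Spectral clustering uses the symmetric-normalized affinity: top-k
eigenvectors, row-normalized, then seeded k-means with 20 restarts.  The
cluster number is estimated two ways: the eigen-gap of the normalized
Laplacian spectrum (primary) and a rotation cost (the Yu–Shi
discretisation alignment cost of the row-normalized spectral embedding,
mildly scale-corrected by √k; smaller is better).  On disagreement the
eigen-gap wins; ties break toward smaller k.

## Autoencoder arm

A fully connected tanh autoencoder (input → 500 → 200 → 500 → input,
linear output) is trained by plain mini-batch SGD on the per-sample
squared reconstruction error averaged over the batch, plus L1 (1e-4) and
L2 (1e-3) penalties on weights only.  Initialization is seeded Xavier
uniform.  Two profiles ship:

* **paper** — the printed hyperparameters of the emulated study
  (5 epochs, batch 32, learning rate 1e-6).  At this learning rate the
  weights barely move, so the bottleneck is essentially a random nonlinear
  projection; the profile exists for faithfulness.
* **tuned** — learning rate 1e-3, 20 epochs; the profile all end-to-end
  properties are stated under.

The 20-epoch choice is deliberate and empirically grounded: with a
bottleneck narrower than the sample count, prolonged SGD reorganizes the
latent axes toward reconstructing isotropic noise variance and measurably
*dilutes* the per-node survival signal (on planted cohorts, subgroup
recovery degrades monotonically beyond ~20 epochs while reconstruction
keeps improving).  Early stopping keeps the bottleneck close to an
information-preserving projection.  A related structural fact worth
knowing: for any rotation-symmetric latent representation, the expected
share of a single node's variance explained by the subgroup is capped at
`δ²π(1-π)·m/d` (m informative of d total features) — about 2.3% under the
default design — so the per-node Cox screen needs a reasonable number of
events to have power.  End-to-end recovery simulations therefore use
moderate censoring (censor scale equal to the baseline scale, ~40–45%
censored), the usual regime for a power analysis, while the bundled cohort
keeps its realistic heavy censoring.

The 200 bottleneck activations are screened by univariate Cox (Wald
p < 0.05, Efron ties); k-means with silhouette-based k selection clusters
the surviving nodes (the dichotomy is forced to k = 2 for risk tagging if
the silhouette prefers another k, which is recorded).  If fewer than two
nodes survive the screen, clustering falls back to all nodes with a
warning.

## Survival machinery

* **Cox fits** (uni- and multivariate) use Efron tie handling via
  lifelines; non-convergent screens skip the feature with a warning,
  never selecting it silently.  The p < 0.05 screen is deliberately
  uncorrected for multiplicity, mirroring common practice in this
  literature; callers can pass a stricter alpha.
* **Harrell's C**: pairs are comparable iff the smaller observed time is
  an event; concordant when the shorter-lived sample has the higher risk;
  tied risks count 1/2.  Subgroup labels are scored as a 0/1 risk
  covariate.
* **Log-rank** tests and **Kaplan–Meier** curves come from lifelines; the
  cutpoint search uses an internal vectorized two-group log-rank statistic
  (tested against lifelines to 1e-9 relative).
* **5-year AUC** is the cumulative/dynamic estimator at 60 months with
  Kaplan–Meier inverse-probability-of-censoring weights: cases are events
  by the horizon weighted 1/G(T_i), controls are samples at risk beyond it
  weighted 1/G(60).  It is cross-checked in the tests against
  scikit-survival's implementation, and a naive "exclude censored before
  horizon" binary AUC is available for comparison.

## Differential features, intersection, panel

Wilcoxon rank-sum tests compare each feature between the high- and
low-risk subgroups (exact enumeration for tie-free groups under 20 per
side, tie-corrected normal approximation otherwise).  Per omics, features
are ranked by ascending p (ties: larger absolute mean difference, then
lexicographic ID — a fully deterministic order) and truncated to quotas of
100 expression, 100 methylation, 50 miRNA.  The two arms' lists are
intersected per omics after both arms' high/low alignment, flagging
direction concordance.  The panel takes the two intersected features per
omics with the smallest mean of the two arms' p-values (neither arm is
privileged), pre-screens them by univariate Cox (p < 0.05), fits a joint
Cox model, and computes `score_i = Σ_j β_j x_ij`.

The cutpoint is the maximally selected log-rank split over candidate cuts
at midpoints of sorted unique scores within the 10th–90th percentile
window.  The log-rank p of the induced split is reported raw, as the
field's tooling reports it, with the explicit caveat that cutpoint
optimization inflates it (the test suite demonstrates the inflation on
null data).  With clinical covariates requested, the Cox model is refitted
with encoded age (numeric), Gleason (numeric) and stage (ordinal I–IV)
appended, and the same metrics are reported for the combined score; this
"refit" reading of combining the panel with clinical information is a
design choice (the alternative — stratifying the KM only — is not
implemented).

## SVM validation

Feature sets: Cox-selected latent nodes; the 250 top multiomics features;
multiomics plus all clinical covariates or each one alone.  An RBF-kernel
SVM (C = 1, gamma = "scale") is evaluated by stratified 5-fold CV repeated
10 times; standardization is fitted on training folds only; sensitivity
treats the high-risk subgroup as the positive class.  Stratification is a
deliberate choice over fully random splits to keep both subgroups in every
fold.  The kernel is the ecosystem default since the emulated analysis
names none.

## Numerical choices and degenerate inputs

Newton–Raphson Cox fitting at lifelines defaults; distance/affinity floors
at 1e-12; constant affinity matrices return the smallest candidate k with
a warning; identical KM curves break risk ties by event count with a
warning; all-equal scores make the cutpoint search fail loudly.  Every
stochastic stage (initialization, batching, k-means restarts, CV folds)
takes a seed, and one run-level seed fans out to all of them.

## Known limitations

The paper-profile autoencoder is near-untrained by construction of its
printed hyperparameters; conclusions about autoencoder quality should use
the tuned profile.  The eigen-gap/rotation heuristics assume reasonably
balanced blocks.  The synthetic cohort's independence structure makes
feature selection easier than on real data at matched effect sizes, and
the bundled cohort's heavy censoring (60/494 events) makes all per-feature
screens low-powered — visible in the worked example, where only ~20 of 200
latent nodes pass the Cox screen.  Competing risks, stratified Cox,
time-varying covariates and pathway enrichment are out of scope.
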