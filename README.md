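# omisurv

Multiomics subtyping of cancer-recurrence risk, implemented as a tested,
config-driven analysis pipeline.  Two independent arms discover patient
subgroups from three omics blocks (gene expression, DNA-methylation probe
values, miRNA expression):

* **Similarity network fusion (SNF)** — per-omics patient-similarity
  graphs built with a self-tuning Gaussian kernel
  `W(i,j) = exp(-d²(i,j) / (σ·ε_ij))`, fused by cross-network diffusion
  `P_v ← S_v · mean_{u≠v}(P_u) · S_vᵀ` over T iterations, then spectral
  clustering with eigen-gap / rotation-cost estimates of the cluster
  number.
* **Autoencoder latent features** — the three z-scored blocks are stacked
  and passed through a tanh autoencoder (hidden widths 500–200–500); the
  200 bottleneck activations are screened by univariate Cox regression
  (p < 0.05) and the surviving nodes are clustered by k-means with
  silhouette-based model selection.

Each arm's two subgroups are tagged high/low recurrence risk from their
Kaplan–Meier curves and scored by Harrell's C-index and the log-rank test.
Per-omics Wilcoxon rank-sum tests rank features between the risk groups;
the arms' top-100/100/50 lists are intersected with a direction-concordance
check; the intersected features feed a multivariate Cox risk score
`score_i = Σ_j β_j x_ij` with a maximally selected log-rank cutpoint,
evaluated by KM split, C-index and the 5-year cumulative/dynamic AUC
(inverse-censoring-weighted).  An SVM suite (repeated stratified 5-fold CV)
quantifies how well each feature-set combination predicts the subgroup
labels.

The package ships a synthetic-cohort generator with planted ground truth
(subgroup labels, informative features, proportional-hazards recurrence
times), so the whole pipeline is testable without any data download.  The
intended audience is method developers and students of multiomics survival
integration; the bundled cohort is synthetic and no clinical conclusions
should be drawn from it.

## Worked example

The numbered drivers under `analysis/` run the full study on the bundled
cohort (494 patients, 60 recurrence events), writing tables under
`results/`:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_preprocess.py
python analysis/03_snf_subtyping.py
python analysis/04_autoencoder_subtyping.py
python analysis/05_differential_features.py
python analysis/06_svm_validation.py
python analysis/07_risk_panel.py
```

Output of the two subtyping arms on the bundled cohort:

```
estimated clusters: eigen-gap 2, rotation cost 2
high-risk group: 168 of 494 samples
C-index 0.612, log-rank p 1.41e-06          # SNF arm

survival-associated bottleneck nodes: 22 of 200 (p < 0.05)
silhouette-optimal k = 2; high-risk group 198 of 494
C-index 0.632, log-rank p 1.34e-06          # autoencoder arm
```

Both cluster-number heuristics agree on two subgroups, and both arms'
dichotomies separate time-to-recurrence far beyond chance, with the
autoencoder arm discriminating slightly better — the pattern the pipeline
is designed to expose.  Downstream, the intersected differential features
yield a risk panel:

```
panel features (after univariate screen): ['gene_288', 'cg_156', 'cg_263']
cutoff 0.364 -> 94 high / 400 low risk
log-rank p 3.08e-06, C-index 0.597, 5-year AUC 0.671
with clinical covariates: C-index 0.601, log-rank p 1.59e-07, AUC 0.667
```

and the SVM validation reproduces the characteristic ordering in which the
latent-node classifier (96.4% accuracy) beats the 250-feature multiomics
classifier (87.7%).

Library use without the scripts:

```python
from omisurv import prad_preset, run_subtyping, run_panel, RunConfig

result = run_subtyping(prad_preset(), RunConfig())
panel, report = run_panel(result)
print(report["c_index"], report["logrank_p"])
```

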