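# immunonoise

Residual-subspace anomaly screening for immunologic biomarker cohorts,
built around a periodontitis case study: do hidden random fluctuations
("noise") in immune parameters distinguish early-onset, rapidly
progressing periodontitis (EOP) from the late-onset, slowly progressing
form (LOP)?

The package is aimed at biostatisticians and computational clinicians who
want a tested, reproducible implementation of this anomaly-detection
workflow — including a synthetic cohort generator that emulates the study
population (68 EOP + 43 LOP discovery patients and 51 EOP-suspected
validation patients, 28 immunologic parameters: neutrophil function,
lymphocyte subsets, cytokine productivity, T-cell blastogenesis and serum
IgG titers against periodontal bacteria), so every stage can be exercised
and validated without access to the original patient data.

## The method

1. **Subspace split (PCA).** Standardize the discovery matrix and
   eigendecompose its correlation matrix `R = V Λ Vᵀ`. Components with
   eigenvalue λ > ε carry the cohort's typical variation; each is
   identified with its dominant parameter (greedy, by |loading|). The
   remaining parameters form the *residual subspace* — the search space
   for collective anomalies that contribute nothing to explained variance.
2. **Sample-entropy screen.** For each residual parameter, the plug-in
   Shannon entropy of its distinct recorded-value frequencies,
   `H = −Σᵢ (nᵢ/S) log₁₀(nᵢ/S)`, with `0 ≤ H² ≤ (log₁₀ S)²`
   (0–4.18 for S = 111, 0–2.92 for S = 51). Parameters with `H² ≥ 3`
   are anomaly candidates. Repeated on the validation cohort, which is
   used for nothing else.
3. **Two-step clustering cross-check.** Seeded k-means pre-clustering
   followed by agglomerative merging under the log-likelihood distance
   `d(j,s) = ξⱼ + ξₛ − ξ⟨j,s⟩`, `ξᵥ = −Nᵥ Σₖ ½ ln(σ̂²ₖ + σ̂²ᵥₖ)`, into two
   patient clusters. Per-parameter importance = normalized −log₁₀ p of a
   two-cluster Welch t-test; anomalous parameters separate the clusters
   poorly, so *low* importance corroborates an entropy flag.
4. **Aggregate LOF + k-NN.** Local Outlier Factor scores (Breunig
   definitions, Euclidean metric) in the joint z-scored space of the
   corroborated parameters give one anomaly score per patient; a k-NN
   classifier on that scalar separates EOP (positive class) from LOP,
   reported apparent and under seeded stratified 10-fold CV.

## Worked example

```python
import numpy as np

from immunonoise import (
    ContaminationSpec, default_table2_config, generate_cohort,
    inject_contamination, subset_by_group, standardize, pca, split_subspaces,
    entropy_screen, two_step_cluster, predictor_importance,
    anomaly_corroboration, aggregate_lof, knn_classify_cv, select_k,
)

# A study-sized synthetic cohort (68 EOP + 43 LOP + 51 validation) with the
# collinear correlation structure, then hidden noise injected into five
# residual-subspace parameters of the EOP group.
config = default_table2_config(seed=42, structure="collinear")
clean = generate_cohort(config)
discovery = subset_by_group(clean, {"EOP", "LOP"})

decomp = pca(standardize(discovery.values, discovery.parameter_names),
             discovery.parameter_names)
normal, residual = split_subspaces(decomp, eps=0.01)
print(f"retained components: {len(normal)}, residual parameters: {len(residual)}")

rng = np.random.default_rng(42)
targets = tuple(sorted(map(str, rng.choice(residual, size=5, replace=False))))
print("injected anomalies:", list(targets))
noise = ContaminationSpec(target_parameters=targets, pi=0.3, displacement=3.0)
discovery = subset_by_group(inject_contamination(clean, noise, seed=7),
                            {"EOP", "LOP"})

entropy = entropy_screen(discovery, residual, threshold=3.0)
z = standardize(discovery.matrix(residual), residual)
clusters = two_step_cluster(z, n_preclusters=20, k=2, seed=42)
importance = predictor_importance(z, clusters.labels, residual)
anomalies = anomaly_corroboration(entropy, importance)
print("corroborated anomaly parameters:", sorted(anomalies))

scores = aggregate_lof(discovery, sorted(anomalies), k_lof=10).scores
k = select_k(scores, discovery.group_labels, folds=10, seed=42)
report = knn_classify_cv(scores, discovery.group_labels, k_nn=k,
                         folds=10, seed=42)
print(f"k-NN (k={k}) on aggregate LOF: "
      f"sensitivity {report.cv_sensitivity:.2f}, "
      f"specificity {report.cv_specificity:.2f} (10-fold CV)")
```

Output:

```
retained components: 11, residual parameters: 17
injected anomalies: ['IFNg', 'IgG_Aa_Y4', 'IgG_Ws_ATCC29543', 'PWM_blastogenesis', 'adhesion']
corroborated anomaly parameters: ['IFNg', 'IgG_Aa_SUNY67', 'IgG_Co_S3', 'IgG_Ws_ATCC29543', 'PWM_blastogenesis', 'adhesion']
k-NN (k=9) on aggregate LOF: sensitivity 0.78, specificity 0.93 (10-fold CV)
```

The discovery correlation structure splits into 11 variance-carrying
components and 17 residual parameters; the screen recovers four of the
five injected anomaly parameters (plus two false positives), and the
classifier built on the aggregate LOF score separates the noisy EOP group
from LOP well above chance.

The same workflow runs from the shell:

```sh
immunonoise run --config cfg.yaml        # full pipeline -> report directory
immunonoise simulate --out cohort.csv --seed 1 --structure collinear
immunonoise entropy --in cohort.csv
immunonoise lof --in cohort.csv --params chemotaxis,CD4_pct,CD8_pct
```

`immunonoise run` writes every intermediate report (group statistics,
scree data, subspace membership, entropy tables, cluster importance, LOF
scores, classification metrics) plus a run manifest; identical configs
reproduce identical outputs byte for byte.

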