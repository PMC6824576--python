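# Methods

## Problem setting

The package operationalizes a noise-detection hypothesis for
periodontitis: early-onset, rapidly progressing disease (EOP, stage 3–4
grade C) may be distinguished from late-onset, slowly progressing disease
(LOP, stage 3 grade A) not by the *level* of immunologic parameters but by
hidden random fluctuations (anomalies) within them. The data model is a
patient × parameter table of 28 continuous immunologic measurements —
neutrophil chemotaxis/phagocytosis/adhesion, lymphocyte subset
percentages (CD3, CD4, CD8, CD20, CD4/CD8), monocytic cytokine
productivity (IL-1, IL-2, IL-4, IL-6, TNF-α, IFN-γ), T-cell blastogenesis
(anti-CD3, PWM), and twelve serum IgG titers against periodontal bacteria
(ELISA units, which can be negative after blank correction) — with one
group label per patient: EOP, LOP, or VALIDATION (EOP-suspected patients
used only to look for entropy trends).

## Pipeline stages and their assumptions

### Group statistics

Per-group median / mean / sample SD per parameter, and a two-sided
Mann-Whitney U comparison (midranks for ties) of EOP vs LOP at α = 0.05,
with no multiplicity adjustment (deliberately mirroring the original
analysis; an adjustment would be trivial to add but would change the
reported significance pattern). The p-value follows standard software
practice: exact null distribution for small tie-free samples, otherwise
the tie-corrected normal approximation with continuity correction. At the
study's sizes (68 vs 43) the asymptotic route is used and is accurate to
well under 10⁻³; at the smallest sizes (min(n) ≤ 2) the asymptotic
two-sided p can deviate from the exact one by up to ~0.13, which is why
the exact route exists.

### PCA subspace split

Correlation-matrix PCA (not covariance: the parameters mix counts,
percentages, pg/ml and ELISA units, so covariance eigenvalues would
reflect scale, not structure). Eigenvalues are clipped at zero;
eigenvector signs are fixed by making each component's largest-|loading|
entry positive so reports are backend-independent. Components with
λ > ε (default ε = 0.01, i.e. "zero on the scree plot") are retained, and
each retained component is identified with its *dominant parameter*: the
largest-|loading| parameter not already claimed by a stronger component,
assigned greedily in decreasing-eigenvalue order. This formalizes the
practice of naming individual parameters as "the principal components"
and guarantees a clean partition: |residual| = p − n_retained. The
assignment rule and ε are both configurable; for strongly collinear data
(the regime this workflow targets) the split is insensitive to ε across
several orders of magnitude because the spectrum has a wide gap.

### Sample-entropy screen

"Sample entropy" here is the plug-in Shannon entropy of the frequency
table of a parameter's *distinct recorded values*,
H = −Σ (nᵢ/S) log₁₀(nᵢ/S) — not the Richman–Moorman time-series SampEn.
The base-10 logarithm is pinned by the published range ceilings:
(log₁₀ 111)² = 4.18 and (log₁₀ 51)² = 2.92. Discretization is rounding
half-to-even to the recorded measurement precision (default 2 decimals);
scale normalization cannot change distinct-value counts, so it is omitted.
H² ≥ 3 (configurable) flags a parameter as an anomaly candidate.

Two properties matter for interpretation. First, the statistic is
informative only through ties: a continuous column recorded at fine
precision has all values distinct and sits at the ceiling regardless of
shape. Real assay data are coarsely quantized, which is what makes the
published screen selective; synthetic continuous columns at 2-decimal
precision saturate, so on synthetic cohorts the screen's flags are
near-universal and the discrimination burden falls on the clustering
cross-check (below). Second, the ceiling (log₁₀ S)² grows with the
cohort, so squared entropies are only comparable within a cohort — hence
the separate discovery and validation reports.

### Two-step clustering and predictor importance

Step 1 is plain seeded k-means into 20 pre-clusters (a CF-tree adds
nothing at n ≈ 100); step 2 merges pre-clusters agglomeratively, at each
step joining the pair with the smallest log-likelihood distance
d(j,s) = ξⱼ + ξₛ − ξ⟨j,s⟩ with ξᵥ = −Nᵥ Σₖ ½ ln(σ̂²ₖ + σ̂²ᵥₖ), until two
clusters remain (no model selection: the workflow is defined for a
two-class grouping). Population (divide-by-N) variances are used inside
ξ; the global-variance term σ̂²ₖ guards the logarithm when a cluster is
internally constant, so no extra smoothing ε is needed. Cluster ids are
renumbered by size. If the data cannot support two clusters (all points
identical) the result is flagged degenerate rather than silently split.

Importance of parameter k is the normalized evidence that k separates
the two clusters: importance = (−log₁₀ pₖ) / maxⱼ(−log₁₀ pⱼ) with pₖ a
two-cluster Welch t-test p-value, clipped to [0, 1]; parameters identical
across clusters get 0. The corroboration rule calls a parameter
low-importance if its score is ≤ 0.05 *or* it ranks in the lowest third
of the profile. The rank route exists because normalized −log p scales
are implementation-specific (the same ranking can map to very different
absolute values depending on how extreme the top p-value is); on a
profile where anomalous parameters sit near zero and the rest spread
broadly upward the two routes agree. Corroborated anomalies = entropy
flags ∩ low-importance parameters.

### Aggregate LOF and k-NN classification

LOF follows the original definitions exactly: tie-inclusive k-distance
neighborhoods, reachability distance max(k-distance(o), d(p,o)), local
reachability density as inverse mean reachability, LOF as the mean
neighbor-to-self lrd ratio, Euclidean metric on per-dimension z-scored
data. A point duplicated at least k_lof times has zero mean reachability;
its lrd is capped at 10¹⁰, which makes mutual duplicates score exactly 1
(they are indistinguishable from their neighborhood). Default
neighborhood size k_lof = 10, a standard MinPts-style choice; the
original study does not state its value, so the reproduction path sweeps
k_lof ∈ {5, 10, 20} and reports the closest configuration.

The classifier input is the scalar aggregate LOF score alone, computed in
the joint space of the corroborated parameters (the pipeline falls back
to the entropy flags if corroboration selects nothing, and a
`use_entropy_flags_only` switch forces that choice). k-NN on a 1-D score
with majority vote, vote ties broken by the single nearest neighbor;
k_nn is selected by maximizing CV balanced accuracy over odd k ∈ [1, 15]
(ties → smallest k) unless fixed. EOP is the positive class. Apparent
metrics refit on all patients; CV metrics use seeded stratified 10-fold
splits with neighbors drawn from the training fold only.

## The synthetic cohort generator

The generator emulates the *published summary structure* of the study
population: per-group means and SDs of all 28 parameters, group sizes
68/43/51, and 2-decimal recorded precision (rounding is part of
generation because the entropy statistic depends on ties).

Marginal families (`independent` preset): a parameter is modelled normal
unless a group is strongly overdispersed (SD/|mean| > 0.8) or clearly
right-skewed (mean − median > 0.5 SD), in which case a shifted log-normal
is used — the published table reports medians well below means for the
cytokines and several IgG titers, and titers can be negative, so the
support shift is required. The shift is set to min over groups of
(mean − 2 SD), which caps the log-normal coefficient of variation at 0.5
while matching both target moments exactly; heavier parameterizations
reproduce the same moments but make finite-sample moment recovery
unverifiable at any practical n. With this choice, sample moments at
n = 10,000/group recover every configured mean within 3 standard errors
and every SD within 5%.

Correlation structure (`collinear` preset): the study's discovery
correlation matrix is strongly collinear (11 components explain
essentially all variance in 28 parameters), which the independent preset
cannot reproduce. The collinear preset draws patients from a seeded
10-factor model: one *common axis* all parameters load on (0.85) — the
cohort's shared overall immune-function variation — plus nine block axes
(0.50, round-robin over parameters) and N(0, 0.3²/√f) cross-loadings,
loading vectors normalized to unit length. Group means follow the
published table; the scale is a single discovery-pooled within-group SD
per parameter, because group-specific scales introduce group × factor
interaction dimensions and destroy the exact low rank. Pooled discovery
data then span exactly 11 dimensions (10 factors + the EOP/LOP mean
contrast), yielding 11 retained components and 17 residual parameters at
the default ε — the study's geometry. The preset trades per-group SD
fidelity for rank fidelity; per-group moment guarantees apply to the
independent preset only.

Contamination ("hidden noise") model: each targeted patient × parameter
cell is perturbed independently with probability π (default 0.3) in the
target groups (default EOP only, matching the hypothesis that noise
concentrates in the rapid-progression group). `bimodal` mode displaces
the value by ±displacement × group-SD (default 3, random sign);
`heavy_tail` mode inflates the deviation from the group mean by
exp(displacement·|N(0,1)|) — defined on deviations rather than raw values
so near-zero-mean parameters (IgG titers) are actually perturbed.
Contamination is applied to the rounded table and re-rounded, keeping the
output at recorded precision and the injection auditable.

What the generator does *not* emulate: recorded-value granularity coarser
than 2 decimals (real assay columns have far fewer distinct values, which
is what made the original entropy screen selective — see above);
longitudinal dynamics; any mechanistic immune model; non-random
missingness (the I/O layer rejects missing values outright). Passing
synthetic tests therefore demonstrates that the machinery recovers
injected anomalies under the study's geometry and sizes, not that the
original biological findings generalize.

## Numerical choices and degenerate inputs

- Standardization uses sample (n−1) SDs; constant columns are a hard
  error naming the parameter (they carry no information and would divide
  by zero downstream).
- PCA reconstruction (loadings · diag(λ) · loadingsᵀ = R) and trace
  conservation (Σλ = p) hold to 1e-8 and are tested.
- Mann-Whitney on pooled-constant data returns p = 1 by convention.
- Welch p-values are floored at 1e-300 before −log₁₀ so importance stays
  finite when a parameter is constant within each cluster but differs
  between them.
- Merge ties in the agglomeration and vote ties in k-NN are broken
  deterministically (first minimal pair; single nearest neighbor), so a
  fixed seed reproduces every output byte for byte.
- All randomness (sampling, contamination, k-means initialization, CV
  folds) flows from explicit integer seeds; the contamination stream is
  spawned from the generator seed so the clean cohort is unchanged by
  toggling contamination.

## Problem sizes used in the checks

The validation suite runs at the study's own scale: 111 discovery + 51
validation patients, 28 parameters, 20-seed Monte-Carlo replications for
the recovery properties (entropy flag recovery, bottom-rank placement of
injected anomalies, CV sensitivity/specificity ≥ 0.75), and
n = 10,000/group for generator moment recovery. LOF is verified against a
loop-based reference and scikit-learn's implementation on ~100 random
instances up to n = 60, d = 6.

## Known limitations

- The dominant-parameter reading of "components as parameters" is one of
  several possible formalizations; the original component-extraction
  heuristic is not recoverable from the published text. Both ε and the
  assignment rule are exposed as configuration.
- The entropy screen saturates on finely-recorded continuous data (see
  above); with the default precision it is a ceiling check rather than a
  ranking, and the clustering importance carries the discrimination.
- The absolute importance values are not comparable to other software's
  importance transforms; only the ranking is.
- Classification quality degrades when corroboration under-selects
  (1–2 features): single-parameter LOF is noisy. The pipeline reports the
  feature list in its manifest so such runs are visible.
- The validation cohort enters only the entropy stage by design; no
  classifier is ever fit on it.
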