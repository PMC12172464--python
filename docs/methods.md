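# Methods

This note records the modelling conventions and algorithmic choices
implemented in `microtensor`, in the order the analysis runs.

## Data cube

A longitudinal study is arranged as a three-way array `X` of shape
subjects (I) × features (J) × time points (K). A (subject, time) pair with
no measurement becomes an all-missing fiber (`NaN`); a feature absent from a
measurement that did take place is an observed zero. The boolean
`observed_mask` is the complement of missingness and is carried through all
later stages; raw counts are retained alongside any transformed values so
that abundance-level tests remain possible after preprocessing.

Per-feature sparsity is the fraction of observed entries that are zero,
computed on counts, either overall or within subject groups.

## Preprocessing

Applied in this fixed order by `process_data_cube`:

1. **Centered log-ratio (CLR) transform**, per measurement:
   `clr(x)_j = ln((x_j + p) / g(x + p))` with pseudocount `p` (default 1) and
   `g` the geometric mean over the **full** feature set of that measurement.
   Alternatively, zeros can be replaced by uniform(0, 1) draws instead of
   adding a constant. Each observed measurement sums to zero afterwards.
2. **Sparsity filtering.** A feature is kept when its sparsity is at most
   the threshold; under the per-group scope the minimum across groups is
   used, so a feature common in any one group survives. Filtering happens
   *after* the CLR transform so the geometric mean reflects the whole
   composition.
3. **Centering across the subject mode**: the observed mean of each
   (feature, time) column is subtracted, removing offsets common to all
   subjects.
4. **Scaling within the feature mode**: each feature slab is divided by its
   observed root mean square, giving every feature equal leverage.

Centering across other modes and scaling within the subject mode are
available; combining centering across one mode with scaling within another
is the standard compatible pairing for multi-way arrays.

## PARAFAC model and fitting

The model is `x[i,j,k] = Σ_f λ_f a[i,f] b[j,f] c[k,f] + e[i,j,k]` with
loading matrices `A (I×F)`, `B (J×F)`, `C (K×F)` and positive weights `λ`.

**Alternating least squares.** Each sweep solves the three linear
least-squares problems in turn via the Khatri–Rao normal equations, e.g.
`A ← X(1) (B ⊙ C) [(BᵀB) ∘ (CᵀC)]⁻¹`, where `X(n)` is the mode-n unfolding
(remaining axes flattened in C order), `⊙` the column-wise Khatri–Rao
product, and `∘` the Hadamard product. A tiny ridge (1e-12) guards the F×F
solve, with a warning when the Gram matrix is ill-conditioned.

**Missing data.** Fitting uses expectation–maximization: before every sweep
the missing entries are filled with the current model reconstruction
(initially zero), so each ALS update is exact for the completed tensor and
the observed-entry sum of squared errors (SSE) is non-increasing.

**Convergence** is declared when the relative change in observed-entry SSE
falls below `ctol` (default 1e-4, at most `maxit = 500` sweeps). With heavy
missingness the EM iteration approaches its fixed point geometrically, so
very tight tolerances may never trigger; the default is chosen to converge
at the missingness levels seen in practice (tested at 62.5 % missing
fibers).

**Normalization convention.** After fitting, all loading columns have unit
norm, `λ_f ≥ 0` absorbs the scales, components are ordered by decreasing
`λ`, and signs are fixed by requiring non-negative time-mode column sums
(compensating flips go to the subject mode).

**Multi-start.** ALS only finds local optima, so `multi_start_fit` runs
`n_starts` random initializations and returns the converged start with the
highest variance explained. Per-start seeds derive from the master seed via
`SeedSequence([seed, index])`, so results are reproducible and adding starts
never changes existing ones. A deterministic SVD-based initialization (the
leading singular vectors of each unfolding) is available and is used where
determinism matters more than global search, e.g. in the jackknife.

**Variance explained** is `100 · (1 − SSE/SSX)` over observed entries only.

## Model selection diagnostics

- **Scree/variance explained** over a grid of component numbers, with
  per-start records to expose local-optimum scatter.
- **CORCONDIA** (core consistency): the least-squares Tucker core for the
  fixed loadings (weights absorbed into the subject mode) is compared with
  the unit superdiagonal; `100 · (1 − Σ(g − t)²/F)`. Values near 100 support
  trilinearity, values below ~50 indicate overfactoring. Under missingness
  the EM-completed tensor is used. Starts whose collapsed components make
  the core regression rank-deficient are recorded as NaN in the quality
  grid.
- **Within-mode Tucker congruence**: the maximum absolute congruence
  `φ(x, y) = ⟨x,y⟩ / (‖x‖‖y‖)` between distinct components of one mode;
  values near 1 flag two-component degeneracies.
- **Jackknife stability** (`assess_model_stability`): repeatedly refit with
  one subject per group removed (balanced removal across a grouping
  variable), align each refit to a deterministic full-data reference by
  Hungarian matching on the product of per-mode congruences, and report
  per-element loading standard deviations. Overfactored models show
  markedly larger SDs.
- **Factor match score** between two models: the mean over matched
  components of `|φ_A · φ_B · φ_C|`.

## Post-hoc interpretation

- **Per-feature fit**: variance explained of each feature slab and the
  congruence between the feature's observed and fitted values. Features are
  *well-modelled* when their variance explained is at least the mean across
  features and their congruence is at least 0.4 (both inclusive).
- **Transformed loadings**: `B̃ = B diag(λ) M^{1/2}` with
  `M = (AᵀA) ∘ (CᵀC)`, so inner products of rows of `B̃` equal inner
  products of the features' fitted subject × time trajectories. Distances in
  this space are therefore model-implied trajectory distances.
- **Clustering**: PAM-style k-medoids (best of 50 random starts) on the
  transformed loadings of well-modelled features; the number of clusters is
  chosen by maximum silhouette width, with within-cluster sum of squares and
  the gap statistic reported alongside.
- **Cluster abundance tests**: per (cluster, time point), each subject's
  statistic is the cluster's share of total counts; the group contrast uses
  the absolute difference of group means with a label-permutation null
  (default 999 permutations, add-one two-sided p-values), followed by
  Benjamini–Hochberg correction across time points within each cluster.
- **Loading–metadata association**: subject loadings vs binary variables by
  Wilcoxon rank-sum, vs continuous variables by Pearson correlation, with
  Benjamini–Hochberg correction across all tested pairs.

## Synthetic data

- `simulate_trilinear`: Gaussian loadings, known rank, additive Gaussian
  noise; returns the cube plus ground-truth loadings and noise-free signal.
- `simulate_mock_counts`: a mock intervention study (default 25 cases, 25
  controls, 10 time points, 3 taxa, sequencing depth 10 000). Cases ramp one
  taxon exponentially and controls another sigmoidally, scaled by an effect
  size (0 ⇒ exchangeable groups); subject-specific factors add realistic
  between-subject variation; counts are multinomial at fixed depth.
- `apply_missingness`: masks a requested fraction of (subject, time) fibers
  while guaranteeing every subject and every time point keeps at least one
  observation.
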