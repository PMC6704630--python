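# Methods

## Model

Let x ∈ ℝ<sup>p</sup> be a log2-scale expression profile over p genes
(with the sentinel −1 at absent entries) and k ∈ {1..K} a cell-type
label. The classifier is multinomial logistic regression with per-class
scores s<sub>k</sub>(x) = β<sub>0k</sub> + xᵀβ<sub>·k</sub> and
posterior softmax(s). Fitting minimizes

    −(1/N) Σᵢ [ s_{yᵢ}(xᵢ) − log Σₖ exp(s_k(xᵢ)) ] + λ Σⱼ Pⱼ

with the grouped elastic-net penalty
Pⱼ = (1−α)/2‖β<sub>j·</sub>‖₂² + α√K‖β<sub>j·</sub>‖₂ (default), or
the ungrouped variant with ‖β<sub>j·</sub>‖₁ in place of the group
norm. The √K scaling makes the group threshold comparable across class
counts and reproduces the all-in/all-out sparsity pattern of grouped
multinomial fits. Binary models (signature step) use a single
coefficient vector with the scalar ℓ₁/ℓ₂ mixture. Intercepts are never
penalized; predictions are invariant to adding a constant to all class
scores.

With `standardize=True` (default) the penalty applies to features
scaled to unit population variance (1/N), as computed on the
−1-encoded matrix — the dummy entries pass through the same
standardization as real values, matching the fact that the fit itself
sees them as data. Coefficients are returned on the input scale.

## Solver

The objective is minimized by an accelerated proximal-gradient
iteration (FISTA) with gradient steps on the smooth multinomial /
logistic loss and an exact proximal map for the penalty: group soft-
thresholding (grouped), scalar soft-thresholding (ungrouped/binary),
each combined with the ridge shrinkage factor. Details:

* Step size 1/(1.05·L), where L = h·σ²<sub>max</sub>([X, 1])/N with
  h = 1/2 (multinomial) or 1/4 (binary) — the standard curvature bounds
  for these losses — and σ<sub>max</sub> obtained by deterministic
  power iteration.
* Adaptive restart: when the objective would increase, momentum is
  dropped and a plain descent step is taken from the current iterate,
  making the iteration monotone in practice.
* Convergence when the relative objective change falls below `tol`
  (default 1e-7); hitting `max_iter` flags the model and warns instead
  of failing.
* λ grids are fitted from the largest penalty downward with warm
  starts; at λ ≥ λ<sub>max</sub> (computed in closed form from the
  intercept-only residuals) the solution is exactly intercept-only
  because the proximal map holds the zero block fixed.

Zeroing is exact (the proximal map returns literal zeros), so
nonzero-gene counts and the grouped all-or-nothing pattern are
structural, not thresholded. On fixed tiny instances the solver's
objective agrees with an independent multi-start quasi-Newton
optimizer of the same objective to 1e-6 across α ∈ {0, 0.5, 0.93, 1}
and both penalty variants (see the test suite).

## Preprocessing chain

Order is fixed and recorded: low-expression filter → within-lane GC
normalization → between-lane full-quantile normalization → second
filter pass (same rule) → log2(v+1). The filter keeps genes with at
least `min_count` (default 5) in at least `min_samples` non-missing
entries (5 for the bulk-immune setting, 4 for small cohorts).
Normalization is intended to be fit separately per sample group
(train/test are never normalized jointly), which the pipeline driver
enforces.

**Within-lane GC normalization.** Per sample, a lowess smoother
(local-linear, span 0.3 by default) of log(count + 0.5) on GC fraction
is fitted over non-missing genes; the fitted trend is subtracted and
the residuals are re-anchored so the sample's median log count is
preserved, then mapped back to counts (clipped at zero). The +0.5
offset admits zero counts inside the smoother while the user-facing
transform stays exactly log2(v+1). A GC-bin-median fallback
(`method="median_bin"`) is exposed for degenerate inputs. Samples with
fewer than 20 observed genes are rejected (the smoother is
unidentifiable). A constant-count sample is a fixed point of the
operation; a planted log-linear GC trend is removed essentially
completely (local-linear smoothers reproduce linear functions).

**Full-quantile normalization.** Every sample's non-missing values are
replaced by a common reference — the across-sample mean of quantile
functions evaluated on a shared grid — at the value's (average, for
ties) rank. With no missing values this is exactly the mean of order
statistics, making sorted columns identical and the operation
idempotent. Ties receive the average of their assigned quantile
values; datasets with cross-sample ties therefore trade exact
distribution equality for rank symmetry (documented behaviour of this
tie rule). Missing entries are excluded from rank computation and
never modified.

## Missing values and augmentation

Source matrices merged from heterogeneous studies have genuinely
missing genes. Rather than imputing means, absent entries are encoded
with the dummy constant −1 (all real log2 values are ≥ 0, so the
sentinel is unambiguous) and the training set is augmented: duplicated
`duplication_factor` (100) times with an independent
`dropout_fraction` (10%) of the observed entries knocked out to −1 in
each replicate. The model thereby learns to treat −1 as uninformative
noise. Augmentation applies to training data only; test samples carry
the plain −1 encoding of genuinely missing entries. The expected
dummy fraction of the augmented matrix is m + 0.1(1−m) for original
missing fraction m.

## Lambda selection by bootstrap-negative ROC

For each λ on the grid {0.1, 0.05, 0.01, 0.005, 0.001, 0.0005, 0.0001}
the fitted model scores (a) the real held-out samples and (b) an equal
number of bootstrap synthetic negatives built gene-wise: each synthetic
sample draws, independently per gene, that gene's value from a random
real test sample. Marginals are preserved; cross-gene (biological)
correlation is destroyed. The score is the maximum class posterior
(in [1/K, 1]); sweeping its threshold yields a ROC whose trapezoidal
area scores the λ. Two selection rules are provided:

* `max_auc_smallest_lambda` (default): among λ with AUC within 1e-3 of
  the maximum, the smallest — keeps the most genes at maximal AUC,
  feeding the signature step.
* `inflection`: the λ maximizing AUC with ties resolved to the larger
  λ — the point beyond which tightening the penalty costs AUC.

If all AUCs tie within tolerance the rule is degenerate; the smallest
λ is returned with a warning. K-fold cross-validated deviance
(stratified, seeded) can be computed alongside as a diagnostic; λ
selection itself always uses the ROC rule.

## Signatures

For each cell type, both splits are restricted to the parent
classifier's selected genes, labels become one-vs-rest, training data
are augmented identically, and a binary elastic net is fitted along
the same λ grid. Each λ is scored by ROC with positives = held-out
samples of the type (class-1 probability) and negatives = bootstrap
synthetic samples; λ entries whose models are empty are excluded
before selection, and an entirely empty grid is an error. One-vs-rest
AUC against the real held-out negatives is reported as a diagnostic.
Signature genes are by construction a subset of the parent selection;
negative coefficients flag genes whose expression argues against the
type. On cleanly separable synthetic fixtures most λ values tie at
AUC 1, so the tie rule keeps many genes; the two-step *compaction*
seen on noisy real data (hundreds of classifier genes shrinking to
tens per signature) emerges only when separability is imperfect.

## Single-cell annotation and composition

Cells are aligned to the model's gene panel (error if fewer than 50%
of model genes are present, configurable); genes the cells lack are
encoded −1; counts are log2(v+1)-transformed. Between-lane quantile
normalization is skipped by default — cells are not bulk lanes — and
can be restored with a flag. Every cell is assigned the argmax
posterior (ties → first class in model order); an optional confidence
floor relabels low-confidence cells "unassigned" but defaults to 0
(always assign). Compositions are percentages per specimen over
annotated cells, with zero-count classes present explicitly.

Composition matrices feed a centered SVD-based PCA whose component
retention is calibrated by a parallel-analysis style negative control:
each column is permuted independently `n_scrambles` (100) times, and
components are kept only if their explained-variance fraction exceeds
the *largest* leading-component fraction observed across scrambles
(the strictest of the common variants; deterministic given the seed).
Hierarchical clustering of composition rows uses euclidean distances
with Ward linkage by default and a user-supplied cluster count.

## Benchmarking

Expression is binarized at strictly greater than 2.48 on the log2
scale (missing = not expressed); the boundary value itself is "not
expressed". Each gene set is scored per sample by the one-sided
enrichment hypergeometric p-value of the (in-set × expressed) 2×2
table; −log10 p is the score. The negative control resamples each
gene's values with replacement across samples (preserving per-gene
marginals and missingness rates, destroying cross-gene structure).
Per bootstrap iteration (1000 by default) a fresh scrambled dataset
provides negatives and one ROC per set is computed — positives are the
real samples of the matching cell type when the set name matches a
label, otherwise all real samples — then interpolated to a fixed
101-point FPR grid. The summary is the pointwise mean curve with
percentile confidence bands (95% by default), widened minimally where
discrete TPR distributions would place the mean outside an empirical
quantile, and the mean AUC. Fewer than 30 input samples triggers a
bootstrap-validity warning; a gene set disjoint from the universe is
flagged, not silently dropped. One-sidedness is a deliberate choice:
enrichment is the discriminative direction for presence-of-type
scoring.

## Synthetic data generator

The generator emulates what the pipeline assumes about merged
multi-study reference profiles:

* per-gene baselines log2-uniform on [2, 9] (≈ 4–512 counts);
* negative-binomial counts with dispersion θ = 10 (variance
  m + m²/θ — moderate overdispersion typical of bulk RNA-seq);
* two marker styles per cell type: 20 *over-expressed* markers
  (×8 in their type, optionally also silenced elsewhere via
  `marker_off_attenuation`) and 10 *absent-in-type* markers (×0.02 in
  their own type, baseline elsewhere), exercising positive and negative
  classifier coefficients respectively;
* three simulated studies with multiplicative GC bias
  exp(b_s(gc−0.5)), b_s spread over ±1, and a ±0.5 log2 library-scale
  spread — the targets of the two normalization steps;
* 5% missing-completely-at-random entries;
* single cells drawn from the same generative model with an extra
  dropout process (each value zeroed with probability 0.3 by default)
  and per-specimen type compositions.

Defaults (5 types × 40 samples × 2000 genes) are the study conditions
for the flagship end-to-end checks; they were chosen to be solvable on
one CPU in minutes while leaving the recovery properties
(≥ 95% held-out accuracy, ≥ 80% marker recovery, ≥ 90% negative signs
on absent-in-type genes) non-trivial. What the generator does *not*
emulate: realistic gene–gene correlation beyond the planted markers,
compositional library-size effects, batch effects other than
GC/scale, structured (non-MCAR) missingness, and real immune
transcriptome covariance. Passing tests demonstrate that the machinery
recovers planted structure under the stated noise model, not
performance on real data.

## Numerical and design notes

* All randomness flows through `numpy.random.default_rng` seeds; the
  CLI derives per-stage seeds from the global seed and stage name, so
  reruns are bitwise identical.
* Argmax ties in prediction resolve to the first class in model order.
* Gene identifiers match by exact string; no alias resolution.
* NA tokens accepted on read: `NA`, `NaN`, empty; written as `NA`.
  Sparse (MTX) zeros are zeros, not missing; duplicate coordinates sum.
* Expression units are treated as generic non-negative counts; sources
  mixing FPKM/TPM/counts are normalized by the chain rather than
  converted.
* The ROC confidence score (max posterior) and the number of synthetic
  negatives (= test-set size) are configuration-visible choices; the
  selection procedure does not prescribe them beyond "accuracy of
  predicting the true positives".

## Known limitations

* The solver is dense; very large augmented matrices are handled by
  streaming nothing — memory is O(N·p).
* Quantile normalization with heavy cross-sample ties does not produce
  exactly identical sorted columns (tie rule, above).
* The scrambled-control PCA threshold uses the max across scrambles;
  with few scrambles it is noisy for borderline components.
* Signature size on perfectly separable data stays close to the parent
  selection (see Signatures).
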