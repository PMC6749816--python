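# Methods

## Problem and model

`hetmc` predicts latent disease–lncRNA associations by matrix
completion on a *heterogeneous bilayer network*.  Given `m` diseases,
`n` lncRNAs, an integrated disease similarity matrix `DS` (m×m), an
integrated lncRNA similarity matrix `LS` (n×n) and a binary association
matrix `DL` (m×n, 1 = experimentally supported, 0 = unknown), the
bilayer adjacency is the symmetric block matrix

    A = [[DS, DL],
         [DL^T, LS]]       (N × N,  N = m + n).

A zero in `DL` never means "verified negative": curated catalogues only
record positives, so the zeros are blanks.  The modelling assumption is
that a small number of latent factors drives both the associations and
the similarities — similar diseases tend to interact with similar
lncRNAs — so the ideal `A` is (approximately) low rank, and the blanks
can be filled by the nuclear-norm relaxation of rank minimization

    min ||A*||_*   s.t.   P_Phi(A*) = P_Phi(A),

where `Phi` is the observed index set: **all** similarity-block entries
(similarities are computed, hence known, zeros included) plus exactly
the 1-entries of the association blocks, so |Phi| = m² + n² + 2·nnz(DL).
The completed association block (the average of the two mirrored
off-diagonal blocks, clipped to [0, 1]) ranks every unknown pair.

## Solver

The linearized Bregman / singular-value-thresholding (SVT) iteration:

    X_i = shrink(Y_{i-1}, tau),     shrink: sigma -> max(sigma - tau, 0)
    Y_i = Y_{i-1} + delta * P_Phi(A - X_i),      Y_0 = c * delta * P_Phi(A)

with data-driven defaults

    delta = N / |Phi|,
    tau   = ||P_Phi(A)||_F · N / |Phi|,
    c     = ceil( tau / (delta · ||P_Phi(A)||) ),

the norm in `c` read as the spectral norm (Frobenius selectable).
Iteration stops when the relative Frobenius residual on `Phi` drops to
`epsilon` (default 0.4; a mean-absolute-error rule is selectable) or at
`max_iter` (default 5000 — the default `delta` is small when the
similarity blocks dominate `Phi`, so many cheap steps are normal; an
explicit `delta` override exists).

The inner partial SVD has two backends:

* `exact` — full SVD, the reference;
* `rsvd_bki` — randomized block-Krylov iteration: project onto the
  span of `[M·Om, (MM^T)M·Om, …, (MM^T)^p M·Om]` for a Gaussian test
  matrix `Om` with `k + oversampling` columns (defaults p = 2,
  oversampling = 10), orthonormalize, solve the small projected SVD.
  Across SVT iterations the right singular basis found at iteration *i*
  seeds `Om` at iteration *i + 1* (subspace reuse).  One RNG seeded
  from the config governs every Gaussian draw, so runs are bit
  reproducible.

The shrink rank adapts: start at `rank_start` (10) singular values,
grow by `rank_increment` (5) while the smallest computed value still
clears `tau`, capped at ⌊N/2⌋.  An optional rule doubles `p` when two
successive shrink calls disagree on the smallest retained singular
value by more than 1%.

### Two parameter regimes, deliberately

The data-driven `tau` above is small (order 1), so the exact fixed
point of the iteration is close to the *minimum-Frobenius-norm*
interpolant of the observed entries: held-out entries get small
absolute values.  That is fine — intended, even — for the ranking
pipeline, where early stopping at a coarse `epsilon` acts as the
regularizer and only the *ordering* of scores matters.  It does not
recover held-out *values*.  For value-recovery benchmarks on genuinely
low-rank matrices the package therefore uses the classical SVT
parameterization `tau = 5N`, `delta = 1.2·N²/|Phi|` (strong nuclear
pull, rank-r fixed point).  `recovery_experiment(mode="latent")`
applies the classical regime; the pipeline (`BilayerLinkPredictor`,
CLI, cross-validation) uses the data-driven defaults.  We verified the
distinction empirically: on a rank-4 bilayer instance (N = 110, 40% of
the association block observed) the classical regime recovers held-out
values to ~4% relative error with the iterate rank settling at exactly
4, while the data-driven regime fits the observed entries and leaves
held-out magnitudes shrunk by an order of magnitude regardless of
`epsilon`.

## Similarity measures

* **Profile cosine** (diseases or lncRNAs): cosine of binary
  interaction-profile vectors.  All-zero profiles get similarity 0 to
  everything including themselves (0/0 carries no information).
* **Term-set Jaccard**: |G_i ∩ G_j| / |G_i ∪ G_j|; two empty sets
  score 0 (no evidence), not 1.
* **DAG semantic similarity**: each disease's profile is its annotated
  nodes plus ancestors with contribution `decay^depth` (decay 0.5 by
  default, maximum over annotated nodes/paths); similarity is the
  shared contribution mass over the two total semantic values.  A
  precomputed matrix can be supplied instead, bypassing the kernel
  choice entirely.
* **Sequence similarity**: global Needleman–Wunsch alignment scores
  under EDNAFULL (match 5 / mismatch −4, IUPAC ambiguity scores as
  published), gap open 10, gap extend 0.5 — a gap of length L costs
  10 + 0.5L, end gaps penalized.  Normalization
  `NW(i,j)/sqrt(NW(i,i)·NW(j,j))` (the geometric-mean denominator is
  the only reading that makes self-similarity exactly 1), negative raw
  cross-scores clamped to 0 first.  Whether the original EMBOSS runs
  penalized end gaps is not recorded anywhere we could check; we fix
  end-gap penalties *on* so that scores are reproducible and
  self-scores equal the diagonal sum.
* **Expression similarity**: |Spearman rho| with average ranks for
  ties; constant rows are isolated (0 off-diagonal, 1 diagonal).
  Optional normalization of raw expression tables is left to the
  caller (log2(x+1) and centering are one line of numpy); the
  similarity itself is rank-based and invariant to monotone
  transforms.
* **Functional similarity of lncRNAs**: best-match average of disease
  semantic similarities across the two associated disease sets;
  lncRNAs with no associated disease are isolated.
* **Integration**: `w·S_source + (1−w)·S_cosine`, weights tuned on a
  0.1…1.0 grid by cross-validation AUC, ties broken toward the larger
  weight (more mass on the non-cosine source).

Every similarity output is symmetric to 1e−10, bounded in [0, 1], and
label-aligned to the association matrix (readers reindex and error on
missing ids rather than dropping them).

## Cross-validation harness

LOOCV hides each known pair in turn (both mirrored entries leave
`Phi`); k-fold CV hides shuffled folds whose sizes differ by at most
one ("strictly equal" folds are impossible when k does not divide the
number of knowns; the remainder is spread one per fold).  Global
protocols rank a hidden pair against all unknown pairs of the training
matrix (excluding the other hidden pairs of the same fold); the local
protocol ranks within the hidden pair's disease row only.  Fold scores
are pooled as normalized average ranks and AUC/AUPR computed on the
pooled list (a per-fold-average AUC is available via the per-repeat
spread of `kfold_cv`).  Ties get average ranks in AUC and lexicographic
id order in emitted rank lists, so output files are deterministic.

The permutation contribution test randomizes one input at a time —
similarity blocks by symmetric label permutation (symmetry and unit
diagonal preserved), the association matrix by reshuffling its
1-positions uniformly (count preserved, degree structure not) — and
records the held-out AUC over 20 repetitions.  The input whose
permutation collapses the AUC furthest toward 0.5 contributes most; in
our synthetic conditions that is the association matrix, followed by
the disease similarities.

## Synthetic data generator

`SyntheticSpec(m, n, r, density, noise_sd=0.05, prevalence=0.02, seed)`
draws non-negative factors `U` (m×r), `V` (n×r) as |N(0,1)|,
row-normalizes them, and defines **one** latent affinity
`Z = U_hat V_hat^T` (rank exactly r, values in [0, 1]) that drives
everything: true associations are the top `prevalence` quantile of `Z`;
`DS`/`LS` are the Gram matrices of the same normalized factors plus
symmetric N(0, noise_sd²) noise (clipped, unit diagonal); each true
association is revealed with probability `density`.  Defaults:
prevalence 0.02 matches the 1–3% density of curated disease–lncRNA
catalogues; noise_sd 0.05 leaves similarities informative but not
oracle-clean; density 0.4 leaves a majority of true pairs hidden for
evaluation.

What the generator does **not** emulate: hub/degree structure of real
catalogues (a handful of intensively studied cancers and lncRNAs),
ascertainment bias in which pairs get tested, block structure of MeSH
DAGs, or real sequence families.  Passing tests therefore show the
machinery is correct under the model's own assumptions, not that the
headline accuracy transfers to any particular database snapshot.

## Numerical choices and edge cases

* Completed scores are clipped to [0, 1] before ranking; clipping can
  only create ties at the boundaries.
* Similarity inputs may be asymmetric up to 1e−8 (symmetrized as
  (S+S^T)/2); larger asymmetry is an error.
* `rsvd_bki` clamps a requested rank above min(m, n) with a warning;
  per-block QR re-orthonormalization keeps the Krylov basis stable at
  p ≥ 2.
* Non-finite iterates abort with the iteration index; hitting
  `max_iter` returns the current iterate flagged `converged=False`.
* Sparsity figures are truncated (not rounded) to 4 significant
  figures, the convention used in the catalogue summary tables.
* Problem sizes in tests and the acceptance script (N = 60–110
  bilayer matrices, 20 permutation repetitions, 200-fold shrink
  checks) were chosen as the smallest instances where the planted
  structure is comfortably detectable.

## Known limitations

* The positive semi-definiteness sometimes claimed for bilayer
  adjacencies does not hold for arbitrary integrated similarities and
  is nowhere assumed.
* The data-driven parameter formulas make the solver a ranker, not a
  value estimator (see "Two parameter regimes"); interpret pipeline
  scores ordinally.
* No GPU path, no out-of-core matrices, no alternative nuclear-norm
  solvers (ADMM, softImpute); the bilayer matrices this package
  targets fit comfortably in memory.
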