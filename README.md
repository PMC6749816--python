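# hetmc

Prediction of latent disease–lncRNA associations by **faster
singular-value-thresholding (SVT) matrix completion** on a
heterogeneous bilayer network.

Curated catalogues of experimentally supported disease–lncRNA links
are tiny (1–3% of all pairs) and record positives only — a zero means
"untested", not "no association".  `hetmc` treats candidate
prioritization as a recommender problem: diseases and lncRNAs are
joined into one network whose adjacency matrix

```
A = [[DS, DL],
     [DL^T, LS]]
```

stacks a disease-similarity block `DS` (semantic / term-set Jaccard /
interaction-profile cosine), a lncRNA-similarity block `LS` (sequence /
expression / functional / cosine) and the binary association matrix
`DL`.  Unknown `DL` entries are recovered by nuclear-norm minimization,

```
min ‖A*‖_*   s.t.   P_Φ(A*) = P_Φ(A),
```

solved with the SVT / linearized-Bregman iteration
`X_i = shrink(Y_{i-1}, τ)`, `Y_i = Y_{i-1} + δ·P_Φ(A − X_i)`, where the
inner partial SVD is a **randomized block-Krylov** scheme whose test
matrix is re-seeded each iteration with the previous singular basis
(subspace reuse).  Completed scores rank every untested pair; the
package also ships the full similarity toolbox, global/local LOOCV and
k-fold cross-validation, a permutation-based data-source diagnostic,
and a seeded synthetic-data generator so everything is testable
offline.  See `docs/methods.md` for the model, parameters and design
choices.

## Worked example

```python
import numpy as np
from hetmc import (SyntheticSpec, generate, BilayerLinkPredictor,
                   SVTCompleter, roc_pr_from_scores)

spec = SyntheticSpec(m=60, n=50, r=4, density=0.4, seed=7)
ds = generate(spec)                       # 25 revealed, 35 hidden true pairs

est = BilayerLinkPredictor(completer=SVTCompleter(epsilon=0.05), random_state=7)
est.fit(ds.observed, ds.DS, ds.LS)        # build A, complete, extract scores

obs = ds.observed.values.astype(bool)
hidden = (ds.truth == 1) & ~obs
res = roc_pr_from_scores(est.scores_[hidden], est.scores_[ds.truth == 0])
print(est.completer_.n_iter_, est.completer_.converged_)
print(f"held-out AUC {res.auc:.3f}  AUPR {res.aupr:.3f}")
```

prints

```
177 True
held-out AUC 0.691  AUPR 0.078
```

i.e. the completion converged in 177 SVT steps and ranks the 35 true
associations it never saw well above the 2 940 never-true pairs
(AUC 0.69 against a 0.5 chance baseline; AUPR 0.078 against a 0.012
positive rate).  On the same instance the value-recovery benchmark —
the association block carrying the rank-4 latent affinity, 40% of its
cells observed — reconstructs the held-out values to 3.9% relative
error with AUC 0.98:

```python
from hetmc import recovery_experiment
rec = recovery_experiment(spec, mode="latent")
print(f"{rec['relative_error']:.4f} {rec['auc']:.3f}")   # 0.0385 0.977
```

The same pipeline is scriptable from the shell:

```
hetmc simulate --m 60 --n 50 --rank 4 --density 0.4 --seed 7 --out data/
hetmc predict --associations data/associations.tsv \
              --disease-sim data/DS.tsv --lncrna-sim data/LS.tsv \
              --seed 7 --out predictions.tsv
hetmc evaluate --associations data/associations.tsv \
               --disease-sim data/DS.tsv --lncrna-sim data/LS.tsv \
               --protocol kfold --k 5 --seed 7
```

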