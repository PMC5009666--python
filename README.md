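# bregnmf

Robust non-negative matrix factorization for data with missing values and
outliers, built for gene-expression analysis (bulk or single-cell panels,
qPCR arrays) and any other naturally non-negative data where a few gross
corruptions and holes would otherwise wreck a low-rank fit.

Given a non-negative matrix M (samples × features) observed on an index
set Ω, the package solves

    min_{Y, S, U≥0, V≥0}  ½ Σ_{(i,j)∈Ω} (Y_ij − (UV^t)_ij)²  +  λ‖S‖₁
    subject to            M = Y + S  on Ω,

so that Y is a denoised, completed version of the data, S is a sparse
matrix that isolates outliers, and U V^t is a rank-r non-negative
factorization whose columns act as interpretable features.  The factors
are updated by an entropic Bregman-proximal (mirror-descent-type) scheme
that keeps them positive without projections; Y and S have closed-form
updates (averaging and soft-thresholding); everything is tied together by
an augmented-Lagrangian ADMM.  The sparsity weight λ is chosen by
entrywise holdout cross-validation: artificially declare a few observed
entries missing, and pick the λ that best predicts them.

See `docs/methods.md` for the full model, parameter meanings and
numerical details.

## Worked example

```python
import dataclasses
import numpy as np
from bregnmf import (SolverConfig, make_toy, inject_outliers, inject_missing,
                     robust_nmf_admm, select_lambda, cluster_index)

# rank-3 non-negative ground truth, 5% spikes at 10x data RMS, 10% missing
inst = make_toy(d=40, n=30, r=3, seed=0)
inst = inject_outliers(inst, fraction=0.05, magnitude=10.0, seed=1)
inst = inject_missing(inst, fraction=0.10, seed=2)
M = inst.M_observed

cfg = SolverConfig(rank=3, seed=3)
report = select_lambda(M, cfg, n_points=15, seed=4, repeats=3)
print(f"selected lambda = {report.selected:.4f}")

dec = robust_nmf_admm(M, dataclasses.replace(cfg, lam=report.selected))
support = dec.S != 0
truth = inst.S_true != 0
tp = (support & truth).sum()
print(f"outliers flagged: {support.sum()} (precision "
      f"{tp / support.sum():.2f}, recall {tp / truth.sum():.2f})")

missing = ~M.observed
rmse = np.sqrt(np.mean((dec.Y[missing] - inst.M_clean[missing])**2))
rms = np.sqrt(np.mean(M.values[M.observed]**2))
print(f"imputation RMSE on missing entries: {rmse:.3f} "
      f"({100 * rmse / rms:.1f}% of data RMS)")
print(f"first ten cluster labels: {cluster_index(dec.factors.U)[:10]}")
```

Output:

```
selected lambda = 0.3334
outliers flagged: 51 (precision 1.00, recall 0.85)
imputation RMSE on missing entries: 0.042 (2.2% of data RMS)
first ten cluster labels: [2 3 2 2 1 3 2 3 1 2]
```

The cross-validated λ lands where the sparse matrix S flags exactly the
injected corruptions (every flagged entry is a true spike; the handful it
misses are negative spikes that the non-negativity clipping turned into
small, inherently undetectable perturbations — see `docs/methods.md`).
The completed matrix Y recovers the held-back entries to about 2 % of the
data's RMS, and each sample's dominant factor gives its cluster label.

## Command line

The same pipeline is available from a shell.  Orientation must be given
explicitly (`samples-rows` or `samples-cols`); internally rows are always
samples, so U carries sample loadings and V feature loadings.

```sh
bregnmf simulate --d 40 --n 30 --rank 3 --outlier-frac 0.05 \
        --missing-frac 0.1 --seed 0 --output-dir sim/
bregnmf select-lambda sim/M_observed.csv --rank 3 \
        --orientation samples-rows --output-dir cv/
bregnmf factorize sim/M_observed.csv --rank 3 --lambda 0.33 \
        --orientation samples-rows --output-dir out/
```

`factorize` writes Y, S, U, V, the multipliers, the per-iteration history,
a cluster-label file and a metadata sidecar; an optional first label
column (e.g. tumor state) is carried through untouched.  Identical
invocations with identical seeds produce byte-identical outputs.

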