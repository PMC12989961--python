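# gsvdnmf — rank expansion for nonnegative matrix factorization

Nonnegative matrix factorization (NMF) decomposes a nonnegative data matrix
`X ≈ W H` (with `W ≥ 0`, `H ≥ 0`) into `r` interpretable components — ion
chromatogram/spectrum pairs in LC-MS unmixing, spectral templates in audio
spectrograms, basis images in imaging data.  Choosing `r` too small merges or
drops real sources, and the standard remedy — rerun NMF from scratch at a
larger rank — is expensive and can land in worse local optima than the
solution you already had.

`gsvdnmf` grows an existing factorization instead.  Given an under-complete
rank-`r0` NMF `(W0, H0)` of `X`, it asks the rank-`r0` truncated SVD
`X ≈ U Σ Vᵀ` — the *global* optimum of rank-`r0` factorization — what the NMF
is missing.  Concretely, it maximizes the generalized Rayleigh quotient

    E(ŷ) = ‖Σ ŷ‖² / ‖Uᵀ(W0 H0)V ŷ‖²

whose extremizers are found by the generalized singular value decomposition
(GSVD) of the pair `(Σ, Uᵀ(W0H0)V)`.  Generalized singular values `λ` far
from 1 — or infinite — mark directions where the SVD carries energy the NMF
does not: candidate missing components `y = V Q⁻ᵀ z`.  The package then

1. truncates each proposed coefficient row to its nonnegative section best
   aligned (1-norm) with the nonnegative residual `ΔX = max(X − W0H0, 0)`;
2. solves a convex least-squares problem for the matching loading columns
   `S` and nonnegative rescalers `α` of the old components (a decoupled
   closed form costing `O(mnr)`, the cost of a couple of NMF sweeps);
3. makes each new rank-1 pair nonnegative by the NNDSVD truncation;
4. rebalances all `r0+k` component amplitudes by nonnegative least squares;
5. refines the expanded factorization with a standard NMF engine
   (HALS, or multiplicative updates with a 1e-5 perturbation to avoid
   zero-locking).

The recovery step provably cannot increase the fitting error, and strictly
decreases it whenever the residual is nonzero.

## Worked example

The package ships a 2×2 worked example: a matrix `X` together with a
deliberately poor rank-2 factorization whose relative fitting error
`100·‖X − W0H0‖²_F / ‖X‖²_F` is 14.44%.  One recovery step finds the missing
direction (generalized singular value λ ≈ 2.80, far from 1) and repairs it
completely:

```
$ printf '3.0\t0.385\n0.84\t0.8087\n' > fixture.tsv
$ gsvdnmf run fixture.tsv --rank0 2 --add 1 --out result.h5
run: rank 3, 1 iterations, relative fitting error 3.511e-27%
```

The same expansion applied to a stored factorization:

```python
>>> import numpy as np
>>> from gsvdnmf import fixture_2x2, gsvd_feature_recovery, relative_fitting_error, Factorization
>>> X, W0, H0 = fixture_2x2()
>>> relative_fitting_error(X, Factorization(W0, H0))
14.438882...
>>> prop = gsvd_feature_recovery(X, W0, H0, k=1)
>>> float(prop.lambda_selected[0])
2.7965...
>>> relative_fitting_error(X, Factorization(prop.Wg, prop.Hg))
0.0
```

A rank-3 factorization of a 2×2 matrix can be exact, and the recovered
direction achieves exactly that: the error drops from 14.44% to machine
precision before any refinement.

On more realistic data — a 200×300 synthetic matrix of ten smooth
nonnegative sources plus 10% Gaussian noise (`gsvdnmf simulate`) — expanding
a rank-9 HALS solution to rank 10 beats or ties rank-10 HALS from the same
deterministic (NNDSVD) initialization in the large majority of draws, and
the expanded components track the ground-truth sources (mean matched Pearson
correlation above 0.9; see `scripts/acceptance.py` output).

## Command-line interface

| command | purpose |
|---|---|
| `gsvdnmf simulate` | generate seeded synthetic data |
| `gsvdnmf factorize` | standard NMF (HALS or MU; random/NNDSVD-family init) |
| `gsvdnmf recover` | one-shot rank expansion of a stored factorization |
| `gsvdnmf run` | full pipeline: under-complete NMF → recovery → refinement |
| `gsvdnmf expand` | incremental growth, one component at a time |
| `gsvdnmf benchmark` | paired comparison against NMF from scratch |

Matrices are read from delimited text, Matrix Market or HDF5; every run
writes a JSON manifest capturing config, seeds and per-stage logs.

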