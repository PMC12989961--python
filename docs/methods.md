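# Methods

## Model and objective

All engines minimize the squared Euclidean distance
`D(W, H; X) = ½‖X − WH‖²_F` over elementwise-nonnegative factors
`W ∈ R₊^{m×r}` (components as columns) and `H ∈ R₊^{r×n}` (components as
rows), without regularization.  Solution quality is reported as the relative
fitting error `100·‖X − WH‖²_F / ‖X‖²_F` (percent).

Convergence is declared when every component changes little between
iterates, in the relative sense

    ‖w_j⁽ᵏ⁺¹⁾ − w_j⁽ᵏ⁾‖² ≤ ϵ ‖w_j⁽ᵏ⁺¹⁾ + w_j⁽ᵏ⁾‖²,

jointly for all columns of W and rows of H.  The default tolerance is
ϵ = 1e-4 everywhere; the staged pipeline distinguishes ϵ0 (under-complete
stage) from ϵ1 (final refinement), both defaulting to ϵ.  A component that
is zero in both iterates counts as converged: a dead component is
unchanging, and any other convention would block termination.  The rule is
evaluated every iteration; the objective itself is only computed when
tracing is requested, because an objective evaluation costs as much as an
update sweep.

## Rank expansion by generalized SVD

Given an under-complete factorization `(W0, H0)` of rank `r0 ≥ 2` and the
rank-`r0` truncated SVD `X ≈ U Σ Vᵀ`, candidate missing coefficient
directions maximize `‖Σ ŷ‖²/‖Uᵀ(W0H0)V ŷ‖²`.  Rather than forming the
cross-product matrices of the equivalent generalized eigenproblem — which
squares the condition number — the pair `(Σ, Uᵀ(W0H0)V)` is decomposed by
the GSVD: stack the two `r0×r0` matrices, take a full QR factorization, and
apply the cosine–sine decomposition to the orthogonal factor
(`scipy.linalg.cossin`).  This yields `Σ = M1 D1 Qᵀ`,
`Uᵀ(W0H0)V = M2 D2 Qᵀ` with diagonal `D1, D2` and generalized singular
values `λ_i = D1[i,i]²/D2[i,i]²`.  The cross-product route survives only as
a brute-force test oracle.  Directions are ranked by λ descending; a `D2`
entry below 1e-12 of the largest classifies its λ as infinite (an exact-zero
test would be floating-point fragile), infinite values sort first in the
decomposition's native (stable) order, and ties among finite values keep
their original column order.  `Q` with condition number above 1e12 aborts
with a degenerate-pair diagnostic, since the directions `V Q⁻ᵀ z_i` would be
meaningless.  Each direction is normalized to unit 2-norm; the scale freedom
is absorbed downstream by `S` and the amplitude rebalancing.

Rank expansion is only defined for `r0 ≥ 2`: at `r0 = 1` the SVD and a
converged rank-1 NMF of a nonnegative matrix coincide and the comparison is
vacuous.

## The recovery step

1. **Direction truncation.**  Each proposed row `y` keeps the sign section
   (positive or negative part) whose image under the nonnegative residual
   `ΔX = max(X − W0H0, 0)` has the larger 1-norm.  Truncation happens
   *before* the least-squares solve (the narrative order); a flag restores
   the variant that solves with signed rows and truncates `S, Y` jointly
   afterwards.  Rows are truncated lazily in chunks of `k`, since the top-k
   rows almost always survive.  A row that truncates to zero is skipped in
   favor of the next-ranked direction; if the spectrum is exhausted, the
   unit coordinate row at the largest positive residual entry is
   substituted (the constructive existence argument behind the
   strict-decrease guarantee) and the event is logged.

2. **Solving for S and α.**  The joint problem
   `min ‖X − Σ_p α_p w0_p h0_pᵀ − S Y‖²` with `α ≥ 0` is solved by
   eliminating `S` in closed form: `S(α) = (X − W0 diag(α) H0) Yᵀ (YYᵀ)⁻¹`,
   leaving a convex `r0`-dimensional quadratic in α with Hessian
   `(W0ᵀW0) ⊙ (H0H0ᵀ − HY (YYᵀ)⁻¹ HYᵀ)`, `HY = H0Yᵀ`.  The `mk×mk`
   operator `(YYᵀ ⊗ I_m)` is never materialized; everything reduces to
   `k×k` Cholesky solves, for an overall `O(mnr)` cost.  The alternative —
   one large NNLS over the materialized Kronecker design, which also
   constrains `S ≥ 0` — is retained as a reference solver behind a flag and
   a memory guard; the two coincide whenever the closed-form `S` is already
   nonnegative, a property the test suite checks on planted-component
   instances.  The decoupled path may return negative entries in `S`; that
   is by design, handled by the next step.

3. **Pair truncation.**  Each rank-1 pair `(s_p, y_p)` keeps the section
   (positive parts of both, or negative parts of both) with the larger
   product of Euclidean norms — the best nonnegative rank-1 approximation,
   as in NNDSVD initialization — rebalanced so both factors carry equal
   magnitude.

4. **Amplitude rebalancing.**  All `r0+k` amplitudes β are re-fit by NNLS
   on the Gram system `(WᵀW) ⊙ (HHᵀ)`; the achieved error is evaluated
   from the same Gram quantities rather than by reconstructing `WH`.

Small NNLS problems (α, β; dimension ≤ 200) go through an eigenvalue square
root of the Gram matrix and the Lawson–Hanson active-set solver; larger ones
fall back to accelerated projected gradient with a 1e-10 KKT-residual
stopping rule.

**Error guarantees.**  The embedding `α = 1, S = 0` (and `β = [1…1, 0…0]`)
makes the under-complete solution feasible at every stage, so recovery
cannot increase the error.  Two safeguards keep this exact in floating
point and under truncation: (i) Algorithm-literally the rebalancing runs
over `[W0 diag(α), Wnew]`; if some `α_p = 0` (NNLS does produce exact
zeros) the original factorization leaves the feasible set, so when the
rebalanced error exceeds the baseline the β fit is repeated over the
unscaled `[W0, Wnew]`, which absorbs α into β — an equivalent
reparametrization whenever α > 0.  (ii) The strict-decrease guarantee is
proved for the optimal *nonnegative* solution, which the
truncate-after-solve pipeline does not exactly compute; if the residual is
nonzero but the achieved error has not strictly dropped, the first new
component is replaced by the rank-1 ansatz at the largest positive residual
entry, which provably reduces the error after the β fit.  Both fallbacks
are logged in the proposal's notes; in randomized sweeps they trigger
rarely and the 200-instance guarantee checks pass at 100%.

If `‖X − W0H0‖ ≤ 1e-12·‖X‖` there is nothing to recover: the input is
returned padded with zero components and flagged.

## Engines and initialization

**HALS** updates one component at a time by the closed-form nonnegative
rank-1 least-squares solution, sweeping columns of W then rows of H in fixed
index order (determinism; the update order is otherwise a free choice).
Per-sweep Gram matrices make each update exact coordinate descent, so the
objective is monotone.  A column driven to all-zero is floored at
`1e-16·max(X)` to avoid permanent component death, and the event is logged.

**MU** uses the multiplicative update rule with a 1e-9 floor in
denominators.  Exact zeros are fixed points of the multiplication, so when
MU refines a recovery output (whose truncation produces structural zeros)
the pipeline adds 1e-5 to every entry of both factors first.

**NNDSVD** initialization computes the leading `r` singular triples,
truncates each to its dominant nonnegative section (the leading triple of a
nonnegative matrix is already nonnegative), and scales by `√(σ·m_p)`.
Variant `a` replaces zeros by `mean(X)`; variant `ar` by uniform draws on
`[0, mean(X)/100]` from a caller-provided seed.  Random initialization
draws entries i.i.d. uniform on `[0, 2·√(mean(X)/r)]` so that
`E[WH] ≈ mean(X)`; the distribution is a package choice.

For the deterministic arms of comparisons, the under-complete stage uses
NNDSVD computed *at rank r0* (not the first r0 columns of a rank-r
NNDSVD); the random-arm protocol explicitly truncates a shared random
rank-r initialization instead, and `benchmark_compare` implements exactly
that pairing.

## Pipeline, incremental mode, benchmarking

`gsvd_nmf` chains under-complete NMF (tolerance ϵ0) → truncated SVD +
recovery → refinement at rank `r0+k` (tolerance ϵ1), initializing the
refinement from the recovery output and recording per-stage errors, the λ
spectrum and timings.  ϵ1 defaults to the generic ϵ = 1e-4 since nothing
mandates a separate value.  The number of added components accepts an
explicit count, `"one"`, or `"fraction:f"` resolved as
`max(1, round(f·r0))` with half-away-from-zero rounding (the 20% policy at
`r0 = 9` gives `k = 2`, at `r0 = 2` gives `k = 1`).

`incremental_expand` alternates refine → recover-one from a small starting
rank; because each recovery starts from the previous refined solution and
cannot increase its error, the recorded error-vs-rank trajectory is
non-increasing.

`benchmark_compare` runs, per seed, a standard rank-`r` factorization from
a random initialization and the expansion pipeline from the first
`r0 = r−k` components of that same initialization, so both arms share as
much of the start as their ranks allow.  Failures are recorded per seed
without aborting the sweep; records are deterministic given config and
seeds.

## Synthetic data

The generator emulates a source-separation scenario: `r_true` components,
each a Gaussian bump in the loading axis and in the coefficient axis, with
defaults m = 200, n = 300, r_true = 10, noise σ = 0.1 × signal RMS,
clipping negatives after noise (valid NMF input requires it; both behaviors
are available and recorded).  Bump widths are uniform in 3–10% of the axis
length — the package's own choice of "smooth, localized feature".  Centers
are stratified: one bump per equal-width stratum, jittered within it and
shuffled, so the sources are clearly distinct and spread across the axis;
fully random centers occasionally produce nearly coincident bumps (pairwise
cosine just below the 0.95 identifiability cap) that no method separates at
this noise level, which is not the scenario being modeled.  Ground truth is
redrawn (up to 100 times) if any pairwise cosine similarity reaches 0.95.

What the generator does *not* model: the heavy-tailed intensity
distributions, correlated/structured noise, sparsity patterns and baseline
drifts of real LC-MS, audio or imaging matrices.  Passing the synthetic
checks demonstrates the mechanics of missing-component recovery under the
stated assumptions (nonnegative smooth sources, additive i.i.d. Gaussian
noise), not performance on any particular instrument's data.

## Problem sizes and tolerances in the shipped checks

The randomized guarantee sweep uses 200 instances with m, n ≤ 30,
r0 ∈ 2–6, k ∈ 1–2; the synthetic comparison uses 20 data seeds at the
default 200×300 conditions with ϵ = 1e-4; the tolerance sweep uses 10
random initializations per ϵ0 ∈ {1e-2, 1e-3, 1e-4} on one default matrix.
These sizes exercise every code path while keeping the whole suite fast.
The soft performance check asserts that one recovery costs no more than
five HALS sweeps on a 600×500 instance — the step is one-shot `O(mnr)`, on
par with two to three sweeps asymptotically, with small fixed costs
(CS decomposition, Cholesky factorizations) on top.

## Known limitations

- The λ spectrum ranks candidate directions but the package does not pick
  `k` automatically (no elbow detection); `k` is a user policy.
- Both truncation sections of a new pair are never kept simultaneously
  (no 2k-component split-and-merge variant).
- Engines are limited to HALS and MU over the squared Euclidean objective;
  the engine interface is pluggable but KL/IS divergences and
  gradient-projection variants are out of scope.
- All matrices are dense in memory; a size guard warns, not prevents,
  above ~2×10⁸ elements.
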