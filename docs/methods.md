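# Methods

## Model and coding

Items are 0/1-coded (not ±1).  For y ∈ {0,1}^J the joint pmf is
P(y | S) ∝ exp(yᵀSy/2) = exp(Σ_j s_jj y_j/2 + Σ_{j<k} s_jk y_j y_k) with S
symmetric; the 1/2 on the quadratic form makes each off-diagonal pair count
once and puts the factor s_jj/2 into every conditional linear predictor,

    P(Y_j = 1 | y_{-j}) = logistic( s_jj/2 + Σ_{k≠j} s_jk y_k ).

This convention matters: the ±1 coding common in the physics literature
yields different parameter values for the same distribution.  The intercept
reported everywhere is s_jj itself, never s_jj/2.  All logistic terms are
computed with softplus/log-sum-exp, stable for |linear predictor| up to the
overflow limit of exp (~700).

Exact enumeration (pmf, exact sampling) is guarded at J ≤ 20; beyond that
the systematic-scan Gibbs sampler is the documented fallback.  The Gibbs
sampler runs n parallel chains from fair-coin starts and returns the states
after `burnin` full sweeps, so its rows are independent up to residual
initialization bias that decays geometrically in `burnin` (default 200
sweeps; adequate for the moderate couplings |s| ≤ 1 used here, but not near
a phase transition — increase `burnin` for strongly coupled networks).

α = vech(S) stacks the lower triangle column-major:
(s_11, …, s_J1, s_22, …, s_J2, …, s_JJ); `vech`/`unvech` round-trip
losslessly and all draw tables use the names s_11, s_21, ….

## The estimation procedure

One iteration has two parts.

**Imputation (every iteration).**  For j = 1..J in order: draw the
unconstrained auxiliary coefficients β_j from their Bayesian logistic
posterior given the *current* completed matrix (design row i = y_i with 1/2
in position j, response y_ij), then redraw only the missing cells of column
j from Bernoulli(logistic(β_jj/2 + Σ_{k≠j} β_jk y_ik)).  Updates are
sequential — the refreshed column feeds the next item — and observed cells
are immutable.  Item order is 1..J by default and configurable; a test
checks the stationary imputation distribution is order-invariant.
Marginally over the imputed cells, β_j's stationary distribution is its
posterior given the *observed* rows only, so the imputation distribution
converges (as N grows) to the true conditional — the compatibility property
that makes FCS valid here.

**Sampling S (thinned).**  At iterations t > T0 with (t − T0) divisible by
k0, α is drawn from the pseudo-posterior π(α) ∏_{i,j} p(y_ij | y_{i,-j}, α):
one joint Pólya–Gamma sweep over the N·J stacked conditional terms, updating
all J(J+1)/2 coordinates in a single multivariate normal draw (not
coordinate-wise Gibbs — the joint update mixes better).  The N·J terms are
treated as independent likelihood contributions *by design*: the target is a
pseudo-posterior, not the exact posterior, and no correction is applied.
The estimate is the mean of retained draws (pooled over chains when several
are run); retained count = floor((T − T0)/k0).

Why two parameter sets: a full α update costs O((N+J)J⁵) while a sweep of
all β_j costs O((N+J)J³), so imputing via the unconstrained β_j and touching
α only at thinned events keeps the chain fast and also decorrelates the
imputations between retained draws.

**Complete data.**  With nothing to impute the β_j influence nothing, so the
chain reduces to plain pseudo-posterior sampling: α is updated every
iteration and retained on the same burn-in/thinning schedule ("identical
MCMC length and configuration").  Listwise deletion = this chain on the
complete rows; single imputation = the full iterative chain frozen at
iteration T (run on a separate seed stream), then this chain on the one
completed dataset.  Hence with zero missingness all three estimators consume
identical randomness and return bit-identical results under a shared seed.

## Pólya–Gamma machinery

With ω_i ~ PG(1, x_iᵀb), the logistic likelihood is conditionally Gaussian:
b | ω ~ N with precision XᵀΩX + V₀⁻¹ and canonical mean Xᵀ(u − ½) + V₀⁻¹m₀.
The Cholesky factor of the precision does both the solve and the draw; a
non-positive-definite precision (impossible with a proper prior) raises a
diagnostic error naming the update.

Two PG samplers are provided and cross-checked against each other and
against the closed-form mean E PG(b,c) = (b/2c) tanh(c/2):

* **Devroye-type exact sampler** for PG(1, c): two-piece proposal
  (truncated inverse-Gaussian below 0.64, exponential above) with the
  alternating-series accept/reject test — the default for per-row draws.
* **Truncated sum-of-gammas** for any shape b > 0:
  PG(b,c) = (1/2π²) Σ_k g_k / ((k−½)² + c²/4π²), g_k ~ Gamma(b), truncated
  at 200 terms plus the *exact* mean of the discarded tail (closed form via
  tanh).  The truncation error in the mean is therefore zero; the omitted
  tail variance at 200 terms is negligible (O(b/K³)).

**Pattern grouping.**  All covariates are binary, so rows sharing a response
pattern share a linear predictor, and a sum of independent PG(1, c) variables
is a single PG(n, c) variable.  The β_j and α kernels group rows by pattern
(bit-code bincount for J ≤ 16, `np.unique` above) and draw one grouped PG
variate per pattern — algebraically the same conditional Gaussian, at
O(min(N, 2^J)) PG draws per update instead of O(N) (or O(N·J) for α).  The
α update streams the design into the precision matrix item by item and never
materializes the N·J × J(J+1)/2 matrix.  A test verifies the grouped and
per-row kernels target the same posterior; a by-product is that the grouped
kernels are exactly invariant to row relabeling.

## Priors, initialization, defaults

* β_j: independent mean-zero normals, variance 100 on the intercept β_jj
  (weakly informative), variance 1 on slopes (edges are sparse and rarely
  extreme).  α mirrors this — variance 100 on diagonal coordinates, 1 on
  off-diagonal — so shrinkage behaves symmetrically between the auxiliary
  and structural parameters.  Both configurable (`PriorSpec`).
* α⁽⁰⁾ ~ Uniform(−0.1, 0.1) per coordinate; β_j⁽⁰⁾ = 0.
* Missing cells are initialized Bernoulli(observed column mean clipped to
  [0.05, 0.95]); clipping avoids degenerate all-0/all-1 starts when a
  column's observed values are constant.
* Reference schedule T=5000, T0=1000, k0=10 (400 retained draws); the
  desk-scale schedule used by the test-size experiments is T=1500, T0=500,
  k0=10 (100 retained draws).
* Multi-chain `fit` defaults to per-chain seeds spawned from the master seed
  (`SeedSequence.spawn`); the reported estimate pools all chains' draws.

Gelman–Rubin is the classic variance-ratio sqrt(((n−1)/n·W + B/n)/W) per
scalar parameter, floored at 1.0 (the unfloored statistic is below 1 by
(2n)⁻¹ even for identical chains; values under 1 carry no information).
Chains that are constant but different give W = 0 and are flagged +inf with
a warning.

## Synthetic data

The generators define the study conditions; their defaults are the
conditions under which all tests run.

* **Sparse random truth** (J=6): each upper-triangle edge is zero with
  probability 0.5, otherwise uniform on [−1, −0.4] ∪ [0.4, 1]; zero
  intercepts.  One fixed truth (seed 20240601) is used across replications.
* **Screening truth** (J=6): six positive edges of weight 0.8 at pairs
  {12, 13, 24, 35, 46, 56} — including the screener–screener edge s_12 —
  zero elsewhere.  Weight and edge set are configurable; 0.8 is a
  representative moderate association chosen once.
* **Missingness**: MCAR (independent cell masking at a given rate);
  anchor-MAR (the last item is always observed; other cells are masked with
  probability 0.1 when the anchor response is 1, 0.4 when it is 0 — a
  moderate, clearly non-MCAR dependence chosen once); screening (items
  beyond the screeners are missing iff *all* screener responses are 0 —
  deterministic given the screeners).  Both non-MCAR mechanisms read only
  always-observed columns, hence are genuinely MAR; a test scrambles the
  maskable columns and checks the mask is unchanged.

What the generators deliberately do not emulate: item batteries measuring
latent factors, MNAR mechanisms, ordinal/continuous nodes, and item counts
beyond a handful.  Passing tests therefore show correct recovery under a
correctly specified Ising model with MAR missingness — they do not certify
behavior under model misspecification or non-ignorable missingness.

A note on the anchor-MAR design: row selection for the complete cases
depends only on the anchor item, so the complete-case population is itself
an Ising model with the anchor intercept shifted by twice the log selection
odds ratio (≈ 4.06 at the default rates).  Listwise deletion is therefore
asymptotically biased — with non-vanishing MSE — specifically in the anchor
intercept, which is the parameter the non-decay check targets.

## Experiment sizes

Chosen once as desk-scale versions of the reference designs (one CPU, a few
minutes each): recovery under 20% MCAR at N ∈ {1000, 4000} with 5
replications; screening design at N=8000 with 10 replications (5 in the
acceptance script) comparing proposed vs complete-case; anchor-MAR at
N=8000 with 5 replications (3 in the script) comparing proposed vs single
imputation; listwise non-decay across N ∈ {1000, 2000, 4000, 8000} with 5
replications each.  Per-replication seeds are master_seed + replication
index; every method within a replication fits the same masked dataset with
the same seed.

## Known limitations

* Point estimation only: no edge selection, FDR control, or credible-set
  inclusion rules; `edge_list`'s threshold is for display.
* The pseudo-posterior is not the exact Bayesian posterior; its spread is
  not a calibrated uncertainty measure.
* Spike-and-slab priors and coordinate-wise Gibbs variants are out of scope.
* Exact enumeration (and hence `sample_exact`) stops at J = 20; the Gibbs
  sampler takes over but inherits the usual mixing caveats.
* The imputation step requires every item to have at least one observed
  value, and listwise deletion requires at least one complete row.
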