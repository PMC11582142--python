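# isingmiss

Bayesian Ising network analysis for binary item-response data **with missing
values**, via iterative imputation and Pólya–Gamma pseudo-posterior sampling.

## The problem

Network psychometrics models a battery of J binary items (symptoms, survey
questions) as nodes of a Markov random field.  With y ∈ {0,1}^J, the Ising
model is

    P(Y = y | S) = exp( yᵀ S y / 2 ) / c(S),

where S is a J×J symmetric matrix: the diagonal s_jj are main effects and the
off-diagonal s_jk are edge weights — s_jk ≠ 0 means items j and k are
conditionally dependent given the rest.  Because the normalizing constant
c(S) sums over 2^J patterns, estimation is routinely based instead on the
conditional (pseudo-) likelihood

    p*(y | S) = ∏_j P(y_j | y_{-j}, S),
    P(Y_j = 1 | y_{-j}, S) = logistic( s_jj/2 + Σ_{k≠j} s_jk y_k ),

which needs **fully observed** rows.  Real item-response data are rarely
fully observed — in particular, *screening items* cause structured
missingness: respondents answering "no" to the screeners skip the remaining
items.  Deleting incomplete rows (listwise deletion) then conditions on a
selection event and can manufacture a spurious *negative* edge between the
screening items (Berkson's paradox), reversing the sign of a real positive
association.

`isingmiss` implements a conditional Bayesian answer:

1. **Iterative imputation (FCS).**  Cycle over items; for each item j, draw
   auxiliary logistic coefficients β_j from their Bayesian posterior given
   the current completed data (Pólya–Gamma augmented, conjugate), then redraw
   only the missing cells of column j from the fitted conditional.  Because
   the logistic conditionals are exactly the Ising model's own conditionals,
   the per-item models are mutually compatible.
2. **Pseudo-posterior sampling of S.**  At thinned iterations after burn-in,
   draw α = vech(S) (all J(J+1)/2 coordinates jointly) from
   π(S) ∏_i p*(y_i | S) via a joint Pólya–Gamma step over the N·J stacked
   conditional terms.  The final estimate is the average of the retained
   draws.

Baselines included for comparison: **listwise deletion** and **single
imputation** (one completed dataset from the last iteration, then a
complete-data chain).  On fully observed data all three reduce to the same
complete-data pseudo-posterior chain and return bit-identical estimates
under a shared seed.

## Worked example

Simulate a 6-item network in which two screening items gate the other four,
fit the proposed method and the complete-case baseline, and look at the
screener–screener edge (true value +0.8):

```python
import numpy as np
from isingmiss import (make_study2_truth, simulate_dataset, MissingnessSpec,
                       proposed_estimate, listwise_estimate)

truth = make_study2_truth()                      # six positive edges, s_12 = 0.8
data, _ = simulate_dataset(truth, 8000, MissingnessSpec.screening(), seed=21)
print(f"missing cells: {data.n_missing}  complete rows: {data.complete_cases().N}")

est_p = proposed_estimate(data, T=1500, T0=500, k0=10, seed=4)
est_l = listwise_estimate(data, T=1500, T0=500, k0=10, seed=4)
print(f"s_12 proposed:      {est_p.values[0, 1]: .3f}")
print(f"s_12 complete-case: {est_l.values[0, 1]: .3f}")
```

Output:

```
missing cells: 2960  complete rows: 7260
s_12 proposed:       0.794
s_12 complete-case: -4.780
```

The proposed method recovers the positive screener edge (0.79 vs truth 0.8);
the complete-case estimate is pushed far negative — its pseudo-ML limit is
−∞ and the finite value reflects only the N(0,1) prior's shrinkage.  That is
Berkson's paradox in action: complete cases exclude every (0,0) screener
pattern, so a positive answer on one screener predicts a negative answer on
the other.

From the shell the same analysis is:

```sh
isingmiss simulate --truth study2 --n 8000 --missing screening --seed 21 --out-prefix sim
isingmiss fit sim_masked.csv --iters 1500 --burnin 500 --thin 10 --chains 4 --seed 4 --out-prefix fit
isingmiss edges fit_shat.csv --threshold 0.5
```

`fit` writes the estimate (`fit_shat.csv`), the retained draws
(`fit_draws.csv`, one row per chain × draw with vech coordinates
s_11, s_21, …) and Gelman–Rubin statistics per parameter (`fit_rhat.csv`).
`isingmiss replicate` runs the full multi-replication MSE/bias comparison of
the three estimators.

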