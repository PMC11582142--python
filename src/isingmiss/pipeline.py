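"""End-to-end chain runner, posterior summaries, convergence diagnostics and
the two baseline estimators (listwise deletion, single imputation).

A chain runs T sweeps with burn-in T0 and thinning k0.  With missing data,
each sweep is one full-conditional-specification pass; alpha = vech(S) is
sampled only at thinning events after burn-in (it is by far the most
expensive update and sampling it during burn-in would be wasted), giving
floor((T - T0) / k0) retained draws.  With complete data the sweep has
nothing to impute and the procedure reduces to a plain thinned
pseudo-posterior chain: alpha is updated at every iteration and retained on
the same schedule.  This is what makes listwise deletion and the second
phase of single imputation exact special cases of the same code path, and
what makes all three estimators bit-identical on fully observed data under
a shared seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .ising import IsingMatrix, ResponseData, unvech, vech_names
from .imputation import ChainState, fcs_sweep, initialize_missing
from .polya_gamma import PriorSpec, _as_rng, sample_alpha

#: entropy stream key for the imputation phase of single imputation
_SINGLE_IMPUTATION_STREAM = 0x51


@dataclass(frozen=True)
class Schedule:
    """MCMC schedule: total iterations T, burn-in T0, thinning k0."""

    T: int = 5000
    T0: int = 1000
    k0: int = 10

    def __post_init__(self):
        if self.T < 1 or self.T0 < 0 or self.k0 < 1:
            raise ValueError(f"invalid schedule {self}")

    @property
    def n_retained(self) -> int:
        return max(0, (self.T - self.T0) // self.k0)


#: reduced desk-scale schedule used throughout the test-size experiments
DESK_SCHEDULE = Schedule(T=1500, T0=500, k0=10)


def run_chain(data: ResponseData, T: int = 5000, T0: int = 1000, k0: int = 10,
              priors: PriorSpec | None = None, seed=None,
              item_order=None, init_scale: float = 0.1,
              trace_path=None) -> ChainState:
    """Run one chain and return its final state with retained alpha draws.

    alpha is initialized from Uniform(-init_scale, init_scale) on every vech
    coordinate; beta_j start at zero.  Retained draw count is
    floor((T - T0) / k0); a warning is emitted when it is zero.  With a
    ``trace_path``, per-sweep imputed-cell means per item are written there
    as CSV (iteration, item, imputed_mean).
    """
    sched = Schedule(T, T0, k0)
    rng = _as_rng(seed)
    priors = priors or PriorSpec()
    J = data.J
    p = J * (J + 1) // 2
    alpha = rng.uniform(-init_scale, init_scale, size=p)
    state = initialize_missing(data, rng)
    state.alpha = alpha
    complete = data.is_complete
    alpha_prior = priors.alpha_prior(J)
    draws = []
    trace: list | None = [] if trace_path is not None else None
    for t in range(1, sched.T + 1):
        if not complete:
            fcs_sweep(state, data, priors, rng, item_order, trace=trace)
        retain = t > sched.T0 and (t - sched.T0) % sched.k0 == 0
        if complete or retain:
            state.alpha = sample_alpha(state.y_current, alpha_prior, state.alpha, rng)
            if retain:
                draws.append(state.alpha)
        state.iteration = t
    if trace_path is not None:
        with open(trace_path, "w") as fh:
            fh.write("iteration,item,imputed_mean\n")
            fh.writelines(f"{it},{j},{m:.6f}\n" for it, j, m in (trace or []))
    if not draws:
        warnings.warn(
            f"schedule (T={T}, T0={T0}, k0={k0}) retains no draws",
            RuntimeWarning, stacklevel=2,
        )
    state.alpha_draws = np.array(draws).reshape(len(draws), p)
    return state


def posterior_mean(state: ChainState | np.ndarray) -> IsingMatrix:
    """Elementwise mean of the retained (unvech'd) draws; symmetric by
    construction."""
    draws = state.alpha_draws if isinstance(state, ChainState) else np.asarray(state)
    if draws is None or draws.size == 0:
        raise ValueError("no retained draws to average")
    return unvech(np.atleast_2d(draws).mean(axis=0))


def gelman_rubin(chains) -> np.ndarray:
    """Classic per-parameter Gelman-Rubin R-hat across chains.

    ``chains`` is (m, n, p) or a list of m equal-length (n, p) draw arrays.
    R-hat = sqrt(((n-1)/n W + B/n) / W), floored at 1.0 (values below 1 are
    finite-sample noise).  Degenerate chains with zero within-variance but
    nonzero between-variance are flagged +inf with a warning.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim == 2:
        x = x[:, :, None]
    if x.ndim != 3:
        raise ValueError("chains must be (m, n, p)")
    m, n, p = x.shape
    if m < 2:
        raise ValueError("at least 2 chains are required")
    if n < 2:
        raise ValueError("chains must have at least 2 draws")
    means = x.mean(axis=1)
    W = x.var(axis=1, ddof=1).mean(axis=0)
    B_over_n = means.var(axis=0, ddof=1)
    rhat = np.empty(p)
    with np.errstate(divide="ignore", invalid="ignore"):
        vhat = (n - 1) / n * W + B_over_n
        rhat = np.sqrt(vhat / W)
    zero_w = W == 0
    if zero_w.any():
        rhat[zero_w & (B_over_n > 0)] = np.inf
        rhat[zero_w & (B_over_n == 0)] = 1.0
        if np.any(zero_w & (B_over_n > 0)):
            warnings.warn("constant chains with differing values: R-hat = inf",
                          RuntimeWarning, stacklevel=2)
    return np.maximum(rhat, 1.0)


def edge_list(S_hat: IsingMatrix, threshold: float = 0.5):
    """Off-diagonal pairs with |s_jk| > threshold, as (item_j, item_k, weight)
    tuples sorted by decreasing magnitude.  The threshold is a visualization
    device, not an edge-selection rule."""
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    names = S_hat.item_names()
    out = []
    v = S_hat.values
    for j in range(S_hat.J):
        for k in range(j + 1, S_hat.J):
            if abs(v[j, k]) > threshold:
                out.append((names[j], names[k], float(v[j, k])))
    out.sort(key=lambda e: -abs(e[2]))
    return out


# ---------------------------------------------------------------------------
# the three estimators
# ---------------------------------------------------------------------------

def proposed_estimate(data: ResponseData, T: int = 5000, T0: int = 1000,
                      k0: int = 10, priors: PriorSpec | None = None,
                      seed=None) -> IsingMatrix:
    """Posterior-mean estimate from the full iterative-imputation chain."""
    return posterior_mean(run_chain(data, T, T0, k0, priors, seed))


def listwise_estimate(data: ResponseData, T: int = 5000, T0: int = 1000,
                      k0: int = 10, priors: PriorSpec | None = None,
                      seed=None) -> IsingMatrix:
    """Complete-case analysis: drop every row with a missing cell, then run
    the same pseudo-posterior chain and averaging on the remainder."""
    sub = data.complete_cases()
    if sub.N == 0:
        raise ValueError("no complete rows; listwise deletion impossible")
    return posterior_mean(run_chain(sub, T, T0, k0, priors, seed))


def single_imputation_estimate(data: ResponseData, T: int = 5000, T0: int = 1000,
                               k0: int = 10, priors: PriorSpec | None = None,
                               seed=None) -> IsingMatrix:
    """Single imputation: run the full iterative chain, freeze the imputed
    matrix at iteration T, then run a fresh complete-data chain (same
    schedule) on that one completed dataset."""
    if isinstance(seed, np.random.Generator):
        raise TypeError("single_imputation_estimate needs a reproducible seed, "
                        "not a Generator")
    imp_seed = np.random.SeedSequence([int(seed) if seed is not None else 0,
                                       _SINGLE_IMPUTATION_STREAM])
    imp_state = run_chain(data, T, T0, k0, priors, np.random.default_rng(imp_seed))
    completed = ResponseData.complete(imp_state.y_current, items=data.items)
    return posterior_mean(run_chain(completed, T, T0, k0, priors, seed))


ESTIMATORS = {
    "proposed": proposed_estimate,
    "single": single_imputation_estimate,
    "listwise": listwise_estimate,
}


def fit(data: ResponseData, method: str = "proposed", n_chains: int = 1,
        T: int = 5000, T0: int = 1000, k0: int = 10,
        priors: PriorSpec | None = None, seed=None):
    """Multi-chain fit: runs ``n_chains`` chains with seeds spawned from the
    master seed, pools all retained draws for the reported estimate and
    computes per-parameter R-hat when there are >= 2 chains.

    For the baseline methods ('single', 'listwise') draws are not exposed
    per chain; the pooled estimate is the mean of per-chain estimates.

    Returns (estimate: IsingMatrix, draws: (m, n, p) array or None,
    rhat: (p,) array or None).
    """
    if method not in ESTIMATORS:
        raise ValueError(f"unknown method {method!r}")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_chains)
    if method == "proposed":
        states = [run_chain(data, T, T0, k0, priors, np.random.default_rng(c))
                  for c in children]
        draws = np.stack([s.alpha_draws for s in states])
        est = posterior_mean(draws.reshape(-1, draws.shape[-1]))
        rhat = gelman_rubin(draws) if n_chains >= 2 and draws.shape[1] >= 2 else None
        est = IsingMatrix(est.values, items=data.items)
        return est, draws, rhat
    fn = ESTIMATORS[method]
    ests = [fn(data, T, T0, k0, priors,
               seed=int(c.generate_state(1, np.uint32)[0])) for c in children]
    mean = np.mean([e.values for e in ests], axis=0)
    return IsingMatrix(mean, items=data.items), None, None


def draws_to_frame(draws: np.ndarray, J: int):
    """Flatten (m, n, p) retained draws to a table: chain, draw, then the
    vech coordinates named s_11, s_21, ..."""
    import pandas as pd

    draws = np.asarray(draws)
    if draws.ndim == 2:
        draws = draws[None]
    m, n, p = draws.shape
    df = pd.DataFrame(draws.reshape(m * n, p), columns=vech_names(J))
    df.insert(0, "draw", np.tile(np.arange(n), m))
    df.insert(0, "chain", np.repeat(np.arange(m), n))
    return df
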