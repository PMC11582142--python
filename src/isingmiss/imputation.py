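"""Full-conditional-specification (chained-equations) imputation sweep.

One sweep loops over items j = 1..J in order: refresh the auxiliary
logistic coefficients beta_j on the current fully imputed matrix, then
redraw the missing cells of column j from Bernoulli(logistic(beta_jj/2 +
sum_{k != j} beta_jk y_ik)) using the most recent values of the other
items.  The updated column feeds the next item's step (sequential, not
parallel).  Observed cells are never touched.

Because each conditional is exactly the Ising model's own logistic
conditional, the per-item models are mutually compatible: the stationary
imputation distribution of the sweep coincides with imputation under the
joint Ising model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .ising import ResponseData
from .polya_gamma import PriorSpec, _as_rng, sample_beta_j


@dataclass
class ChainState:
    """Mutable state of one chain: the current fully imputed matrix, the J
    auxiliary coefficient vectors (row j is beta_j), the current alpha and
    the retained alpha draws.

    ``y_current`` always agrees with the observed data at every observed
    cell; only masked cells are rewritten by the sweep.
    """

    y_current: np.ndarray
    betas: np.ndarray
    alpha: np.ndarray | None = None
    alpha_draws: np.ndarray | None = None
    iteration: int = 0


def initialize_missing(data: ResponseData, seed=None) -> ChainState:
    """Fill each missing cell (i, j) with Bernoulli(p_j), p_j the observed
    column mean clipped to [0.05, 0.95]; observed cells are copied."""
    rng = _as_rng(seed)
    obs_count = data.mask.sum(axis=0)
    if np.any(obs_count == 0):
        bad = np.flatnonzero(obs_count == 0) + 1
        raise ValueError(f"items with no observed values: {bad.tolist()}")
    phat = (data.y * data.mask).sum(axis=0) / obs_count
    phat = np.clip(phat, 0.05, 0.95)
    y = data.y.copy()
    miss = ~data.mask
    if miss.any():
        p_cell = np.broadcast_to(phat, y.shape)[miss]
        y[miss] = rng.random(p_cell.size) < p_cell
    return ChainState(y_current=y, betas=np.zeros((data.J, data.J)))


def impute_item(state: ChainState, j: int, data: ResponseData, seed=None) -> ChainState:
    """Redraw the missing cells of item j from the logistic conditional under
    the current beta_j; rows with observed y_ij are untouched."""
    rng = _as_rng(seed)
    miss = ~data.mask[:, j]
    if not miss.any():
        return state
    Y = state.y_current
    beta = state.betas[j]
    eta = beta[j] / 2.0 + Y[miss].astype(float) @ beta - Y[miss, j] * beta[j]
    Y[miss, j] = rng.random(int(miss.sum())) < expit(eta)
    return state


def fcs_sweep(state: ChainState, data: ResponseData, priors: PriorSpec | None = None,
              seed=None, item_order=None, trace: list | None = None) -> ChainState:
    """One full sweep: for each item in order, sample beta_j then impute
    column j, sequentially (the refreshed column feeds the next item).

    When ``trace`` is a list, one (iteration, item, imputed-cell mean) row per
    item with missing cells is appended — a cheap mixing diagnostic.
    """
    rng = _as_rng(seed)
    priors = priors or PriorSpec()
    J = data.J
    order = range(J) if item_order is None else item_order
    for j in order:
        state.betas[j] = sample_beta_j(
            j, state.y_current, priors.beta_prior(J, j), state.betas[j], rng
        )
        impute_item(state, j, data, rng)
        if trace is not None:
            miss = ~data.mask[:, j]
            if miss.any():
                trace.append((state.iteration + 1, j + 1,
                              float(state.y_current[miss, j].mean())))
    state.iteration += 1
    return state
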