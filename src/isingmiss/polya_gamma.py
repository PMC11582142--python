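"""Polya-Gamma augmented Gibbs kernels.

Two conjugate updates drive the whole procedure:

* per-item Bayesian logistic regression for the auxiliary coefficient
  vector beta_j used by the imputation step, and
* the joint update of alpha = vech(S) from the pseudo-posterior, treating
  the N*J per-item conditional likelihood terms as independent
  contributions (deliberately: the target is a pseudo-posterior, not the
  exact posterior, and must not be "corrected").

Both follow the standard augmentation: with omega_i ~ PG(1, x_i'b) the
logistic likelihood becomes conditionally Gaussian, so b is redrawn from a
multivariate normal with precision X' Omega X + V0^-1 and canonical mean
X'(u - 1/2) + V0^-1 m0.

Because all covariates here are binary item responses, rows sharing a
response pattern share a linear predictor, and the sum of their PG(1, c)
augmentation variables is one PG(n_g, c) variable.  The high-level kernels
(:func:`sample_beta_j`, :func:`sample_alpha`) exploit this: they group the
N (or N*J) pseudo-observations by pattern and draw one grouped PG variate
per pattern, which is algebraically identical to the per-row kernel and
reduces the augmentation cost from O(N) draws to O(min(N, 2^J)) per update.

PG sampling itself is provided in two flavours: an exact Devroye-type
rejection sampler for PG(1, c), and a truncated sum-of-gammas
representation (200 terms plus an exact mean correction for the discarded
tail) valid for any shape b > 0, used for the grouped PG(n, c) draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_solve, solve_triangular
from scipy.special import log_ndtr

from .ising import ResponseData, vech_indices, _unvech_values

_TRUNC = 0.64  # Devroye proposal changeover point for the Jacobi density
DEFAULT_TRUNC_TERMS = 200


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GaussianPrior:
    """Independent normal prior with diagonal covariance."""

    mean: np.ndarray
    variances: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.mean, dtype=float).ravel()
        v = np.asarray(self.variances, dtype=float).ravel()
        if m.shape != v.shape:
            raise ValueError("prior mean and variances must have equal length")
        if not np.all(v > 0):
            raise ValueError("prior variances must be strictly positive")
        if not np.all(np.isfinite(m)) or not np.all(np.isfinite(v)):
            raise ValueError("prior parameters must be finite")
        object.__setattr__(self, "mean", m)
        object.__setattr__(self, "variances", v)

    @property
    def dim(self) -> int:
        return self.mean.size


@dataclass(frozen=True)
class PriorSpec:
    """Mean-zero normal priors for the whole procedure.

    Variance 100 on intercept coordinates (beta_jj and the diagonal of S) is
    weakly informative; variance 1 on slope/edge coordinates reflects that
    edge weights are sparse and rarely extreme.  The alpha prior mirrors the
    beta prior so shrinkage behaves symmetrically.
    """

    var_intercept: float = 100.0
    var_edge: float = 1.0

    def beta_prior(self, J: int, j: int) -> GaussianPrior:
        v = np.full(J, self.var_edge)
        v[j] = self.var_intercept
        return GaussianPrior(np.zeros(J), v)

    def alpha_prior(self, J: int) -> GaussianPrior:
        rows, cols = vech_indices(J)
        v = np.where(rows == cols, self.var_intercept, self.var_edge)
        return GaussianPrior(np.zeros(rows.size), v)


# ---------------------------------------------------------------------------
# Polya-Gamma sampling
# ---------------------------------------------------------------------------

def pg_mean(b, c):
    """Closed-form E[PG(b, c)] = (b / 2c) tanh(c / 2), -> b/4 as c -> 0."""
    b = np.asarray(b, dtype=float)
    h = np.abs(np.asarray(c, dtype=float)) / 2.0
    small = h < 1e-6
    hs = np.where(small, 1.0, h)
    ratio = np.where(small, 1.0 - h * h / 3.0, np.tanh(hs) / hs)
    return b * ratio / 4.0


def _pg_gamma(b, c, rng, trunc=DEFAULT_TRUNC_TERMS):
    """Truncated sum-of-gammas representation of PG(b, c), any b > 0.

    PG(b, c) = (1 / 2 pi^2) sum_k g_k / ((k - 1/2)^2 + c^2 / 4 pi^2) with
    g_k ~ Gamma(b, 1); truncated at ``trunc`` terms, plus the exact mean of
    the discarded tail.
    """
    b, c = np.broadcast_arrays(np.asarray(b, float), np.asarray(c, float))
    shape = b.shape
    b = b.ravel()
    a = np.abs(c).ravel()
    k = np.arange(1, trunc + 1) - 0.5
    denom = k[:, None] ** 2 + (a / (2 * np.pi)) ** 2  # (K, n)
    g = rng.standard_gamma(b, size=(trunc, b.size))
    s = (g / denom).sum(axis=0) / (2 * np.pi ** 2)
    tail = pg_mean(b, a) - (b / (2 * np.pi ** 2)) * (1.0 / denom).sum(axis=0)
    return (s + tail).reshape(shape)


def _a_coef(n: int, x: np.ndarray) -> np.ndarray:
    """Alternating-series coefficients of the Jacobi density, piecewise in x."""
    h = n + 0.5
    small = x <= _TRUNC
    out = np.empty_like(x)
    xs = x[small]
    out[small] = np.pi * h * (2.0 / (np.pi * xs)) ** 1.5 * np.exp(-2.0 * h * h / xs)
    xl = x[~small]
    out[~small] = np.pi * h * np.exp(-h * h * np.pi ** 2 * xl / 2.0)
    return out


def _trunc_inv_gauss(z: np.ndarray, rng) -> np.ndarray:
    """Draw X ~ InverseGaussian(1/z, 1) truncated to (0, _TRUNC]."""
    t = _TRUNC
    out = np.empty_like(z)
    with np.errstate(divide="ignore"):
        mu = 1.0 / z
    big = mu > t

    # mu > t (small z): scaled reciprocal-chi-square proposal with exp tilt
    idx = np.flatnonzero(big)
    while idx.size:
        m = idx.size
        e1 = rng.exponential(size=m)
        e2 = rng.exponential(size=m)
        ok = e1 * e1 <= 2.0 * e2 / t
        x = t / (1.0 + t * e1) ** 2
        acc = ok & (rng.random(m) <= np.exp(-0.5 * z[idx] ** 2 * x))
        out[idx[acc]] = x[acc]
        idx = idx[~acc]

    # mu <= t: standard inverse-Gaussian draw, retried into the truncation
    idx = np.flatnonzero(~big)
    mu_w = mu[idx]
    while idx.size:
        m = idx.size
        y = rng.standard_normal(m) ** 2
        muy = mu_w * y
        x = mu_w + 0.5 * mu_w * muy - 0.5 * mu_w * np.sqrt(4.0 * muy + muy ** 2)
        flip = rng.random(m) > mu_w / (mu_w + x)
        x[flip] = mu_w[flip] ** 2 / x[flip]
        ok = x <= t
        out[idx[ok]] = x[ok]
        idx = idx[~ok]
        mu_w = mu_w[~ok]
    return out


def _propose_jstar(z: np.ndarray, rng) -> np.ndarray:
    """One proposal from the two-piece envelope of the tilted Jacobi density."""
    t = _TRUNC
    fz = np.pi ** 2 / 8.0 + z ** 2 / 2.0
    b = np.sqrt(1.0 / t) * (t * z - 1.0)
    a = -np.sqrt(1.0 / t) * (t * z + 1.0)
    x0 = np.log(fz) + fz * t
    qdivp = 4.0 / np.pi * (np.exp(x0 - z + log_ndtr(b)) + np.exp(x0 + z + log_ndtr(a)))
    use_exp = rng.random(z.size) < 1.0 / (1.0 + qdivp)
    out = np.empty_like(z)
    ne = int(use_exp.sum())
    if ne:
        out[use_exp] = t + rng.exponential(size=ne) / fz[use_exp]
    rest = ~use_exp
    if rest.any():
        out[rest] = _trunc_inv_gauss(z[rest], rng)
    return out


def _pg_devroye(c, rng):
    """Exact PG(1, c) draws via Devroye-type alternating-series rejection."""
    z = np.abs(np.asarray(c, dtype=float)).ravel() / 2.0
    n = z.size
    out = np.empty(n)
    pending = np.arange(n)
    while pending.size:
        zp = z[pending]
        x = _propose_jstar(zp, rng)
        # alternating-series accept/reject
        s = _a_coef(0, x)
        y = rng.random(x.size) * s
        accept = np.zeros(x.size, dtype=bool)
        undecided = np.arange(x.size)
        term = 0
        while undecided.size:
            term += 1
            an = _a_coef(term, x[undecided])
            if term % 2 == 1:
                s[undecided] -= an
                hit = y[undecided] <= s[undecided]
                accept[undecided[hit]] = True
                undecided = undecided[~hit]
            else:
                s[undecided] += an
                miss = y[undecided] > s[undecided]
                undecided = undecided[~miss]
        out[pending[accept]] = x[accept] / 4.0
        pending = pending[~accept]
    return out.reshape(np.shape(c))


def draw_pg(b, c, seed=None, method: str = "auto", trunc: int = DEFAULT_TRUNC_TERMS):
    """Draw Polya-Gamma PG(b, c) variates, elementwise over broadcast b, c.

    ``method='devroye'`` is the exact sampler (requires b == 1);
    ``method='gamma'`` is the truncated sum-of-gammas representation for any
    b > 0; ``'auto'`` picks Devroye when every shape equals 1.
    """
    rng = _as_rng(seed)
    b_arr = np.asarray(b, dtype=float)
    if not np.all(b_arr > 0):
        raise ValueError("PG shape parameter b must be > 0")
    all_one = np.all(b_arr == 1.0)
    if method == "auto":
        method = "devroye" if all_one else "gamma"
    if method == "devroye":
        if not all_one:
            raise ValueError("the Devroye sampler is implemented for b == 1 only")
        return _pg_devroye(c, rng)
    if method == "gamma":
        return _pg_gamma(b, c, rng, trunc=trunc)
    raise ValueError(f"unknown PG sampling method {method!r}")


# ---------------------------------------------------------------------------
# conjugate Gaussian step
# ---------------------------------------------------------------------------

def _draw_mvn_canonical(prec: np.ndarray, rhs: np.ndarray, rng, context: str) -> np.ndarray:
    """Draw from N(prec^-1 rhs, prec^-1) via a Cholesky factor of ``prec``."""
    try:
        L = np.linalg.cholesky(prec)
    except np.linalg.LinAlgError as err:
        raise RuntimeError(
            f"precision matrix not positive definite in {context}; "
            "this cannot occur with a proper prior"
        ) from err
    mean = cho_solve((L, True), rhs)
    z = rng.standard_normal(rhs.size)
    return mean + solve_triangular(L.T, z, lower=False)


def pg_logistic_update(X, u, prior: GaussianPrior, current, seed=None,
                       method: str = "devroye", trunc: int = DEFAULT_TRUNC_TERMS):
    """One Polya-Gamma sweep of Bayesian logistic regression coefficients.

    Draws omega_i ~ PG(1, x_i' current) independently, then the coefficient
    vector from the conditional normal with precision X' Omega X + V0^-1 and
    canonical mean X'(u - 1/2) + V0^-1 m0.  With no rows the draw is from
    the prior.
    """
    rng = _as_rng(seed)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    u = np.asarray(u, dtype=float).ravel()
    n, p = X.shape
    if u.size != n:
        raise ValueError("response length does not match design rows")
    if n and not np.isin(u, (0.0, 1.0)).all():
        raise ValueError("responses must be binary 0/1")
    if prior.dim != p:
        raise ValueError("prior dimension does not match design columns")
    current = np.zeros(p) if current is None else np.asarray(current, dtype=float)
    prec = np.diag(1.0 / prior.variances)
    rhs = prior.mean / prior.variances
    if n:
        omega = draw_pg(1.0, X @ current, rng, method=method, trunc=trunc)
        prec = prec + X.T @ (X * omega[:, None])
        rhs = rhs + X.T @ (u - 0.5)
    return _draw_mvn_canonical(prec, rhs, rng, "logistic coefficient update")


def _pg_update_grouped(Xg, n_g, ksum, prior: GaussianPrior, current, rng,
                       trunc: int, context: str):
    """Grouped variant: rows of Xg are unique patterns, n_g their counts and
    ksum_g = sum over the group of (u_i - 1/2).  Identical in distribution to
    the per-row kernel."""
    eta = Xg @ current
    w = _pg_gamma(n_g, eta, rng, trunc=trunc)
    prec = Xg.T @ (Xg * w[:, None]) + np.diag(1.0 / prior.variances)
    rhs = Xg.T @ ksum + prior.mean / prior.variances
    return _draw_mvn_canonical(prec, rhs, rng, context)


# ---------------------------------------------------------------------------
# the two model-specific kernels
# ---------------------------------------------------------------------------

def _complete_matrix(y) -> np.ndarray:
    if isinstance(y, ResponseData):
        if not y.is_complete:
            raise ValueError("data contain missing cells; impute first")
        return y.y
    y = np.asarray(y)
    if np.isnan(np.asarray(y, dtype=float)).any():
        raise ValueError("data contain missing cells; impute first")
    return y.astype(np.int8)


def beta_design(j: int, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Explicit design for the item-j auxiliary logistic regression: row i is
    y_i with entry 1/2 in position j (so beta_jj keeps the s_jj convention);
    responses are y_ij."""
    X = np.asarray(Y, dtype=float).copy()
    u = X[:, j].copy()
    X[:, j] = 0.5
    return X, u


def _grouped_patterns(Y: np.ndarray, zero_col: int | None = None):
    """Unique binary row patterns with counts (bincount on bit codes for
    J <= 16, np.unique above).  ``zero_col`` ignores one column when coding.
    Returns (patterns uint8 (G, J), counts (G,), sum of Y[:, zero_col] per
    group when zero_col is given else None)."""
    N, J = Y.shape
    if J <= 16:
        pow2 = (1 << np.arange(J)).astype(np.int64)
        code = Y.astype(np.int64) @ pow2
        if zero_col is not None:
            code = code - Y[:, zero_col].astype(np.int64) * pow2[zero_col]
        counts = np.bincount(code, minlength=1 << J)
        active = np.flatnonzero(counts)
        pats = ((active[:, None] >> np.arange(J)) & 1).astype(np.uint8)
        s1 = None
        if zero_col is not None:
            s1 = np.bincount(code, weights=Y[:, zero_col].astype(float),
                             minlength=1 << J)[active]
        return pats, counts[active], s1
    Yk = Y.copy()
    if zero_col is not None:
        Yk[:, zero_col] = 0
    pats, inv, counts = np.unique(Yk, axis=0, return_inverse=True, return_counts=True)
    s1 = None
    if zero_col is not None:
        s1 = np.bincount(inv, weights=Y[:, zero_col].astype(float))
    return pats.astype(np.uint8), counts, s1


def sample_beta_j(j: int, y_imputed, prior: GaussianPrior | None = None,
                  current=None, seed=None, trunc: int = DEFAULT_TRUNC_TERMS):
    """One PG sweep of the auxiliary coefficients beta_j for item j on a
    fully imputed response matrix (grouped by response pattern)."""
    Y = _complete_matrix(y_imputed)
    N, J = Y.shape
    if not 0 <= j < J:
        raise IndexError(f"item index {j} out of range for J={J}")
    rng = _as_rng(seed)
    if prior is None:
        prior = PriorSpec().beta_prior(J, j)
    current = np.zeros(J) if current is None else np.asarray(current, dtype=float)
    if N == 0:
        return _draw_mvn_canonical(np.diag(1.0 / prior.variances),
                                   prior.mean / prior.variances, rng,
                                   f"beta update for item {j + 1}")
    pats, n_g, s1 = _grouped_patterns(Y, zero_col=j)
    Xg = pats.astype(float)
    Xg[:, j] = 0.5
    ksum = s1 - n_g / 2.0
    return _pg_update_grouped(Xg, n_g, ksum, prior, current, rng, trunc,
                              f"beta update for item {j + 1}")


def vech_position_map(J: int) -> np.ndarray:
    """M[j, k] = index of s_jk within vech(S)."""
    rows, cols = vech_indices(J)
    M = np.empty((J, J), dtype=np.int64)
    M[rows, cols] = np.arange(rows.size)
    M[cols, rows] = M[rows, cols]
    return M


def build_alpha_design(y_imputed) -> tuple[np.ndarray, np.ndarray]:
    """Explicit stacked design for the joint alpha = vech(S) update.

    Pseudo-observation (i, j) sits at row i*J + j with response y_ij; its
    design row carries 1/2 on the diagonal coordinate (j, j) and y_ik on the
    pair coordinate {j, k} for k != j, so X @ vech(S) reproduces every
    conditional linear predictor.
    """
    Y = _complete_matrix(y_imputed).astype(float)
    N, J = Y.shape
    p = J * (J + 1) // 2
    M = vech_position_map(J)
    X = np.zeros((N * J, p))
    u = np.empty(N * J)
    rows = np.arange(N) * J
    for j in range(J):
        X[rows + j, M[j, j]] = 0.5
        for k in range(J):
            if k != j:
                X[rows + j, M[j, k]] = Y[:, k]
        u[rows + j] = Y[:, j]
    return X, u


def sample_alpha(y_imputed, prior: GaussianPrior | None = None, current=None,
                 seed=None, trunc: int = DEFAULT_TRUNC_TERMS) -> np.ndarray:
    """One joint PG sweep of alpha = vech(S) from the pseudo-posterior.

    All J(J+1)/2 coordinates are updated in one multivariate normal draw
    conditional on the N*J grouped augmentation variables (not
    coordinate-wise Gibbs).  The N*J design is never materialized: rows are
    grouped by full response pattern and streamed item by item into the
    precision matrix.
    """
    Y = _complete_matrix(y_imputed)
    N, J = Y.shape
    p = J * (J + 1) // 2
    rng = _as_rng(seed)
    if prior is None:
        prior = PriorSpec().alpha_prior(J)
    if prior.dim != p:
        raise ValueError("alpha prior dimension must be J(J+1)/2")
    current = np.zeros(p) if current is None else np.asarray(current, dtype=float)
    prec = np.diag(1.0 / prior.variances)
    rhs = prior.mean / prior.variances
    if N:
        pats, n_g, _ = _grouped_patterns(Y)
        P = pats.astype(float)
        Sv = _unvech_values(current, J)
        d = np.diagonal(Sv)
        eta = P @ Sv - P * d + d / 2.0                      # (G, J)
        w = _pg_gamma(np.broadcast_to(n_g[:, None], eta.shape), eta, rng,
                      trunc=trunc)                           # (G, J)
        M = vech_position_map(J)
        G = P.shape[0]
        for j in range(J):
            Dj = np.zeros((G, p))
            Dj[:, M[j, j]] = 0.5
            for k in range(J):
                if k != j:
                    Dj[:, M[j, k]] = P[:, k]
            prec += Dj.T @ (Dj * w[:, j][:, None])
            rhs = rhs + Dj.T @ (n_g * (P[:, j] - 0.5))
    return _draw_mvn_canonical(prec, rhs, rng, "joint alpha update")
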