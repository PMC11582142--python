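"""Core 0/1-coded Ising model: exact enumeration, logistic conditionals,
pseudo-likelihood, samplers and the half-vectorization reparameterization.

Coding convention
-----------------
Items are coded 0/1 (not the +/-1 "physics" convention).  For a binary
response vector ``y`` the model is

    P(Y = y | S)  =  exp( y' S y / 2 ) / c(S)
                  =  exp( sum_j s_jj y_j / 2  +  sum_{j<k} s_jk y_j y_k ) / c(S),

with ``S`` a J x J symmetric matrix: diagonal entries ``s_jj`` are main
effects (intercepts, on the log-odds scale), off-diagonal entries ``s_jk``
are edge weights.  The conditional distribution of one item given the rest
is logistic with linear predictor ``s_jj/2 + sum_{k != j} s_jk y_k``; note
the factor 1/2 on the diagonal entry.  The intercept reported to users is
``s_jj`` itself, never ``s_jj/2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.special import expit

#: enumeration over 2^J patterns is refused above this size
MAX_ENUM_ITEMS = 20


@dataclass(frozen=True)
class IsingMatrix:
    """Symmetric J x J Ising parameter matrix (log-odds scale).

    ``values[j, j]`` are main effects, ``values[j, k]`` (j != k) edge
    weights.  Entries must be finite and exactly symmetric; use
    :meth:`from_array` to symmetrize nearly-symmetric input.
    """

    values: np.ndarray
    items: tuple[str, ...] | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] < 1:
            raise ValueError(f"expected a square matrix, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("Ising matrix entries must be finite")
        if not np.array_equal(v, v.T):
            raise ValueError(
                "Ising matrix must be exactly symmetric; "
                "use IsingMatrix.from_array to symmetrize"
            )
        object.__setattr__(self, "values", v)
        if self.items is not None:
            items = tuple(str(s) for s in self.items)
            if len(items) != v.shape[0]:
                raise ValueError("items length does not match matrix size")
            object.__setattr__(self, "items", items)

    @classmethod
    def from_array(cls, a, tol: float = 1e-8, items=None) -> "IsingMatrix":
        """Build from a nearly-symmetric array; asymmetry beyond ``tol`` errors."""
        a = np.asarray(a, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError(f"expected a square matrix, got shape {a.shape}")
        if np.max(np.abs(a - a.T), initial=0.0) > tol:
            raise ValueError(f"matrix asymmetric beyond tolerance {tol}")
        return cls((a + a.T) / 2.0, items=items)

    @property
    def J(self) -> int:
        return self.values.shape[0]

    def item_names(self) -> tuple[str, ...]:
        if self.items is not None:
            return self.items
        return tuple(f"item{j + 1}" for j in range(self.J))


@dataclass
class ResponseData:
    """N x J binary item responses with a missingness mask.

    ``mask[i, j]`` is True when the response is observed.  Masked cells carry
    no information (stored as 0).  The set ``{i : mask[i, j] == False}`` is
    the missing index set for item j.
    """

    y: np.ndarray
    mask: np.ndarray
    items: tuple[str, ...] | None = None

    def __post_init__(self):
        y = np.asarray(self.y)
        mask = np.asarray(self.mask, dtype=bool)
        if y.ndim != 2:
            raise ValueError("y must be a 2-D array")
        if mask.shape != y.shape:
            raise ValueError("mask shape must match y")
        if not np.isin(y[mask], (0, 1)).all():
            raise ValueError("observed responses must be 0 or 1")
        yc = np.where(mask, y, 0).astype(np.int8)
        self.y = yc
        self.mask = mask
        if self.items is not None:
            items = tuple(str(s) for s in self.items)
            if len(items) != y.shape[1]:
                raise ValueError("items length does not match column count")
            self.items = items

    @classmethod
    def complete(cls, y, items=None) -> "ResponseData":
        y = np.asarray(y)
        return cls(y, np.ones(y.shape, dtype=bool), items=items)

    @property
    def N(self) -> int:
        return self.y.shape[0]

    @property
    def J(self) -> int:
        return self.y.shape[1]

    @property
    def n_missing(self) -> int:
        return int((~self.mask).sum())

    @property
    def is_complete(self) -> bool:
        return bool(self.mask.all())

    def complete_cases(self) -> "ResponseData":
        """Rows without any missing entry (listwise deletion)."""
        keep = self.mask.all(axis=1)
        return ResponseData(self.y[keep], self.mask[keep], items=self.items)

    def item_names(self) -> tuple[str, ...]:
        if self.items is not None:
            return self.items
        return tuple(f"item{j + 1}" for j in range(self.J))


# ---------------------------------------------------------------------------
# half-vectorization
# ---------------------------------------------------------------------------

def vech_indices(J: int) -> tuple[np.ndarray, np.ndarray]:
    """(row, col) index arrays of the lower triangle in column-major order:
    (1,1),(2,1),...,(J,1),(2,2),(3,2),...,(J,J)."""
    cols, rows = np.triu_indices(J)
    return rows, cols


def vech_names(J: int) -> list[str]:
    rows, cols = vech_indices(J)
    return [f"s_{c + 1}{r + 1}" if J < 10 else f"s_{c + 1}_{r + 1}"
            for r, c in zip(rows, cols)]


def vech(S: IsingMatrix | np.ndarray) -> np.ndarray:
    """Half-vectorize a symmetric matrix, lower triangle in column-major order."""
    v = S.values if isinstance(S, IsingMatrix) else np.asarray(S, dtype=float)
    if v.ndim != 2 or v.shape[0] != v.shape[1]:
        raise ValueError("vech expects a square matrix")
    if not np.array_equal(v, v.T):
        raise ValueError("vech expects an exactly symmetric matrix")
    rows, cols = vech_indices(v.shape[0])
    return v[rows, cols].copy()


def _unvech_values(a: np.ndarray, J: int) -> np.ndarray:
    rows, cols = vech_indices(J)
    out = np.zeros((J, J))
    out[rows, cols] = a
    out[cols, rows] = a
    return out


def unvech(a: Sequence[float] | np.ndarray) -> IsingMatrix:
    """Inverse of :func:`vech`; input length must be J(J+1)/2 for integer J."""
    a = np.asarray(a, dtype=float).ravel()
    J = int(round((math.sqrt(8 * a.size + 1) - 1) / 2))
    if J * (J + 1) // 2 != a.size:
        raise ValueError(f"length {a.size} is not J(J+1)/2 for any integer J")
    return IsingMatrix(_unvech_values(a, J))


# ---------------------------------------------------------------------------
# conditionals and pseudo-likelihood
# ---------------------------------------------------------------------------

def _linear_predictors(Svals: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """eta[i, j] = s_jj/2 + sum_{k != j} s_jk y_ik for every row of Y."""
    d = np.diagonal(Svals)
    return Y @ Svals - Y * d + d / 2.0


def conditional_probability(S: IsingMatrix, j: int, y_rest) -> float:
    """P(Y_j = 1 | Y_{-j} = y_rest) = logistic(s_jj/2 + sum_{k != j} s_jk y_k).

    ``y_rest`` holds the other J-1 items in their original order with item j
    removed.
    """
    J = S.J
    if not 0 <= j < J:
        raise IndexError(f"item index {j} out of range for J={J}")
    y_rest = np.asarray(y_rest, dtype=float).ravel()
    if y_rest.size != J - 1:
        raise ValueError(f"y_rest must have length {J - 1}, got {y_rest.size}")
    if not np.isin(y_rest, (0.0, 1.0)).all():
        raise ValueError("y_rest must be binary")
    others = np.delete(np.arange(J), j)
    eta = S.values[j, j] / 2.0 + S.values[j, others] @ y_rest
    return float(expit(eta))


def log_pseudo_likelihood(S: IsingMatrix, y) -> float | np.ndarray:
    """Log conditional (pseudo-) likelihood of one observation or a batch.

    For a single vector y returns
    ``sum_j [ eta_j y_j - log(1 + exp(eta_j)) ]`` with
    ``eta_j = s_jj/2 + sum_{k != j} s_jk y_k``; for a 2-D batch returns the
    per-row values.  Computed with softplus so it is stable for |eta| up to
    the overflow limit of exp (~700).
    """
    y = np.asarray(y, dtype=float)
    single = y.ndim == 1
    Y = np.atleast_2d(y)
    if Y.shape[1] != S.J:
        raise ValueError(f"response length {Y.shape[1]} != J={S.J}")
    if np.isnan(Y).any():
        raise ValueError("response contains missing entries")
    if not np.isin(Y, (0.0, 1.0)).all():
        raise ValueError("responses must be binary 0/1")
    eta = _linear_predictors(S.values, Y)
    ll = (eta * Y - np.logaddexp(0.0, eta)).sum(axis=1)
    return float(ll[0]) if single else ll


# ---------------------------------------------------------------------------
# exact enumeration and sampling
# ---------------------------------------------------------------------------

class PmfTable(NamedTuple):
    """All 2^J binary patterns (lexicographic in (y_1, ..., y_J)) and their
    exact probabilities."""

    patterns: np.ndarray  # (2^J, J) uint8
    probs: np.ndarray     # (2^J,)

    def prob_of(self, y) -> float:
        y = np.asarray(y).ravel()
        J = self.patterns.shape[1]
        idx = int(y @ (1 << np.arange(J - 1, -1, -1)))
        return float(self.probs[idx])


def enumerate_patterns(J: int) -> np.ndarray:
    if J > MAX_ENUM_ITEMS:
        raise ValueError(
            f"enumeration over 2^{J} patterns refused (J > {MAX_ENUM_ITEMS}); "
            "use sample_gibbs for large J"
        )
    return ((np.arange(2 ** J)[:, None] >> np.arange(J - 1, -1, -1)) & 1).astype(np.uint8)


def pmf_table(S: IsingMatrix) -> PmfTable:
    """Exact pmf by enumeration of all 2^J patterns (guarded at J <= 20)."""
    pats = enumerate_patterns(S.J)
    Y = pats.astype(float)
    logw = 0.5 * np.einsum("ij,jk,ik->i", Y, S.values, Y)
    logw -= logw.max()
    w = np.exp(logw)
    return PmfTable(pats, w / w.sum())


def sample_exact(S: IsingMatrix, n: int, seed=None) -> ResponseData:
    """n i.i.d. draws from the exact pmf (enumeration; J <= 20)."""
    rng = np.random.default_rng(seed)
    table = pmf_table(S)
    idx = rng.choice(table.probs.size, size=int(n), p=table.probs)
    return ResponseData.complete(table.patterns[idx], items=S.items)


def sample_gibbs(S: IsingMatrix, n: int, burnin: int = 200, seed=None) -> ResponseData:
    """n draws via systematic-scan Gibbs over items.

    Runs n chains in parallel from independent fair-coin starts and applies
    ``burnin`` full sweeps to each, returning the final states; suitable for
    J beyond the enumeration guard.  Draws are independent across rows up to
    residual initialization bias, which decays geometrically in ``burnin``.
    """
    if burnin < 0:
        raise ValueError("burnin must be >= 0")
    rng = np.random.default_rng(seed)
    J = S.J
    Y = (rng.random((int(n), J)) < 0.5).astype(np.int8)
    Sv = S.values
    for _ in range(int(burnin)):
        for j in range(J):
            eta = Sv[j, j] / 2.0 + Y @ Sv[:, j] - Y[:, j] * Sv[j, j]
            Y[:, j] = rng.random(int(n)) < expit(eta)
    return ResponseData.complete(Y, items=S.items)
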