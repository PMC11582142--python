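"""Synthetic truth matrices and missingness mechanisms for the two
simulation designs, so every experiment runs with no external data.

Study-I design: a J=6 Ising network whose upper-triangle edges are zero
with probability 1/2 and otherwise uniform on [-1, -0.4] u [0.4, 1], zero
intercepts; missingness of items 1..J-1 depends on the always-observed
anchor item J (missing at random, but not completely at random).

Study-II design: six items, the first two being screening items; six
strictly positive edges including one between the two screeners.  A
respondent answering 0 to both screening items has all remaining items
missing — deterministic, screening-induced MAR missingness.  Complete-case
analysis of such data suffers Berkson's paradox: the (0,0) screener pattern
is excluded, inducing a spuriously negative screener-screener edge.

Both mechanisms read only always-observed values, so they are genuinely
missing-at-random.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ising import IsingMatrix, ResponseData, sample_exact
from .polya_gamma import _as_rng

#: default Study-II edge set (0-based pairs) and weight; the first pair joins
#: the two screening items
STUDY2_EDGES = ((0, 1), (0, 2), (1, 3), (2, 4), (3, 5), (4, 5))
STUDY2_WEIGHT = 0.8


@dataclass(frozen=True)
class MissingnessSpec:
    """A masking mechanism.

    kind 'mcar': every cell masked independently with probability ``rate``.
    kind 'mar_anchor': the anchor column is never masked; every other cell
    of row i is masked with probability ``p_miss_anchor1`` when the anchor
    response is 1, else ``p_miss_anchor0``.
    kind 'screening': screening columns are never masked; the remaining
    cells of row i are masked iff every screening response is 0.
    """

    kind: str
    rate: float = 0.2
    anchor: int = 5
    p_miss_anchor1: float = 0.1
    p_miss_anchor0: float = 0.4
    screen_items: tuple[int, ...] = (0, 1)

    def __post_init__(self):
        if self.kind not in ("mcar", "mar_anchor", "screening"):
            raise ValueError(f"unknown missingness kind {self.kind!r}")
        for p in (self.rate, self.p_miss_anchor1, self.p_miss_anchor0):
            if not 0.0 <= p <= 1.0:
                raise ValueError("missingness probabilities must be in [0, 1]")
        if len(self.screen_items) == 0:
            raise ValueError("screening mechanism needs at least one item")

    @classmethod
    def mcar(cls, rate: float) -> "MissingnessSpec":
        return cls("mcar", rate=rate)

    @classmethod
    def mar_anchor(cls, anchor: int = 5, p_miss_anchor1: float = 0.1,
                   p_miss_anchor0: float = 0.4) -> "MissingnessSpec":
        return cls("mar_anchor", anchor=anchor,
                   p_miss_anchor1=p_miss_anchor1, p_miss_anchor0=p_miss_anchor0)

    @classmethod
    def screening(cls, screen_items=(0, 1)) -> "MissingnessSpec":
        return cls("screening", screen_items=tuple(screen_items))


def make_study1_truth(J: int = 6, sparsity: float = 0.5, low: float = 0.4,
                      high: float = 1.0, seed=None) -> IsingMatrix:
    """Random sparse truth: each upper-triangle edge is zero with probability
    ``sparsity``, otherwise uniform on [-high, -low] u [low, high]; zero
    intercepts."""
    if J < 2:
        raise ValueError("need at least two items")
    rng = _as_rng(seed)
    m = J * (J - 1) // 2
    nonzero = rng.random(m) >= sparsity
    mag = rng.uniform(low, high, size=m)
    sign = rng.choice([-1.0, 1.0], size=m)
    vals = np.where(nonzero, sign * mag, 0.0)
    S = np.zeros((J, J))
    iu = np.triu_indices(J, k=1)
    S[iu] = vals
    return IsingMatrix(S + S.T)


def make_study2_truth(weight: float = STUDY2_WEIGHT, edges=STUDY2_EDGES,
                      diagonal: float = 0.0, J: int = 6, seed=None) -> IsingMatrix:
    """Deterministic screening-design truth: J=6 symmetric matrix with six
    strictly positive edges (including the screener-screener edge s_12) of
    the given weight, zero elsewhere; ``seed`` is accepted for interface
    uniformity and unused."""
    if weight <= 0:
        raise ValueError("edge weight must be strictly positive")
    S = np.full((J, J), 0.0)
    np.fill_diagonal(S, diagonal)
    for j, k in edges:
        S[j, k] = S[k, j] = weight
    return IsingMatrix(S)


def apply_missingness(full: ResponseData, spec: MissingnessSpec, seed=None) -> ResponseData:
    """Mask a complete dataset under the given mechanism.  The masking
    decision reads only always-observed values (the anchor / screening
    columns) and external coin flips, so the result is missing at random."""
    if not full.is_complete:
        raise ValueError("apply_missingness expects complete data")
    rng = _as_rng(seed)
    Y = full.y
    N, J = Y.shape
    mask = np.ones((N, J), dtype=bool)
    if spec.kind == "mcar":
        if spec.rate > 0:
            mask = rng.random((N, J)) >= spec.rate
    elif spec.kind == "mar_anchor":
        if not 0 <= spec.anchor < J:
            raise ValueError("anchor index out of range")
        p = np.where(Y[:, spec.anchor] == 1, spec.p_miss_anchor1, spec.p_miss_anchor0)
        mask = rng.random((N, J)) >= p[:, None]
        mask[:, spec.anchor] = True
    else:  # screening
        items = np.asarray(spec.screen_items)
        if items.min() < 0 or items.max() >= J:
            raise ValueError("screening item index out of range")
        screened = (Y[:, items] == 0).all(axis=1)
        others = np.setdiff1d(np.arange(J), items)
        mask[np.ix_(screened, others)] = False
    return ResponseData(np.where(mask, Y, 0), mask, items=full.items)


def simulate_dataset(truth: IsingMatrix, N: int, missing: MissingnessSpec | None = None,
                     seed=None):
    """Draw N complete rows from the truth and optionally mask them.

    Returns (masked: ResponseData, complete: ResponseData)."""
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    s_draw, s_mask = ss.spawn(2)
    complete = sample_exact(truth, N, np.random.default_rng(s_draw))
    if missing is None:
        return complete, complete
    return apply_missingness(complete, missing, np.random.default_rng(s_mask)), complete
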