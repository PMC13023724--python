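"""Bayesian assignment engine.

Given an assignment block — n predicted items and n experimental peaks — the
posterior probability of a bijective assignment ``a`` is

    p(a | y)  ∝  Π_i  p_i(y_{a(i)})

with a uniform prior over assignments.  The per-site marginal assignment
probability is obtained by summing the posterior over all permutations that
map site i to peak j:

    P[i, j]  =  Σ_{a : a(i)=j} p(a | y)

The matrix P is a convex combination of permutation matrices and therefore
doubly stochastic.  Two exact routes are provided:

* :func:`marginals_by_enumeration` — sums over all n! permutations in
  log-sum-exp arithmetic (n ≤ 9); serves as the oracle.
* :func:`marginals_by_permanent` — uses the identity
  ``P[i, j] = L[i, j] · perm(minor_ij) / perm(L)`` with Ryser's exact
  permanent (n ≤ 22).

All likelihoods live in log space; any per-row rescaling of the likelihood
matrix (which is exactly what normalising each site's conditional
distribution would do) cancels between numerator and denominator and leaves
the marginals unchanged.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.special import logsumexp

from .densities import (
    Density,
    ShiftGaussian,
    ShiftGaussian2D,
    ShiftMixture,
    ShiftMixture2D,
    is_2d,
)
from .errors import BlockSizeError, InfeasibleError, UsageError
from .model import AssignmentBlock, block_key_str
from .permanent import N_PERM_MAX, permanent_scaled

#: Largest block handled by full permutation enumeration.
N_ENUM_MAX = 9

_NEG = -1.0e30  # stand-in for -inf inside linear_sum_assignment


# ---------------------------------------------------------------------------
# density evaluation


def density_1d(density: Density, y: float) -> float:
    """Evaluate a 1D shift density at y (ppm); returns a density in 1/ppm."""
    if is_2d(density):
        raise UsageError("density_1d called with a 2D density")
    return density.pdf(y)


def density_2d(density: Density, y1: float, y2: float) -> float:
    """Evaluate a 2D cross-peak density at (y1, y2) = (13C, 1H) ppm."""
    if not is_2d(density):
        raise UsageError("density_2d called with a 1D density")
    return density.pdf(y1, y2)


def conditional_row(densities_at_peaks: np.ndarray) -> np.ndarray:
    """Normalise one site's density values over the peaks to a probability vector."""
    v = np.asarray(densities_at_peaks, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise UsageError("conditional_row expects a non-empty 1D vector")
    if np.any(v < 0) or not np.all(np.isfinite(v)):
        raise UsageError("densities must be finite and non-negative")
    s = v.sum()
    if s == 0.0:
        raise InfeasibleError("site has zero density at every peak (unassignable)")
    return v / s


# ---------------------------------------------------------------------------
# likelihood and marginal containers


@dataclass
class LikelihoodMatrix:
    """Log-domain likelihoods: log_L[i, j] = log p_i(peak_j) for one block."""

    log_L: np.ndarray
    item_ids: list[str]
    peak_ids: list[str]
    block: Optional[AssignmentBlock] = None

    def __post_init__(self) -> None:
        self.log_L = np.asarray(self.log_L, dtype=float)
        n, m = self.log_L.shape
        if n != m:
            raise UsageError(f"likelihood matrix must be square, got {self.log_L.shape}")
        if len(self.item_ids) != n or len(self.peak_ids) != n:
            raise UsageError("item/peak id lists must match the matrix size")
        if np.any(np.isnan(self.log_L)) or np.any(self.log_L == math.inf):
            raise UsageError("log likelihoods must be finite or -inf")
        finite = np.isfinite(self.log_L)
        if not finite.any(axis=1).all():
            i = int(np.flatnonzero(~finite.any(axis=1))[0])
            raise InfeasibleError(
                f"item {self.item_ids[i]} has zero likelihood at every peak"
            )
        if not finite.any(axis=0).all():
            j = int(np.flatnonzero(~finite.any(axis=0))[0])
            raise InfeasibleError(
                f"peak {self.peak_ids[j]} has zero likelihood under every item"
            )

    @property
    def n(self) -> int:
        return self.log_L.shape[0]


@dataclass
class MarginalMatrix:
    """Doubly stochastic marginal assignment probabilities for one block.

    ``map_assignment[i]`` is the peak index assigned to item i under the
    maximum-a-posteriori permutation (lexicographically smallest among ties);
    ``map_log_posterior`` is its normalised log posterior probability.
    """

    P: np.ndarray
    item_ids: list[str]
    peak_ids: list[str]
    map_assignment: tuple[int, ...]
    map_log_posterior: float
    map_tie: bool = False
    block: Optional[AssignmentBlock] = None

    @property
    def n(self) -> int:
        return self.P.shape[0]

    def argmax_row(self, i: int, tol: float = 1e-9) -> tuple[int, bool]:
        """(argmax peak index, tie?) for item row i; a tie is >1 entry within tol of the max."""
        row = self.P[i]
        m = row.max()
        near = np.flatnonzero(row >= m - tol)
        return int(near[0]), len(near) > 1


# ---------------------------------------------------------------------------
# posterior computation


def build_likelihood(block: AssignmentBlock, mode: Optional[str] = None) -> LikelihoodMatrix:
    """Evaluate every item density at every peak of the block, in log space.

    ``mode`` is informational: the density objects attached to the items
    already encode the single-Gaussian (XS) or mixture (DB) form, and a
    one-component mixture is numerically identical to a single Gaussian.
    """
    if mode not in (None, "xs", "db"):
        raise UsageError(f"unknown mode {mode!r}")
    n = block.size
    log_L = np.empty((n, n))
    for i, item in enumerate(block.items):
        d = item.density
        if d is None:
            raise UsageError(
                f"item {item.item_id} has no density attached "
                "(DB mode requires fragment matching first)"
            )
        if mode == "xs" and not isinstance(d, (ShiftGaussian, ShiftGaussian2D)):
            raise UsageError(f"item {item.item_id}: xs mode expects single-Gaussian densities")
        if mode == "db" and not isinstance(d, (ShiftMixture, ShiftMixture2D)):
            raise UsageError(f"item {item.item_id}: db mode expects mixture densities")
        for j, peak in enumerate(block.peaks):
            log_L[i, j] = d.logpdf(*peak.shifts)
    return LikelihoodMatrix(
        log_L=log_L,
        item_ids=[it.item_id for it in block.items],
        peak_ids=[pk.peak_id for pk in block.peaks],
        block=block,
    )


def log_posterior_of_assignment(L: LikelihoodMatrix, perm) -> float:
    """Unnormalised log posterior of one assignment: Σ_i log L[i, perm(i)]."""
    perm = tuple(int(p) for p in perm)
    n = L.n
    if sorted(perm) != list(range(n)):
        raise UsageError(f"perm {perm} is not a bijection of size {n}")
    return float(sum(L.log_L[i, perm[i]] for i in range(n)))


def _map_tolerance(v: float) -> float:
    return 1e-9 * (1.0 + abs(v))


def marginals_by_enumeration(L: LikelihoodMatrix, n_enum_max: int = N_ENUM_MAX) -> MarginalMatrix:
    """Exact marginals by summing over all n! permutations (log-sum-exp).

    The oracle path; refuses n > ``n_enum_max`` (use
    :func:`marginals_by_permanent` instead).
    """
    n = L.n
    if n > n_enum_max:
        raise BlockSizeError(
            f"block size {n} exceeds the enumeration limit {n_enum_max}; "
            "use marginals_by_permanent"
        )
    perms = np.array(list(itertools.permutations(range(n))), dtype=np.intp)
    scores = L.log_L[np.arange(n)[None, :], perms].sum(axis=1)
    logZ = float(logsumexp(scores))
    if logZ == -math.inf:
        raise InfeasibleError("no assignment has nonzero posterior probability")
    w = np.exp(scores - logZ)
    P = np.empty((n, n))
    for i in range(n):
        P[i] = np.bincount(perms[:, i], weights=w, minlength=n)

    best = float(scores.max())
    near = np.flatnonzero(scores >= best - _map_tolerance(best))
    # itertools.permutations yields lexicographic order, so near[0] is the
    # lexicographically smallest MAP assignment.
    map_perm = tuple(int(j) for j in perms[near[0]])
    return MarginalMatrix(
        P=P,
        item_ids=L.item_ids,
        peak_ids=L.peak_ids,
        map_assignment=map_perm,
        map_log_posterior=float(scores[near[0]] - logZ),
        map_tie=len(near) > 1,
        block=L.block,
    )


def _lsa_max(log_L: np.ndarray) -> float:
    """Maximum assignment score (sum of entries over a bijection); -inf as _NEG."""
    if log_L.size == 0:
        return 0.0
    cost = np.where(np.isfinite(log_L), log_L, _NEG)
    rows, cols = linear_sum_assignment(cost, maximize=True)
    return float(cost[rows, cols].sum())


def _map_lexicographic(log_L: np.ndarray) -> tuple[tuple[int, ...], float, bool]:
    """MAP permutation, its unnormalised log score, and a tie flag.

    Chooses the lexicographically smallest optimal permutation by fixing
    rows in order and testing, for each candidate column in ascending order,
    whether the optimum is still attainable.
    """
    n = log_L.shape[0]
    vstar = _lsa_max(log_L)
    if vstar <= _NEG / 2:
        raise InfeasibleError("no assignment has nonzero posterior probability")
    tol = _map_tolerance(vstar)
    remaining = list(range(n))
    perm: list[int] = []
    prefix = 0.0
    tie = False
    for i in range(n):
        candidates = []
        for jpos, j in enumerate(remaining):
            if not math.isfinite(log_L[i, j]):
                continue
            rest_cols = remaining[:jpos] + remaining[jpos + 1 :]
            sub = log_L[np.ix_(range(i + 1, n), rest_cols)]
            val = prefix + log_L[i, j] + _lsa_max(sub)
            if val >= vstar - tol:
                candidates.append(j)
        if not candidates:  # pragma: no cover - guarded by vstar feasibility
            raise InfeasibleError("assignment search failed unexpectedly")
        if len(candidates) > 1:
            tie = True
        j = candidates[0]
        perm.append(j)
        prefix += log_L[i, j]
        remaining.remove(j)
    return tuple(perm), prefix, tie


def marginals_by_permanent(L: LikelihoodMatrix, n_perm_max: int = N_PERM_MAX) -> MarginalMatrix:
    """Exact marginals via matrix permanents: P[i,j] = L[i,j]·perm(minor_ij)/perm(L).

    Identical contract to :func:`marginals_by_enumeration`; handles blocks up
    to ``n_perm_max`` (Ryser's algorithm, O(2^n · n) per permanent).
    """
    n = L.n
    if n > n_perm_max:
        raise BlockSizeError(
            f"block size {n} exceeds the permanent limit {n_perm_max}; "
            "subdivide the block (e.g. by multiplicity or spectral region)"
        )
    # Marginals are invariant under any positive rescaling of rows and
    # columns (both cancel between perm(minor) products and perm(L)).  A few
    # Sinkhorn balancing sweeps in log space compress the dynamic range of
    # the matrix, which keeps Ryser's alternating sum well conditioned even
    # for likelihood ratios spanning hundreds of orders of magnitude.
    balanced = L.log_L.copy()
    r_off = np.zeros(n)
    c_off = np.zeros(n)
    for _ in range(30):
        r = logsumexp(balanced, axis=1)
        balanced -= r[:, None]
        r_off += r
        c = logsumexp(balanced, axis=0)
        balanced -= c[None, :]
        c_off += c
        if max(np.abs(r).max(), np.abs(c).max()) < 1e-12:
            break
    M = np.exp(balanced)
    log_perm_M, ok = permanent_scaled(M, n_perm_max=n_perm_max)
    if not ok:
        raise InfeasibleError("no assignment has nonzero posterior probability")

    P = np.zeros((n, n))
    idx = np.arange(n)
    for i in range(n):
        minor_rows = idx[idx != i]
        for j in range(n):
            if M[i, j] == 0.0:
                continue
            minor = M[np.ix_(minor_rows, idx[idx != j])]
            log_perm_minor, ok_minor = permanent_scaled(minor, n_perm_max=n_perm_max)
            if not ok_minor:
                continue
            P[i, j] = math.exp(math.log(M[i, j]) + log_perm_minor - log_perm_M)

    map_perm, map_score, tie = _map_lexicographic(L.log_L)
    log_perm_L = log_perm_M + float(r_off.sum() + c_off.sum())
    return MarginalMatrix(
        P=P,
        item_ids=L.item_ids,
        peak_ids=L.peak_ids,
        map_assignment=map_perm,
        map_log_posterior=map_score - log_perm_L,
        map_tie=tie,
        block=L.block,
    )


def assign_block(
    block: AssignmentBlock,
    mode: Optional[str] = None,
    n_enum_max: int = N_ENUM_MAX,
    n_perm_max: int = N_PERM_MAX,
) -> MarginalMatrix:
    """Compute the marginal assignment matrix for one block.

    Dispatches to exact enumeration for n ≤ ``n_enum_max`` and to the
    permanent route for n ≤ ``n_perm_max``; larger blocks are refused with
    advice to subdivide (no silent approximation is ever made).
    """
    L = build_likelihood(block, mode=mode)
    if block.size <= n_enum_max:
        return marginals_by_enumeration(L, n_enum_max=n_enum_max)
    if block.size <= n_perm_max:
        return marginals_by_permanent(L, n_perm_max=n_perm_max)
    raise BlockSizeError(
        f"block {block_key_str(block.block_key)} has {block.size} sites, above the "
        f"exact limit {n_perm_max}; subdivide it (finer multiplicity/region labels)"
    )


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class AccuracyResult:
    """Top-1 assignment accuracy over a set of marginal matrices."""

    accuracy: float
    n_items: int
    n_correct: int
    n_ties: int
    tied_items: list[str] = field(default_factory=list)


def accuracy_top1(marginals: list[MarginalMatrix], truth: dict[str, str]) -> AccuracyResult:
    """Fraction of items whose highest-marginal peak is the true peak.

    ``truth`` maps item_id -> peak_id and must cover every item.  An argmax
    tie counts as incorrect and the item is reported in ``tied_items``.
    """
    n_items = n_correct = n_ties = 0
    tied: list[str] = []
    for mm in marginals:
        for i, item_id in enumerate(mm.item_ids):
            if item_id not in truth:
                raise UsageError(f"item {item_id} missing from the truth map")
            n_items += 1
            j, tie = mm.argmax_row(i)
            if tie:
                n_ties += 1
                tied.append(item_id)
            elif mm.peak_ids[j] == truth[item_id]:
                n_correct += 1
    if n_items == 0:
        raise UsageError("no items to score")
    return AccuracyResult(
        accuracy=n_correct / n_items,
        n_items=n_items,
        n_correct=n_correct,
        n_ties=n_ties,
        tied_items=tied,
    )
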