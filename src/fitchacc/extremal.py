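"""Extremal tree shapes: specialized recurrences, asymptotics, thresholds.

Three families sit at the extremes of tree balance:

* the *equal-branch complete binary tree* with ``2^n`` leaves, where the
  root class vector follows a one-dimensional iterated map over levels;
* the *equal-branch comb* (caterpillar), where each step attaches one new
  leaf next to the previous comb;
* the *Hennigian comb*, an ultrametric caterpillar with equal interior edge
  lengths and pendant edges sized so all leaves are equidistant from the
  root.

For the complete binary tree there is an equilibrium interval of the
conservation probability ``q`` in which the limiting ambiguous accuracy
equals random guessing ``1/N``; its upper end ``b`` is located here by
bisection on the iterated level map.  For the Hennigian comb the ambiguous
accuracy always degenerates to ``1/N`` while the unambiguous accuracy tends
to a closed-form limit independent of the edge length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from math import factorial
from typing import Dict, List, Optional, Tuple

import numpy as np

from .recurrence import (
    AccuracyResult,
    CombinationKernel,
    accuracies_from_classvector,
    branch_mixing,
    build_combination_kernel,
    combine_children,
    leaf_class_vector,
)
from .trees import DomainError, Node, PhyloTree, branch_prob_from_length

__all__ = [
    "EquilibriumResult",
    "build_complete_binary",
    "build_comb",
    "build_hennigian",
    "complete_binary_level_map",
    "comb_step",
    "comb_accuracy",
    "hennigian_accuracy",
    "hennigian_limiting_ua",
    "hennigian_limiting_ua_exact",
    "path_accuracy",
    "estimate_threshold_b",
]

_STATIONARY_TOL = 1e-13


# ---------------------------------------------------------------------------
# explicit tree builders (used by cross-checks and the CLI)


def build_complete_binary(levels: int, p: float) -> PhyloTree:
    """Equal-branch complete binary tree with ``2**levels`` leaves."""
    if levels < 1:
        raise DomainError("levels must be >= 1")
    counter = [0]

    def rec(depth: int) -> Node:
        if depth == 0:
            counter[0] += 1
            return Node(name=f"t{counter[0]}", branch_p=p)
        return Node(branch_p=p, children=[rec(depth - 1), rec(depth - 1)])

    root = Node(children=[rec(levels - 1), rec(levels - 1)])
    return PhyloTree(root)


def build_comb(n_leaves: int, p: float) -> PhyloTree:
    """Equal-branch caterpillar with ``n_leaves`` leaves.

    Every internal node has a leaf child; the two deepest leaves form a
    cherry.  All branches carry the same substitution probability.
    """
    if n_leaves < 2:
        raise DomainError("a comb needs at least 2 leaves")
    node = Node(
        children=[Node(name="t1", branch_p=p), Node(name="t2", branch_p=p)]
    )
    for k in range(3, n_leaves + 1):
        node.branch_p = p
        node = Node(children=[Node(name=f"t{k}", branch_p=p), node])
    node.branch_p = None
    return PhyloTree(node)


def build_hennigian(n_leaves: int, l: float, rate: float, N: int) -> PhyloTree:
    """Ultrametric caterpillar: interior edges of length ``l``, pendant edges
    sized so every leaf sits at depth ``(n_leaves - 1) * l`` from the root.

    The leaf hanging off the ``k``-th interior node (root = 1st) gets pendant
    length ``(n_leaves - k) * l``; the deepest interior node carries two
    pendant leaves of length ``l``.  Branch probabilities follow the
    Jukes--Cantor length map.
    """
    if n_leaves < 2:
        raise DomainError("a comb needs at least 2 leaves")
    p_int = branch_prob_from_length(l, rate, N)
    node = Node(
        children=[
            Node(name="t1", branch_p=p_int, branch_length=l),
            Node(name="t2", branch_p=p_int, branch_length=l),
        ]
    )
    # node currently is interior node n_leaves-1; climb to the root
    for k in range(n_leaves - 2, 0, -1):
        node.branch_p = p_int
        node.branch_length = l
        pend = (n_leaves - k) * l
        leaf = Node(
            name=f"t{n_leaves + 1 - k}",
            branch_p=branch_prob_from_length(pend, rate, N),
            branch_length=pend,
        )
        node = Node(children=[node, leaf])
    return PhyloTree(node)


# ---------------------------------------------------------------------------
# specialized recurrences


def complete_binary_level_map(
    A: np.ndarray, p: float, N: int, kernel: Optional[CombinationKernel] = None
) -> np.ndarray:
    """One level step of the equal-branch complete binary tree.

    Both subtrees of the root are copies of the previous level, so the root
    vector of ``T_n`` is the combination of two identically mixed copies of
    the root vector of ``T_{n-1}``; iterating ``n`` times from the leaf
    vector yields the tree with ``2^n`` leaves.

    The map is quadratic in ``A``, so a rounding error ``eps`` in the
    vector's total doubles per application and would destroy long iterations
    (the total evolves as ``(1 + eps)^(2^t)``).  The output is therefore
    rescaled to total one, after checking the drift is at rounding level.
    """
    if kernel is None:
        kernel = build_combination_kernel(N)
    M = branch_mixing(A, p, N)
    out = combine_children(M, M, kernel)
    total = out.sum()
    if abs(total - 1.0) > 1e-6:
        raise AssertionError(f"level map lost normalization (sum={total!r})")
    return out / total


def comb_step(
    A_prev: np.ndarray, p: float, N: int, kernel: Optional[CombinationKernel] = None
) -> np.ndarray:
    """Grow an equal-branch comb by one leaf.

    The root of the ``n``-leaf comb has a single pendant leaf on one side and
    the ``(n-1)``-leaf comb on the other, both across branches with the same
    ``p``; starting from the leaf vector (``n = 1``) each step adds a leaf.
    """
    if kernel is None:
        kernel = build_combination_kernel(N)
    return combine_children(
        branch_mixing(leaf_class_vector(N), p, N),
        branch_mixing(A_prev, p, N),
        kernel,
    )


def comb_accuracy(n_leaves: int, p: float, N: int) -> AccuracyResult:
    """UA/AA at the root of the equal-branch comb with ``n_leaves`` leaves."""
    if n_leaves < 1:
        raise DomainError("n_leaves must be >= 1")
    kernel = build_combination_kernel(N)
    A = leaf_class_vector(N)
    for _ in range(n_leaves - 1):
        A = comb_step(A, p, N, kernel)
    return accuracies_from_classvector(A, N)


def hennigian_accuracy(n: int, l: float, rate: float, N: int) -> AccuracyResult:
    """UA/AA at the root of the Hennigian comb with ``n`` leaves.

    Evaluated by walking the interior path from the deepest cherry up to the
    root (``O(n)`` kernel applications) with the pendant branch of the
    ``k``-th interior node spanning length ``(n - k) l``.
    """
    if n < 2:
        raise DomainError("n must be >= 2")
    if l <= 0:
        raise DomainError("edge length must be positive")
    kernel = build_combination_kernel(N)
    p_int = branch_prob_from_length(l, rate, N)
    leaf = leaf_class_vector(N)
    A = combine_children(
        branch_mixing(leaf, p_int, N), branch_mixing(leaf, p_int, N), kernel
    )
    for k in range(n - 2, 0, -1):
        pend = branch_prob_from_length((n - k) * l, rate, N)
        A = combine_children(
            branch_mixing(A, p_int, N), branch_mixing(leaf, pend, N), kernel
        )
    return accuracies_from_classvector(A, N)


def hennigian_limiting_ua_exact(N: int) -> Fraction:
    """Limiting UA on Hennigian combs as ``n`` grows, as an exact rational.

    ``UA_inf(N) = N^(N-2) / sum_{i=1..N} N^(N-i) (N-1)! / (N-i)!``; the limit
    does not depend on the edge length.  Exact integer arithmetic keeps the
    value reliable for large ``N`` (factorials up to ``N = 50`` and beyond).
    """
    if N < 2:
        raise DomainError(f"number of states must be >= 2, got {N}")
    denom = sum(N ** (N - i) * factorial(N - 1) // factorial(N - i) for i in range(1, N + 1))
    return Fraction(N ** (N - 2), denom)


def hennigian_limiting_ua(N: int) -> float:
    """Float value of :func:`hennigian_limiting_ua_exact`."""
    return float(hennigian_limiting_ua_exact(N))


def path_accuracy(k: int, p: float, N: int) -> float:
    """Accuracy of reconstructing the root by copying a leaf ``k`` branches
    below it: the ``k``-step conservation probability
    ``1/N + ((N-1)/N) (1 - N p)^k``.  UA and AA coincide (the reconstructed
    set is always a singleton).
    """
    if k < 0:
        raise DomainError("k must be >= 0")
    if not (-1e-12 <= p <= 1.0 / N + 1e-12):
        raise DomainError(f"branch probability {p} outside [0, 1/N] for N={N}")
    return 1.0 / N + (N - 1) / N * (1.0 - N * p) ** k


# ---------------------------------------------------------------------------
# equilibrium threshold of the complete binary tree


@dataclass
class EquilibriumResult:
    """Equilibrium interval ``[a, b]`` of the conservation probability.

    For ``q`` in ``(a, b)`` the iterated level map drives AA to ``1/N``
    (random guessing); above ``b`` the limit is informative.  ``a`` is 0 for
    ``N >= 3``; for ``N = 2`` the region below ``a`` shows period-2 behavior
    (the even and odd level subsequences converge to different limits).
    """

    N: int
    b: float
    a: float
    diagnostics: Dict[str, float] = field(default_factory=dict)


def _iterate_level_map(
    q: float, N: int, kernel: CombinationKernel, max_iters: int
) -> Tuple[np.ndarray, np.ndarray, int, bool]:
    """Iterate the level map at conservation probability ``q``.

    Returns the last two iterates (current, previous), the iteration count
    and whether period-2 stationarity (``|A_t - A_{t-2}| < 1e-13``) was
    reached.  Comparing two levels apart makes the test valid both for fixed
    points and for the 2-state alternating regime.
    """
    p = (1.0 - q) / (N - 1)
    A = leaf_class_vector(N)
    prev = A
    prev2 = None
    for it in range(1, max_iters + 1):
        A_new = complete_binary_level_map(A, p, N, kernel)
        prev2, prev, A = prev, A, A_new
        if prev2 is not None and float(np.max(np.abs(A - prev2))) < _STATIONARY_TOL:
            return A, prev, it, True
    return A, prev, max_iters, False


def _classify_equilibrium(
    q: float, N: int, kernel: CombinationKernel, max_iters: int, detect_tol: float
) -> Tuple[bool, float, float]:
    """Classify ``q``; returns (is_equilibrium, AA_even, AA_odd)."""
    A, prev, _, _ = _iterate_level_map(q, N, kernel, max_iters)
    aa_even = accuracies_from_classvector(A, N).aa
    aa_odd = accuracies_from_classvector(prev, N).aa
    target = 1.0 / N
    is_eq = abs(aa_even - target) < detect_tol and abs(aa_odd - target) < detect_tol
    return is_eq, aa_even, aa_odd


def estimate_threshold_b(
    N: int,
    max_iters: int = 10000,
    bisect_tol: float = 1e-4,
    detect_tol: float = 1e-5,
) -> EquilibriumResult:
    """Locate the equilibrium interval of the complete binary tree.

    Bisection on ``q``: a candidate is "equilibrium" when the iterated level
    map (run to period-2 stationarity or ``max_iters``) leaves both level
    subsequences with ``|AA - 1/N| < detect_tol``.  The boundary between the
    equilibrium and informative classifications is ``b``.  For ``N = 2`` the
    lower endpoint ``a`` is located the same way on the divergence criterion
    ``|AA_even - AA_odd| > detect_tol``; for ``N >= 3`` equilibrium is
    verified at small ``q`` and ``a`` is reported as 0.
    """
    kernel = build_combination_kernel(N)
    target = 1.0 / N

    def is_eq(q: float) -> bool:
        return _classify_equilibrium(q, N, kernel, max_iters, detect_tol)[0]

    q_lo = 0.5 if N == 2 else 1.0 / N + 0.01
    q_hi = 0.999
    if not is_eq(q_lo):
        raise RuntimeError(
            f"lower bisection endpoint q={q_lo} did not classify as equilibrium"
        )
    if is_eq(q_hi):
        raise RuntimeError(
            f"upper bisection endpoint q={q_hi} did not classify as informative"
        )
    lo, hi = q_lo, q_hi
    b_iters = 0
    while hi - lo > bisect_tol:
        mid = 0.5 * (lo + hi)
        if is_eq(mid):
            lo = mid
        else:
            hi = mid
        b_iters += 1
    b = 0.5 * (lo + hi)

    if N == 2:

        def is_div(q: float) -> bool:
            _, aa_even, aa_odd = _classify_equilibrium(
                q, N, kernel, max_iters, detect_tol
            )
            return abs(aa_even - aa_odd) > detect_tol

        lo_a, hi_a = 0.01, 0.49
        if not is_div(lo_a):
            raise RuntimeError("expected period-2 divergence at q=0.01 for N=2")
        if is_div(hi_a):
            raise RuntimeError("expected equilibrium convergence at q=0.49 for N=2")
        while hi_a - lo_a > bisect_tol:
            mid = 0.5 * (lo_a + hi_a)
            if is_div(mid):
                lo_a = mid
            else:
                hi_a = mid
        a = 0.5 * (lo_a + hi_a)
    else:
        for q in (0.01, 0.05, 0.1):
            if not is_eq(q):
                raise RuntimeError(
                    f"q={q} unexpectedly informative for N={N}; equilibrium "
                    "interval does not extend to 0"
                )
        a = 0.0

    return EquilibriumResult(
        N=N,
        b=b,
        a=a,
        diagnostics={
            "bisection_iterations": b_iters,
            "bisect_tol": bisect_tol,
            "detect_tol": detect_tol,
            "aa_target": target,
        },
    )
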