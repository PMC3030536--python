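"""Exact Fitch reconstruction accuracies via the symmetry-reduced recurrence.

The probability that the Fitch leaf-to-root stage reconstructs a particular
state set at a node, conditional on the node's true state, depends only on
the set's size and on whether it contains the true state.  The ``2^N - 1``
nonempty subsets of the state space therefore collapse into ``2N - 1``
classes ``(i, c)`` with size ``i`` and indicator ``c`` (set contains the true
state), and the full dynamic program over subsets reduces to a linear
recurrence over class probabilities:

* a *branch mixing* step transports a child's class vector (conditional on
  the child's true state) to the parent's conditioning state, using only the
  branch substitution probability ``p``;
* a *combination* step applies the Fitch intersect-else-union rule to two
  independent child sets that are, by symmetry, uniform within their classes,
  which makes the intersection size hypergeometric.

Unambiguous accuracy (UA) is the probability the root set is exactly the
true-state singleton; ambiguous accuracy (AA) additionally credits a set
containing the true state with ``1/|set|`` (a uniform draw from the set).

Class vectors here hold CLASS-TOTAL probabilities and always sum to one,
which is enforced as a running invariant rather than fixed by renormalizing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache
from math import comb
from typing import Dict, Optional, Tuple

import numpy as np

from .trees import DomainError, PhyloTree

__all__ = [
    "ClassPartition",
    "CombinationKernel",
    "AccuracyResult",
    "leaf_class_vector",
    "branch_mixing",
    "build_combination_kernel",
    "combine_children",
    "tree_accuracy",
    "accuracies_from_classvector",
]

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class ClassPartition:
    """Index map between classes ``(i, c)`` and vector positions.

    Class ``(i, 1)`` (size-``i`` sets containing the true state) sits at
    0-based index ``2i - 2`` for ``i = 1..N``; class ``(i, 0)`` at ``2i - 1``
    for ``i = 1..N-1``.  Class ``(N, 0)`` does not exist: a size-``N`` set is
    the whole state space and necessarily contains the true state.  Class
    ``(i, 1)`` holds ``C(N-1, i-1)`` sets and class ``(i, 0)`` holds
    ``C(N-1, i)``, which together exhaust the ``2^N - 1`` nonempty subsets.
    """

    N: int

    def __post_init__(self) -> None:
        if self.N < 2:
            raise DomainError(f"number of states must be >= 2, got {self.N}")

    @property
    def n_classes(self) -> int:
        return 2 * self.N - 1

    def index(self, i: int, c: int) -> int:
        if not (1 <= i <= self.N) or c not in (0, 1):
            raise ValueError(f"no class ({i}, {c}) for N={self.N}")
        if c == 0 and i == self.N:
            raise ValueError(f"class ({self.N}, 0) does not exist")
        return 2 * i - 2 if c == 1 else 2 * i - 1

    def cls(self, index: int) -> Tuple[int, int]:
        if not 0 <= index < self.n_classes:
            raise ValueError(f"index {index} out of range")
        return (index // 2 + 1, 1) if index % 2 == 0 else (index // 2 + 1, 0)

    def classes(self):
        return [self.cls(k) for k in range(self.n_classes)]

    def cardinality(self, i: int, c: int) -> int:
        return comb(self.N - 1, i - 1) if c == 1 else comb(self.N - 1, i)


@dataclass
class AccuracyResult:
    """Unambiguous (UA) and ambiguous (AA) root reconstruction accuracy."""

    ua: float
    aa: float
    diagnostics: Dict[str, float] = field(default_factory=dict)

    def __iter__(self):
        yield self.ua
        yield self.aa


def leaf_class_vector(N: int) -> np.ndarray:
    """Class vector of a leaf: the singleton of its own state, surely."""
    part = ClassPartition(N)
    A = np.zeros(part.n_classes)
    A[part.index(1, 1)] = 1.0
    return A


def branch_mixing(A_child: np.ndarray, p: float, N: int) -> np.ndarray:
    """Transport a class vector across a branch with substitution prob ``p``.

    ``A_child`` is conditional on the child's true state; the result is
    conditional on the parent's.  Conditioning on the child's state: with
    probability ``q = 1 - (N-1)p`` it equals the parent's, and with
    probability ``p`` each it is one of the ``N - 1`` other states ``j``.  By
    exchangeability over non-true states, a size-``i`` set containing its own
    true state ``j`` contains the parent's state with probability
    ``(i-1)/(N-1)``, and a size-``i`` set avoiding ``j`` with probability
    ``i/(N-1)``; summing over the ``N - 1`` values of ``j`` gives

        m(i,1) = q a(i,1) + p [ (i-1) a(i,1) + i a(i,0) ]
        m(i,0) = q a(i,0) + p [ (N-i) a(i,1) + (N-1-i) a(i,0) ]

    The size marginal ``a(i,1) + a(i,0)`` is preserved (the set itself does
    not change, only the conditioning state).  ``p`` may exceed ``1/N`` up to
    ``1/(N-1)`` (q >= 0): the map is well defined on the whole stochastic
    range even where the length parameterization cannot reach.
    """
    part = ClassPartition(N)
    if not (-1e-12 <= p <= 1.0 / (N - 1) + 1e-12):
        raise DomainError(f"branch probability {p} outside [0, 1/(N-1)] for N={N}")
    q = 1.0 - (N - 1) * p
    M = np.zeros_like(A_child)
    for i in range(1, N + 1):
        a1 = A_child[part.index(i, 1)]
        a0 = A_child[part.index(i, 0)] if i < N else 0.0
        M[part.index(i, 1)] = q * a1 + p * ((i - 1) * a1 + i * a0)
        if i < N:
            M[part.index(i, 0)] = q * a0 + p * ((N - i) * a1 + (N - 1 - i) * a0)
    return M


@dataclass(frozen=True)
class CombinationKernel:
    """Transition table of the Fitch combination on class pairs.

    ``tensor[a, b, k]`` is the probability that combining an independent pair
    of sets uniform on classes ``a`` and ``b`` yields a set in class ``k``.
    Built once per ``N`` with exact rational arithmetic and stored as floats.
    """

    N: int
    tensor: np.ndarray

    def combine(self, M_X: np.ndarray, M_Y: np.ndarray) -> np.ndarray:
        if M_X.shape != (2 * self.N - 1,) or M_Y.shape != (2 * self.N - 1,):
            raise ValueError("class-vector length does not match kernel N")
        return np.einsum("i,ijk,j->k", M_X, self.tensor, M_Y)


@lru_cache(maxsize=None)
def build_combination_kernel(N: int) -> CombinationKernel:
    """Build the Fitch combination kernel for ``N`` states.

    For child sets uniform on classes ``(i, c)`` and ``(j, c')`` let
    ``i' = i - c`` and ``j' = j - c'`` be the sizes of their non-true-state
    parts, which are independent uniform subsets of the ``N - 1`` non-true
    states.  Their overlap ``m`` is hypergeometric,
    ``P(m) = C(i', m) C(N-1-i', j'-m) / C(N-1, j')``, and the true state lies
    in the intersection iff ``c c' = 1``.  The Fitch rule then lands in class
    ``(m + c c', c c')`` when the intersection is nonempty and in the union
    class ``(i + j, max(c, c'))`` otherwise.
    """
    part = ClassPartition(N)
    K = part.n_classes
    table = [[[Fraction(0)] * K for _ in range(K)] for _ in range(K)]
    for a in range(K):
        i, c = part.cls(a)
        for b in range(K):
            j, c2 = part.cls(b)
            i_, j_ = i - c, j - c2
            denom = comb(N - 1, j_)
            lo = max(0, j_ - (N - 1 - i_))
            hi = min(i_, j_)
            for m in range(lo, hi + 1):
                prob = Fraction(comb(i_, m) * comb(N - 1 - i_, j_ - m), denom)
                inter = m + c * c2
                if inter >= 1:
                    k = part.index(inter, c * c2)
                else:
                    k = part.index(i + j, max(c, c2))
                table[a][b][k] += prob
    tensor = np.array(
        [[[float(x) for x in row] for row in plane] for plane in table]
    )
    return CombinationKernel(N=N, tensor=tensor)


def combine_children(
    M_X: np.ndarray, M_Y: np.ndarray, kernel: CombinationKernel
) -> np.ndarray:
    """Class vector of a parent from its two branch-mixed child vectors."""
    return kernel.combine(M_X, M_Y)


def accuracies_from_classvector(A: np.ndarray, N: int) -> AccuracyResult:
    """UA and AA from a root class vector.

    ``UA = A[(1,1)]`` and ``AA = sum_k A[(k,1)] / k``: a root set of size
    ``k`` containing the true state yields it with probability ``1/k`` under
    the uniform root draw of the Fitch top-down stage.
    """
    part = ClassPartition(N)
    total = float(A.sum())
    if abs(total - 1.0) > _SUM_TOL:
        raise ValueError(f"class vector is not normalized (sum={total!r})")
    ua = float(A[part.index(1, 1)])
    aa = float(sum(A[part.index(k, 1)] / k for k in range(1, N + 1)))
    return AccuracyResult(ua=ua, aa=aa)


def _node_class_vector(tree: PhyloTree, N: int, kernel: CombinationKernel) -> np.ndarray:
    vectors: Dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            A = leaf_class_vector(N)
        else:
            mixed = []
            for child in node.children:
                if child.branch_p is None:
                    raise ValueError("tree has a branch without branch_p")
                mixed.append(branch_mixing(vectors.pop(id(child)), child.branch_p, N))
            if len(mixed) == 2:
                A = combine_children(mixed[0], mixed[1], kernel)
            elif len(mixed) == 1 and node is tree.root:
                A = mixed[0]  # single-child root from leaf-subset restriction
            else:
                raise ValueError("non-root internal node must have two children")
        if abs(A.sum() - 1.0) > _SUM_TOL:
            raise AssertionError("class vector lost normalization during traversal")
        vectors[id(node)] = A
    return vectors[id(tree.root)]


def tree_accuracy(
    tree: PhyloTree, N: int, kernel: Optional[CombinationKernel] = None
) -> AccuracyResult:
    """Exact UA/AA of the Fitch method at the root of an arbitrary tree.

    One post-order sweep: leaves start at the singleton class vector, each
    branch applies :func:`branch_mixing`, each internal node applies the
    combination kernel.  Cost ``O(#nodes * N^3)``.
    """
    if kernel is None:
        kernel = build_combination_kernel(N)
    if tree.root.is_leaf:
        return AccuracyResult(ua=1.0, aa=1.0)
    return accuracies_from_classvector(_node_class_vector(tree, N, kernel), N)
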