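"""Ground truth and stochastic machinery for validating the recurrence.

* exact enumeration of all leaf-state configurations on small trees (the
  definitional form of the accuracies, used as the independent oracle);
* Markov character-evolution simulation along a tree;
* a vectorized Monte-Carlo accuracy estimator;
* a Yule (pure-birth) topology generator.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Sequence

import numpy as np
import pandas as pd

from .extremal import complete_binary_level_map
from .recurrence import (
    AccuracyResult,
    accuracies_from_classvector,
    build_combination_kernel,
    leaf_class_vector,
    tree_accuracy,
)
from .trees import DomainError, Node, PhyloTree

__all__ = [
    "MCEstimate",
    "simulate_evolution",
    "exact_enumeration_accuracy",
    "estimate_accuracy_mc",
    "generate_yule",
    "yule_experiment",
]

_ENUM_CAP = 10_000_000


@dataclass
class MCEstimate:
    """Monte-Carlo estimates of UA and AA with binomial-style standard errors."""

    ua_hat: float
    aa_hat: float
    se_ua: float
    se_aa: float
    reps: int
    seed: int


def simulate_evolution(
    tree: PhyloTree, root_state: int, rng: np.random.Generator, N: int
) -> Dict[str, int]:
    """Evolve a character down the tree; returns leaf name -> state.

    Each branch keeps the parent state with probability ``q = 1 - (N-1) p``
    and otherwise moves to one of the other ``N - 1`` states uniformly.
    """
    if not 1 <= root_state <= N:
        raise DomainError(f"root state {root_state} outside 1..{N}")
    leaf_states: Dict[str, int] = {}

    def rec(node: Node, state: int) -> None:
        if node.is_leaf:
            leaf_states[node.name] = state
            return
        for child in node.children:
            if child.branch_p is None:
                raise ValueError("tree has a branch without branch_p")
            q = 1.0 - (N - 1) * child.branch_p
            if rng.random() < q:
                child_state = state
            else:
                t = int(rng.integers(1, N))  # uniform over the other N-1 states
                child_state = t if t < state else t + 1
            rec(child, child_state)

    rec(tree.root, root_state)
    return leaf_states


def _conditional_leaf_likelihood(
    node: Node, states: Dict[str, int], N: int
) -> np.ndarray:
    """Pruning vector L[x] = P(observed leaf states below node | node state x).

    Leaves missing from ``states`` are marginalized (contribute ones), which
    is what restricting attention to a taxon subset amounts to.
    """
    if node.is_leaf:
        L = np.ones(N) if node.name not in states else np.zeros(N)
        if node.name in states:
            L[states[node.name] - 1] = 1.0
        return L
    out = np.ones(N)
    for child in node.children:
        Lc = _conditional_leaf_likelihood(child, states, N)
        p = child.branch_p
        q = 1.0 - (N - 1) * p
        out *= q * Lc + p * (Lc.sum() - Lc)
    return out


def _fitch_root_set(tree: PhyloTree, states: Dict[str, int]) -> FrozenSet[int]:
    sets: Dict[int, FrozenSet[int]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            sets[id(node)] = frozenset({states[node.name]})
        else:
            cs = [sets[id(c)] for c in node.children]
            if len(cs) == 1:
                sets[id(node)] = cs[0]
            else:
                inter = cs[0] & cs[1]
                sets[id(node)] = inter if inter else cs[0] | cs[1]
    return sets[id(tree.root)]


def exact_enumeration_accuracy(tree: PhyloTree, N: int) -> AccuracyResult:
    """Definitional UA/AA by enumerating every leaf-state configuration.

    Sums ``Pr[D | root state 1]`` (by pruning) times the Fitch outcome over
    all ``N^L`` configurations ``D``; the unambiguous term requires the root
    set to be exactly ``{1}``, the ambiguous term credits ``1/|S_r|`` when
    the root set contains the true state.  Capacity-limited to small trees.
    """
    leaves = tree.leaf_names()
    L = len(leaves)
    if N**L > _ENUM_CAP:
        raise ValueError(f"enumeration over N^L = {N**L} configurations exceeds cap")
    ua = 0.0
    aa = 0.0
    total = 0.0
    for combo in itertools.product(range(1, N + 1), repeat=L):
        D = dict(zip(leaves, combo))
        pr = float(_conditional_leaf_likelihood(tree.root, D, N)[0])
        total += pr
        S_r = _fitch_root_set(tree, D)
        if S_r == frozenset({1}):
            ua += pr
        if 1 in S_r:
            aa += pr / len(S_r)
    if abs(total - 1.0) > 1e-9:
        raise AssertionError(f"leaf-configuration probabilities sum to {total}, not 1")
    return AccuracyResult(ua=ua, aa=aa, diagnostics={"configurations": float(N**L)})


def _flatten(tree: PhyloTree):
    """Preorder node list with parent indices and branch probabilities."""
    nodes = list(tree.preorder())
    index = {id(n): k for k, n in enumerate(nodes)}
    parents = np.full(len(nodes), -1, dtype=np.int64)
    probs = np.zeros(len(nodes))
    for k, n in enumerate(nodes):
        for c in n.children:
            parents[index[id(c)]] = k
            probs[index[id(c)]] = c.branch_p if c.branch_p is not None else np.nan
    return nodes, parents, probs


def estimate_accuracy_mc(
    tree: PhyloTree, N: int, reps: int, seed: int, chunk: int = 200_000
) -> MCEstimate:
    """Monte-Carlo UA/AA: simulate characters, run the Fitch set stage.

    Per replicate the root state is fixed to 1 (accuracies do not depend on
    the root prior under the symmetric model), the leaf states are evolved,
    and the replicate contributes the indicator ``[S_r = {1}]`` to UA and the
    analytic ``[1 in S_r] / |S_r|`` to AA — the expectation of sampling the
    top-down stage, at strictly lower variance.  Vectorized over replicates
    with state sets as bit masks (requires ``N <= 63``).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if N > 63:
        raise ValueError("Monte-Carlo bitmask encoding supports N <= 63")
    rng = np.random.default_rng(seed)
    nodes, parents, probs = _flatten(tree)
    n_nodes = len(nodes)
    is_leaf = np.array([n.is_leaf for n in nodes])
    children_idx: List[List[int]] = [[] for _ in range(n_nodes)]
    for i in range(1, n_nodes):
        children_idx[parents[i]].append(i)
    ua_parts: List[np.ndarray] = []
    aa_parts: List[np.ndarray] = []
    done = 0
    while done < reps:
        m = min(chunk, reps - done)
        states = np.zeros((n_nodes, m), dtype=np.int64)  # 0-based states
        for k in range(1, n_nodes):
            par = states[parents[k]]
            q = 1.0 - (N - 1) * probs[k]
            stay = rng.random(m) < q
            jump = (par + rng.integers(1, N, size=m)) % N
            states[k] = np.where(stay, par, jump)
        masks = np.zeros((n_nodes, m), dtype=np.uint64)
        masks[is_leaf] = np.uint64(1) << states[is_leaf].astype(np.uint64)
        for k in range(n_nodes - 1, -1, -1):  # reverse preorder = postorder-safe
            node = nodes[k]
            if node.is_leaf:
                continue
            child_idx = children_idx[k]
            if len(child_idx) == 1:
                masks[k] = masks[child_idx[0]]
            else:
                a, b = masks[child_idx[0]], masks[child_idx[1]]
                inter = a & b
                masks[k] = np.where(inter != 0, inter, a | b)
        root_mask = masks[0]
        ua_parts.append((root_mask == 1).astype(float))
        aa_parts.append(
            ((root_mask & np.uint64(1)) != 0).astype(float)
            / np.bitwise_count(root_mask)
        )
        done += m
    ua_samples = np.concatenate(ua_parts)
    aa_samples = np.concatenate(aa_parts)
    se_ua = float(ua_samples.std(ddof=1) / np.sqrt(reps)) if reps > 1 else 0.0
    se_aa = float(aa_samples.std(ddof=1) / np.sqrt(reps)) if reps > 1 else 0.0
    return MCEstimate(
        ua_hat=float(ua_samples.mean()),
        aa_hat=float(aa_samples.mean()),
        se_ua=se_ua,
        se_aa=se_aa,
        reps=reps,
        seed=seed,
    )


def generate_yule(n_leaves: int, rng: np.random.Generator) -> PhyloTree:
    """Yule (pure-birth) topology: starting from a cherry, repeatedly split a
    uniformly chosen extant leaf until ``n_leaves`` leaves exist.

    Branch probabilities are left unset; the caller assigns them (the
    extremal analyses sweep one common conservation probability over all
    branches).
    """
    if n_leaves < 2:
        raise DomainError("n_leaves must be >= 2")
    root = Node(children=[Node(), Node()])
    leaves: List[Node] = list(root.children)
    while len(leaves) < n_leaves:
        idx = int(rng.integers(len(leaves)))
        node = leaves[idx]
        node.children = [Node(), Node()]
        leaves[idx] = node.children[0]
        leaves.append(node.children[1])
    for k, leaf in enumerate(leaves, start=1):
        leaf.name = f"t{k}"
    return PhyloTree(root)


def yule_experiment(
    n_trees: int,
    n_leaves: int,
    q_grid: Sequence[float],
    N: int,
    seed: int,
) -> pd.DataFrame:
    """Accuracy sweep over Yule topologies with one common conservation
    probability per run, plus the equal-branch complete binary reference.

    Returns a long-format frame (tree, q, ua, aa); the reference rows carry
    ``tree = "complete-binary"`` and use the balanced tree with the same
    number of leaves (``n_leaves`` must be a power of two for that row to be
    exact, which the defaults respect).
    """
    if n_trees < 1 or n_leaves < 2:
        raise ValueError("n_trees must be >= 1 and n_leaves >= 2")
    for q in q_grid:
        if not 1.0 / N <= q <= 1.0:
            raise DomainError(f"conservation probability {q} outside [1/N, 1]")
    rng = np.random.default_rng(seed)
    kernel = build_combination_kernel(N)
    records = []
    levels = int(round(np.log2(n_leaves)))
    for q in q_grid:
        p = (1.0 - q) / (N - 1)
        A = leaf_class_vector(N)
        for _ in range(levels):
            A = complete_binary_level_map(A, p, N, kernel)
        acc = accuracies_from_classvector(A, N)
        records.append(
            {"tree": "complete-binary", "q": q, "ua": acc.ua, "aa": acc.aa}
        )
    for t in range(1, n_trees + 1):
        topo = generate_yule(n_leaves, rng)
        for q in q_grid:
            topo.set_uniform_branch_p((1.0 - q) / (N - 1))
            acc = tree_accuracy(topo, N, kernel)
            records.append({"tree": f"yule-{t}", "q": q, "ua": acc.ua, "aa": acc.aa})
    return pd.DataFrame.from_records(records)
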