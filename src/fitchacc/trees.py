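"""Rooted binary phylogenies with per-branch substitution probabilities.

A tree here is the object the accuracy recurrence runs on: strictly binary,
rooted, with every non-root node carrying the Jukes--Cantor substitution
probability ``branch_p`` along the branch into it.  Under the symmetric
N-state model a branch is fully described by the probability ``p`` of
changing into EACH particular other state; the conservation probability is
``q = 1 - (N-1) p``.  Branch lengths ``l`` (in expected substitutions per
unit time times a rate) map onto probabilities via
``p = (1/N) (1 - exp(-N lambda l))``, which never exceeds ``1/N``.

Newick input/output is delegated to :mod:`dendropy`; the rest of the package
works on the light-weight :class:`PhyloTree` structure defined here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Set

import dendropy

__all__ = [
    "ModelParams",
    "Node",
    "PhyloTree",
    "NewickParseError",
    "InvalidTreeError",
    "DomainError",
    "parse_newick",
    "write_newick",
    "branch_prob_from_length",
    "compose_branch",
    "restrict_to_leafset",
    "read_leaf_states",
]


class NewickParseError(ValueError):
    """Malformed Newick text."""


class InvalidTreeError(ValueError):
    """Structurally invalid tree (multifurcation, missing branch value, ...)."""


class DomainError(ValueError):
    """Parameter outside its mathematically valid range."""


@dataclass
class ModelParams:
    """Symmetric N-state Jukes--Cantor model parameters.

    Parameters
    ----------
    N:
        Number of character states (state set ``{1, ..., N}``); at least 2.
    rate:
        Substitution rate per unit branch length (lambda); only needed when
        branch values are interpreted as lengths.
    """

    N: int
    rate: Optional[float] = None

    def __post_init__(self) -> None:
        if self.N < 2:
            raise DomainError(f"number of states must be >= 2, got {self.N}")
        if self.rate is not None and self.rate <= 0:
            raise DomainError(f"substitution rate must be positive, got {self.rate}")


@dataclass
class Node:
    """A tree node; ``branch_p`` is the substitution probability into it."""

    name: Optional[str] = None
    branch_p: Optional[float] = None
    branch_length: Optional[float] = None
    state: Optional[int] = None
    children: List["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


class PhyloTree:
    """Rooted binary tree; the root carries no branch.

    Internal non-root nodes have exactly two children.  The root normally has
    two children as well; a root with a single child arises from leaf-subset
    restriction and is accepted everywhere downstream.
    """

    def __init__(self, root: Node):
        self.root = root

    # -- traversal ---------------------------------------------------------

    def postorder(self) -> Iterator[Node]:
        stack = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded or node.is_leaf:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            for child in reversed(node.children):
                stack.append(child)

    def leaves(self) -> List[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> List[str]:
        return [n.name for n in self.leaves()]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    # -- utilities ---------------------------------------------------------

    def copy(self) -> "PhyloTree":
        def rec(node: Node) -> Node:
            return Node(
                name=node.name,
                branch_p=node.branch_p,
                branch_length=node.branch_length,
                state=node.state,
                children=[rec(c) for c in node.children],
            )

        return PhyloTree(rec(self.root))

    def set_uniform_branch_p(self, p: float) -> None:
        """Assign one common substitution probability to every branch."""
        for node in self.preorder():
            if node is not self.root:
                node.branch_p = p

    def validate(self, N: Optional[int] = None, allow_superstationary: bool = False) -> None:
        """Check binarity, branch probabilities and leaf-name uniqueness."""
        names: Set[str] = set()
        for node in self.postorder():
            if node.is_leaf:
                if node.name is None:
                    raise InvalidTreeError("leaf without a name")
                if node.name in names:
                    raise InvalidTreeError(f"duplicate leaf name {node.name!r}")
                names.add(node.name)
            else:
                n_child = len(node.children)
                if node is self.root:
                    if n_child not in (1, 2):
                        raise InvalidTreeError(
                            f"root must have 1 or 2 children, found {n_child}"
                        )
                elif n_child != 2:
                    raise InvalidTreeError(
                        f"internal node with {n_child} children; tree must be binary"
                    )
            if node is not self.root:
                if node.branch_p is None:
                    raise InvalidTreeError("non-root node without a branch probability")
                if N is not None:
                    _check_branch_p(node.branch_p, N, allow_superstationary)


def _check_branch_p(p: float, N: int, allow_superstationary: bool) -> None:
    eps = 1e-12
    cap = 1.0 / (N - 1) if allow_superstationary else 1.0 / N
    if not (-eps <= p <= cap + eps):
        label = "1/(N-1)" if allow_superstationary else "1/N"
        raise DomainError(
            f"branch substitution probability {p} outside [0, {label}] for N={N}; "
            "a value in (1/N, 1/(N-1)] is unreachable under the Jukes-Cantor "
            "length parameterization (pass allow_superstationary to accept it)"
        )


def branch_prob_from_length(l: float, rate: float, N: int) -> float:
    """Substitution probability to each other state after length ``l``.

    ``p = (1/N) (1 - exp(-N * rate * l))``, so the conservation probability is
    ``q = 1/N + ((N-1)/N) exp(-N * rate * l)``.
    """
    if l < 0:
        raise DomainError(f"branch length must be nonnegative, got {l}")
    if rate <= 0:
        raise DomainError(f"substitution rate must be positive, got {rate}")
    if N < 2:
        raise DomainError(f"number of states must be >= 2, got {N}")
    return (1.0 - math.exp(-N * rate * l)) / N


def compose_branch(p1: float, p2: float, N: int) -> float:
    """Serial composition of two Jukes--Cantor branches.

    Satisfies ``1 - N p_out = (1 - N p1)(1 - N p2)`` (the eigenvalue of the
    transition matrix multiplies along a path); associative and commutative,
    with identity 0 and absorbing element ``1/N``.
    """
    for p in (p1, p2):
        if not (-1e-12 <= p <= 1.0 / N + 1e-12):
            raise DomainError(f"branch probability {p} outside [0, 1/N] for N={N}")
    return (1.0 - (1.0 - N * p1) * (1.0 - N * p2)) / N


def parse_newick(
    text: str,
    interpretation: str = "probability",
    model: Optional[ModelParams] = None,
    allow_superstationary: bool = False,
) -> PhyloTree:
    """Parse a single rooted binary Newick tree.

    Parameters
    ----------
    text:
        Newick string; every non-root edge must carry a numeric value.
    interpretation:
        ``"probability"`` stores branch values directly as ``branch_p``;
        ``"length"`` stores them as ``branch_length`` and derives ``branch_p``
        via :func:`branch_prob_from_length` (requires ``model.rate``).
        There is deliberately no autodetection.
    model:
        Model parameters; required (``N`` bounds the valid ``branch_p`` range).
    """
    if interpretation not in ("probability", "length"):
        raise ValueError(f"unknown interpretation {interpretation!r}")
    if model is None:
        raise ValueError("model parameters (N, optionally rate) are required")
    if interpretation == "length" and model.rate is None:
        raise ValueError("interpretation='length' requires model.rate")

    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            rooting="force-rooted",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"could not parse Newick input: {exc}") from None

    def convert(dnode, is_root: bool) -> Node:
        children = dnode.child_nodes()
        if len(children) > 2:
            raise InvalidTreeError(
                f"multifurcating node with {len(children)} children is not supported"
            )
        if not is_root and len(children) == 1:
            raise InvalidTreeError("unifurcating internal node is not supported")
        node = Node(children=[convert(c, False) for c in children])
        if not children:
            node.name = dnode.taxon.label if dnode.taxon is not None else dnode.label
        if not is_root:
            value = dnode.edge.length
            if value is None:
                raise InvalidTreeError("non-root branch without a numeric value")
            if interpretation == "probability":
                node.branch_p = float(value)
            else:
                node.branch_length = float(value)
                node.branch_p = branch_prob_from_length(
                    float(value), model.rate, model.N
                )
        return node

    tree = PhyloTree(convert(dtree.seed_node, True))
    if tree.root.is_leaf:
        raise InvalidTreeError("input must contain at least two leaves")
    tree.validate(N=model.N, allow_superstationary=allow_superstationary)
    return tree


def write_newick(tree: PhyloTree, digits: int = 12) -> str:
    """Serialize ``tree`` with ``branch_p`` as branch values.

    Round-trips through :func:`parse_newick` (probability interpretation) with
    branch values preserved to ``digits`` significant digits.
    """

    def rec(node: Node) -> str:
        if node.is_leaf:
            core = node.name or ""
        else:
            core = "(" + ",".join(rec(c) for c in node.children) + ")"
        if node.branch_p is not None:
            core += ":" + format(node.branch_p, f".{digits}g")
        return core

    return rec(tree.root) + ";"


def restrict_to_leafset(tree: PhyloTree, keep: Set[str], N: int) -> PhyloTree:
    """Induced rooted tree on the leaf subset ``keep``.

    Pruned degree-2 internal nodes are suppressed and their two incident
    branch probabilities composed with :func:`compose_branch`.  The original
    root is retained even if it ends up with a single child (the accuracy
    recurrence handles that case by mixing along the remaining branch).
    """
    if not keep:
        raise ValueError("keep must be a nonempty set of leaf names")
    known = set(tree.leaf_names())
    unknown = set(keep) - known
    if unknown:
        raise ValueError(f"unknown leaf names: {sorted(unknown)}")

    def rec(node: Node) -> Optional[Node]:
        if node.is_leaf:
            if node.name in keep:
                return Node(
                    name=node.name,
                    branch_p=node.branch_p,
                    branch_length=node.branch_length,
                    state=node.state,
                )
            return None
        kept = [c for c in (rec(ch) for ch in node.children) if c is not None]
        if not kept:
            return None
        if len(kept) == 2:
            return Node(
                branch_p=node.branch_p, branch_length=node.branch_length, children=kept
            )
        # suppress this degree-2 node: merge its branch into the single child
        child = kept[0]
        if node.branch_p is not None:
            child.branch_p = compose_branch(node.branch_p, child.branch_p, N)
            child.branch_length = None
        return child

    new_root = rec(tree.root)
    if new_root is None:  # unreachable: keep is nonempty and validated
        raise ValueError("restriction removed every leaf")
    if new_root.is_leaf and new_root.branch_p is None:
        # single kept leaf that was a direct child of the root
        raise AssertionError("restricted leaf lost its branch")
    if not new_root.is_leaf and new_root.branch_p is None:
        root = new_root
    else:
        # the root itself was suppressed into a pending branch: re-hang it
        root = Node(children=[new_root])
    out = PhyloTree(root)
    out.validate(N=N)
    return out


def read_leaf_states(path: str, N: int) -> Dict[str, int]:
    """Read a 2-column TSV (leaf name, state in 1..N)."""
    states: Dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"expected 2 tab-separated columns, got {line!r}")
            name, raw = parts
            state = int(raw)
            if not 1 <= state <= N:
                raise DomainError(f"state {state} for leaf {name!r} outside 1..{N}")
            states[name] = state
    return states
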