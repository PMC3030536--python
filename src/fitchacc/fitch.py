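"""The Fitch parsimony method: set stage and state-choice stage.

Stage one (leaf to root) assigns each node the intersection of its
children's sets when nonempty, else their union; the number of union events
equals the parsimony score of the character on the tree.  Stage two (root to
leaf) draws the root state uniformly from the root set and propagates it
down, keeping the parent's state wherever possible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, Mapping, Optional

import numpy as np

from .trees import DomainError, Node, PhyloTree

__all__ = ["FitchAnnotation", "fitch_bottom_up", "fitch_top_down", "parsimony_score"]


@dataclass
class FitchAnnotation:
    """Per-node state sets (stage one) and chosen states (stage two)."""

    sets: Dict[int, FrozenSet[int]]  # keyed by id(node)
    union_count: int
    chosen: Optional[Dict[int, int]] = None

    def node_set(self, node: Node) -> FrozenSet[int]:
        return self.sets[id(node)]

    def node_state(self, node: Node) -> int:
        if self.chosen is None:
            raise ValueError("top-down stage has not been run")
        return self.chosen[id(node)]


def fitch_bottom_up(
    tree: PhyloTree, N: int, leaf_states: Optional[Mapping[str, int]] = None
) -> FitchAnnotation:
    """Leaf-to-root set stage.

    Leaf states are taken from ``leaf_states`` (name -> state) when given,
    else from each leaf's ``state`` attribute.  ``union_count`` is the number
    of internal nodes where the children's sets were disjoint, i.e. the
    parsimony score.
    """
    sets: Dict[int, FrozenSet[int]] = {}
    union_count = 0
    for node in tree.postorder():
        if node.is_leaf:
            state = leaf_states.get(node.name) if leaf_states is not None else node.state
            if state is None:
                raise ValueError(f"leaf {node.name!r} has no state assigned")
            if not 1 <= state <= N:
                raise DomainError(f"leaf state {state} outside 1..{N}")
            sets[id(node)] = frozenset({state})
        else:
            child_sets = [sets[id(c)] for c in node.children]
            if len(child_sets) == 1:  # single-child root from restriction
                sets[id(node)] = child_sets[0]
                continue
            inter = child_sets[0] & child_sets[1]
            if inter:
                sets[id(node)] = inter
            else:
                sets[id(node)] = child_sets[0] | child_sets[1]
                union_count += 1
    return FitchAnnotation(sets=sets, union_count=union_count)


def fitch_top_down(
    annotation: FitchAnnotation, tree: PhyloTree, rng: np.random.Generator
) -> FitchAnnotation:
    """Root-to-leaf state choice.

    The root state is uniform on the root set; a child keeps its parent's
    state whenever its own set contains it, and otherwise draws uniformly
    from its set.  Every assignment produced this way attains the parsimony
    score.  Deterministic given the generator state.
    """
    if any(id(n) not in annotation.sets for n in tree.preorder()):
        raise ValueError("annotation does not match this tree")
    chosen: Dict[int, int] = {}
    root_set = sorted(annotation.sets[id(tree.root)])
    chosen[id(tree.root)] = root_set[int(rng.integers(len(root_set)))]
    for node in tree.preorder():
        s_u = chosen[id(node)]
        for child in node.children:
            s_v = annotation.sets[id(child)]
            if s_u in s_v:
                chosen[id(child)] = s_u
            else:
                options = sorted(s_v)
                chosen[id(child)] = options[int(rng.integers(len(options)))]
    return FitchAnnotation(
        sets=annotation.sets, union_count=annotation.union_count, chosen=chosen
    )


def parsimony_score(
    tree: PhyloTree, N: int, leaf_states: Optional[Mapping[str, int]] = None
) -> int:
    """Minimum number of state changes needed to explain the leaf states."""
    return fitch_bottom_up(tree, N, leaf_states).union_count
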