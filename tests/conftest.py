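"""Shared fixtures and small tree-building helpers."""

from __future__ import annotations

from typing import List, Tuple, Union

import numpy as np
import pytest

from fitchacc.trees import Node, PhyloTree

Shape = Union[str, Tuple["Shape", "Shape"]]


def tree_shapes(n_leaves: int) -> List[Shape]:
    """All rooted binary tree shapes (unlabeled) with ``n_leaves`` leaves."""
    if n_leaves == 1:
        return ["L"]
    out: List[Shape] = []
    seen = set()
    for k in range(1, n_leaves // 2 + 1):
        for a in tree_shapes(k):
            for b in tree_shapes(n_leaves - k):
                key = frozenset({repr(a), repr(b)}) if repr(a) != repr(b) else repr(a)
                if key not in seen:
                    seen.add(key)
                    out.append((a, b))
    return out


def build_from_shape(
    shape: Shape, rng: np.random.Generator, N: int, p_max: float | None = None
) -> PhyloTree:
    """Random branch probabilities in ``[0, p_max]`` on a given shape."""
    if p_max is None:
        p_max = 1.0 / N
    counter = [0]

    def rec(s: Shape) -> Node:
        if s == "L":
            counter[0] += 1
            return Node(name=f"x{counter[0]}", branch_p=float(rng.uniform(0, p_max)))
        return Node(
            branch_p=float(rng.uniform(0, p_max)),
            children=[rec(s[0]), rec(s[1])],
        )

    root = rec(shape)
    root.branch_p = None
    if root.is_leaf:
        raise ValueError("shape must have at least 2 leaves")
    return PhyloTree(root)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)


@pytest.fixture
def cherry() -> PhyloTree:
    """Two-leaf tree with both branch probabilities 0.1."""
    return PhyloTree(
        Node(children=[Node(name="A", branch_p=0.1), Node(name="B", branch_p=0.1)])
    )
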