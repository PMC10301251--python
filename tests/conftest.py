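"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import random

import pytest

from phylodiscord.treecore import Node, Tree


def random_binary_tree(rng: random.Random, labels, with_lengths=False, with_supports=False) -> Tree:
    """Independent random rooted binary tree builder (sequential joins)."""
    nodes = [Node(lab) for lab in labels]
    if with_lengths:
        for n in nodes:
            n.length = round(rng.uniform(0.01, 5.0), 4)
    while len(nodes) > 1:
        i = rng.randrange(len(nodes))
        j = rng.randrange(len(nodes) - 1)
        if j >= i:
            j += 1
        joined = Node(children=[nodes[i], nodes[j]])
        if with_lengths:
            joined.length = round(rng.uniform(0.01, 5.0), 4)
        if with_supports:
            joined.support = float(rng.randint(0, 100))
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(joined)
    root = nodes[0]
    root.length = None
    root.support = None
    return Tree(root)


def enumerate_splits(tree: Tree) -> set[frozenset]:
    """Brute-force non-trivial split enumeration, independent of the
    package's bipartition machinery: collect the leafset under every node
    and canonicalise against the full taxon set by hand."""
    taxa = set()

    def leaves_below(node, acc):
        if not node.children:
            acc.append(node.label)
        for c in node.children:
            leaves_below(c, acc)
        return acc

    taxa = frozenset(leaves_below(tree.root, []))
    anchor = min(taxa)
    splits = set()

    def walk(node):
        for c in node.children:
            walk(c)
        if node is tree.root or not node.children:
            return
        block = frozenset(leaves_below(node, []))
        if 2 <= len(block) <= len(taxa) - 2:
            canon = block if anchor in block else taxa - block
            splits.add(canon)

    walk(tree.root)
    return splits


def brute_force_rf(t1: Tree, t2: Tree) -> int:
    """Symmetric difference of explicitly enumerated splits."""
    return len(enumerate_splits(t1) ^ enumerate_splits(t2))


def clean_copies(tree: Tree, n: int, support: float = 100.0) -> list[Tree]:
    """n copies of a tree with every internal edge at the given support."""
    out = []
    for _ in range(n):
        g = tree.copy()
        for node in g.nodes():
            if not node.is_leaf and node is not g.root:
                node.support = support
        out.append(g)
    return out


@pytest.fixture
def rng():
    return random.Random(20240917)
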