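"""Tree data model, Newick round-tripping and bipartition algebra.

Every other module builds on the structures here: a lightweight rooted
:class:`Tree` of :class:`Node` objects, canonical :class:`Bipartition`
encoding (the substrate for Robinson--Foulds distances and concordance
mapping), taxon restriction, induced quartet/triple topologies, majority
consensus and outgroup rerooting.

Conventions
-----------
* Branch lengths live on the node *below* the edge; units are context
  dependent (coalescent units for species trees, arbitrary for gene trees).
* Support values (0--100 scale) live on internal edges only.  By default,
  numeric internal-node labels in a Newick string are read as supports --
  the dominant maximum-likelihood dialect; a flag switches to comment-style
  supports (``[85]`` after a node).
* All tree-to-tree comparisons are on unrooted topologies: a rooted tree is
  treated as its unrooted version, so the two edges incident to a
  degree-two root encode a single bipartition.
* Output is deterministic: children are ordered by their smallest
  descendant taxon label, lengths are printed with 6 significant digits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Sequence

import dendropy

__all__ = [
    "Node",
    "Tree",
    "Bipartition",
    "NewickParseError",
    "TreeError",
    "parse_newick",
    "write_newick",
    "read_newick_file",
    "write_newick_file",
    "bipartition_set",
    "bipartition_supports",
    "rf_distance",
    "restrict_to_taxa",
    "induced_topology",
    "majority_consensus",
    "reroot",
]


class TreeError(ValueError):
    """Raised for structurally invalid trees or invalid tree operations."""


class NewickParseError(TreeError):
    """Raised for malformed Newick input; carries a character offset when known."""

    def __init__(self, message: str, offset: Optional[int] = None):
        if offset is not None:
            message = f"{message} (at character offset {offset})"
        super().__init__(message)
        self.offset = offset


class Node:
    """A tree node; ``length`` and ``support`` describe the edge above it."""

    __slots__ = ("label", "length", "support", "children")

    def __init__(
        self,
        label: Optional[str] = None,
        length: Optional[float] = None,
        support: Optional[float] = None,
        children: Optional[list["Node"]] = None,
    ):
        self.label = label
        self.length = length
        self.support = support
        self.children: list[Node] = children if children is not None else []

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_labels(self) -> frozenset:
        out = []
        stack = [self]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.append(n.label)
            else:
                stack.extend(n.children)
        return frozenset(out)

    def copy(self) -> "Node":
        new = Node(self.label, self.length, self.support)
        new.children = [c.copy() for c in self.children]
        return new

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.label!r}, length={self.length}, support={self.support}, nchild={len(self.children)})"


class Tree:
    """A rooted tree over uniquely labelled leaves.

    A tree whose root has exactly two children is *rooted* in the
    phylogenetic sense; a root of degree three or more is the conventional
    representation of an unrooted tree.
    """

    __slots__ = ("root",)

    def __init__(self, root: Node):
        self.root = root

    # -- structure ---------------------------------------------------------
    @property
    def taxa(self) -> frozenset:
        return self.root.leaf_labels()

    @property
    def is_rooted(self) -> bool:
        return len(self.root.children) == 2

    def nodes(self) -> Iterator[Node]:
        """Preorder iteration over all nodes."""
        stack = [self.root]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(n.children)

    def leaves(self) -> list[Node]:
        return [n for n in self.nodes() if n.is_leaf]

    def n_leaves(self) -> int:
        return sum(1 for n in self.nodes() if n.is_leaf)

    def is_binary(self) -> bool:
        return all(n.is_leaf or len(n.children) == 2 for n in self.nodes())

    def copy(self) -> "Tree":
        return Tree(self.root.copy())

    def validate(self) -> "Tree":
        labels = []
        for n in self.nodes():
            if n.is_leaf:
                if not n.label:
                    raise TreeError("leaf with empty label")
                labels.append(n.label)
            elif len(n.children) < 2:
                raise TreeError("internal node with a single child")
            if n.length is not None and n.length < 0:
                raise TreeError(f"negative branch length {n.length}")
            if n.support is not None and not (0 <= n.support <= 100):
                raise TreeError(f"support {n.support} outside [0, 100]")
        if len(labels) != len(set(labels)):
            dup = sorted({x for x in labels if labels.count(x) > 1})
            raise TreeError(f"duplicate taxon labels: {', '.join(dup)}")
        if len(labels) < 2:
            raise TreeError("tree must have at least 2 leaves")
        return self

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tree({write_newick(self)})"


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------


def _as_support(text: Optional[str]) -> Optional[float]:
    if text is None:
        return None
    try:
        val = float(text)
    except ValueError:
        return None
    return val if 0.0 <= val <= 100.0 else None


def parse_newick(text: str, support_convention: str = "internal-node-label") -> Tree:
    """Parse a single Newick statement into a :class:`Tree`.

    Parameters
    ----------
    text:
        A Newick string terminated by ``;``.
    support_convention:
        ``"internal-node-label"`` (default) reads numeric internal-node
        labels in [0, 100] as edge supports; ``"comment"`` reads the first
        numeric bracket comment attached to an internal node instead;
        ``"none"`` keeps labels as labels.
    """
    if support_convention not in ("internal-node-label", "comment", "none"):
        raise ValueError(f"unknown support convention {support_convention!r}")
    stripped = text.strip()
    if not stripped.endswith(";"):
        raise NewickParseError("Newick statement must end with ';'", offset=len(text))
    try:
        dtree = dendropy.Tree.get(
            data=stripped,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises schema-specific subclasses
        offset = getattr(exc, "col_num", None)
        if offset is None:
            offset = _first_imbalance_offset(stripped)
        raise NewickParseError(f"malformed Newick: {exc}", offset=offset) from None

    def convert(dnode) -> Node:
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon is not None else dnode.label
            return Node(label=label, length=dnode.edge.length)
        node = Node(length=dnode.edge.length)
        node.children = [convert(c) for c in dnode.child_nodes()]
        if support_convention == "internal-node-label":
            sup = _as_support(dnode.label)
            if sup is not None:
                node.support = sup
            else:
                node.label = dnode.label
        elif support_convention == "comment":
            node.label = dnode.label
            for comment in dnode.comments or []:
                sup = _as_support(comment.strip())
                if sup is not None:
                    node.support = sup
                    break
        else:
            node.label = dnode.label
        return node

    root = convert(dtree.seed_node)
    root.length = None  # a root edge has no meaning here
    root.support = None
    tree = Tree(root)
    _validate_parsed(tree, stripped)
    return tree


def _first_imbalance_offset(text: str) -> Optional[int]:
    depth = 0
    for i, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                return i
    if depth != 0:
        return len(text)
    return None


def _validate_parsed(tree: Tree, text: str) -> None:
    labels: list[str] = []
    for n in tree.nodes():
        if n.is_leaf:
            if not n.label:
                raise NewickParseError("empty taxon label", offset=None)
            labels.append(n.label)
        if n.length is not None and n.length < 0:
            raise NewickParseError(
                f"negative branch length {n.length:g}",
                offset=text.find(f":{n.length:g}"),
            )
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise NewickParseError(
                f"duplicate taxon label {lab!r}",
                offset=text.find(lab, text.find(lab) + 1),
            )
        seen.add(lab)
    if len(labels) < 2:
        raise NewickParseError("tree must have at least 2 leaves")


def _fmt_number(x: float, precision: int = 6) -> str:
    if float(x).is_integer() and abs(x) < 1e15:
        return str(int(x))
    return f"{x:.{precision}g}"


def write_newick(
    tree: Tree, lengths: bool = True, supports: bool = True, precision: int = 6
) -> str:
    """Serialize deterministically: children ordered by smallest descendant
    label, numbers at ``precision`` significant digits (17 is lossless)."""

    def render(node: Node) -> tuple[str, str]:
        if node.is_leaf:
            s = node.label
            key = node.label
        else:
            parts = sorted((render(c) for c in node.children), key=lambda p: p[1])
            s = "(" + ",".join(p[0] for p in parts) + ")"
            key = parts[0][1]
            if supports and node.support is not None:
                s += _fmt_number(node.support, precision)
            elif node.label:
                s += node.label
        if lengths and node.length is not None:
            s += f":{_fmt_number(node.length, precision)}"
        return s, key

    return render(tree.root)[0] + ";"


def read_newick_file(path, support_convention: str = "internal-node-label") -> list[Tree]:
    """Read one tree per line; blank lines and ``#`` comment lines are skipped."""
    trees = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            trees.append(parse_newick(line, support_convention=support_convention))
    return trees


def write_newick_file(path, trees: Iterable[Tree]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for t in trees:
            fh.write(write_newick(t) + "\n")


# ---------------------------------------------------------------------------
# Bipartitions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Bipartition:
    """A two-block partition of a taxon set in canonical orientation.

    ``block`` is the side containing the lexicographically smallest taxon,
    so a split and its complement encode equal.
    """

    block: frozenset
    taxa: frozenset

    @staticmethod
    def make(block: Iterable, taxa: Iterable) -> "Bipartition":
        taxa = frozenset(taxa)
        block = frozenset(block)
        if not block or not block < taxa:
            raise TreeError("bipartition blocks must be non-empty proper subsets")
        if min(taxa) not in block:
            block = taxa - block
        return Bipartition(block=block, taxa=taxa)

    @property
    def other(self) -> frozenset:
        return self.taxa - self.block

    @property
    def is_trivial(self) -> bool:
        return min(len(self.block), len(self.other)) < 2

    def restricted(self, subset: frozenset) -> Optional["Bipartition"]:
        """Restriction to a taxon subset; ``None`` when it becomes trivial."""
        a = self.block & subset
        b = self.other & subset
        if len(a) < 2 or len(b) < 2:
            return None
        return Bipartition.make(a, subset)

    def compatible(self, other: "Bipartition") -> bool:
        """Two splits of the same taxon set can coexist in one tree iff one
        of the four pairwise block intersections is empty."""
        a, b = self.block, self.other
        c, d = other.block, other.other
        return not (a & c) or not (a & d) or not (b & c) or not (b & d)

    def __str__(self) -> str:
        small, large = sorted((self.block, self.other), key=lambda s: (len(s), sorted(s)))
        return ",".join(sorted(small)) + " | " + ",".join(sorted(large))


def _edge_blocks(tree: Tree) -> list[tuple[Node, frozenset]]:
    """(node, leafset-below) for every non-root node, computed in one pass."""
    out: list[tuple[Node, frozenset]] = []

    def collect(node: Node) -> frozenset:
        if node.is_leaf:
            ls = frozenset((node.label,))
        else:
            ls = frozenset().union(*(collect(c) for c in node.children))
        out.append((node, ls))
        return ls

    collect(tree.root)
    out.pop()  # root has no edge
    return out


def bipartition_set(tree: Tree, min_support: Optional[float] = None) -> set[Bipartition]:
    """All non-trivial unrooted bipartitions induced by internal edges.

    With ``min_support``, edges whose support is missing or below the cutoff
    are skipped.  Trees with fewer than four leaves have no non-trivial
    splits and yield the empty set.
    """
    taxa = tree.taxa
    n = len(taxa)
    if n < 4:
        return set()
    out: set[Bipartition] = set()
    for node, block in _edge_blocks(tree):
        if len(block) < 2 or len(block) > n - 2:
            continue
        if min_support is not None and (node.support is None or node.support < min_support):
            continue
        out.add(Bipartition.make(block, taxa))
    return out


def bipartition_supports(tree: Tree) -> dict[Bipartition, Optional[float]]:
    """Map each non-trivial bipartition to its edge support (max over the two
    root-incident representations of the same split)."""
    taxa = tree.taxa
    n = len(taxa)
    result: dict[Bipartition, Optional[float]] = {}
    if n < 4:
        return result
    for node, block in _edge_blocks(tree):
        if len(block) < 2 or len(block) > n - 2:
            continue
        bip = Bipartition.make(block, taxa)
        sup = node.support
        if bip not in result:
            result[bip] = sup
        elif sup is not None:
            prev = result[bip]
            result[bip] = sup if prev is None else max(prev, sup)
    return result


def rf_distance(t1: Tree, t2: Tree) -> int:
    """Robinson--Foulds distance: symmetric difference of the unrooted
    non-trivial bipartition sets.  Requires identical taxon sets."""
    x1, x2 = t1.taxa, t2.taxa
    if x1 != x2:
        only1 = sorted(x1 - x2)
        only2 = sorted(x2 - x1)
        raise TreeError(
            "taxon sets differ: "
            f"only in first: {only1 or '[]'}; only in second: {only2 or '[]'}"
        )
    return len(bipartition_set(t1) ^ bipartition_set(t2))


def max_rf(n_taxa: int) -> int:
    """RF distance upper bound for binary trees on ``n_taxa`` leaves."""
    return max(2 * (n_taxa - 3), 0)


# ---------------------------------------------------------------------------
# Restriction / induced topologies
# ---------------------------------------------------------------------------


def _merge_length(a: Optional[float], b: Optional[float]) -> Optional[float]:
    if a is None and b is None:
        return None
    return (a or 0.0) + (b or 0.0)


def _merge_support(a: Optional[float], b: Optional[float]) -> Optional[float]:
    if a is None:
        return b
    if b is None:
        return a
    return min(a, b)


def restrict_to_taxa(tree: Tree, taxa: Iterable) -> Tree:
    """Prune to a taxon subset, suppressing degree-two nodes.

    Lengths sum across suppressed nodes; the minimum support across merged
    edges is kept (a pruned edge can only lose, never gain, support).
    """
    keep = frozenset(taxa)
    unknown = keep - tree.taxa
    if unknown:
        raise TreeError(f"unknown taxa in restriction: {sorted(unknown)}")
    if len(keep) < 2:
        raise TreeError("restriction needs at least 2 taxa")

    def prune(node: Node) -> Optional[Node]:
        if node.is_leaf:
            if node.label in keep:
                return Node(node.label, node.length, node.support)
            return None
        kept = [c for c in (prune(ch) for ch in node.children) if c is not None]
        if not kept:
            return None
        if len(kept) == 1:
            child = kept[0]
            child.length = _merge_length(child.length, node.length)
            child.support = _merge_support(child.support, node.support)
            return child
        return Node(node.label, node.length, node.support, kept)

    root = prune(tree.root)
    assert root is not None
    root.length = None
    if not root.is_leaf:
        root.support = None
    return Tree(root)


UNRESOLVED = None


def induced_topology(tree: Tree, taxa: Sequence, rooted: bool = False) -> Optional[frozenset]:
    """Induced topology of a quartet (unrooted) or triple (rooted).

    For a quartet, returns the pair (as a frozenset, the one containing the
    smallest of the four taxa) that is split from the other two, or ``None``
    when the restriction is a star.  For a rooted triple, returns the pair
    that coalesces first, or ``None`` when unresolved.
    """
    taxa = frozenset(taxa)
    if rooted:
        if len(taxa) != 3:
            raise TreeError("rooted mode expects exactly 3 taxa")
        if not tree.is_rooted:
            raise TreeError("rooted triple topology requires a rooted tree")
        sub = restrict_to_taxa(tree, taxa)
        if len(sub.root.children) != 2:
            return UNRESOLVED
        for child in sub.root.children:
            ls = child.leaf_labels()
            if len(ls) == 2:
                return ls
        return UNRESOLVED
    if len(taxa) != 4:
        raise TreeError("unrooted mode expects exactly 4 taxa")
    sub = restrict_to_taxa(tree, taxa)
    bips = bipartition_set(sub)
    if not bips:
        return UNRESOLVED
    bip = next(iter(bips))
    return bip.block if min(taxa) in bip.block else bip.other


# ---------------------------------------------------------------------------
# Consensus and rerooting
# ---------------------------------------------------------------------------


def majority_consensus(trees: Sequence[Tree], threshold: float = 0.5) -> Tree:
    """Majority-rule consensus: keep bipartitions with frequency strictly
    above ``threshold`` (at ``threshold=1`` those present in every tree);
    retained edges carry frequency x 100 as support."""
    if not trees:
        raise TreeError("consensus of an empty tree collection")
    if not 0.5 <= threshold <= 1.0:
        raise TreeError("consensus threshold must lie in [0.5, 1]")
    taxa = trees[0].taxa
    for t in trees[1:]:
        if t.taxa != taxa:
            raise TreeError("consensus requires a shared taxon set")
    counts: dict[Bipartition, int] = {}
    for t in trees:
        for bip in bipartition_set(t):
            counts[bip] = counts.get(bip, 0) + 1
    n = len(trees)
    if threshold == 1.0:
        kept = {b: c / n for b, c in counts.items() if c == n}
    else:
        kept = {b: c / n for b, c in counts.items() if c / n > threshold}

    anchor = min(taxa)
    root = Node(children=[Node(lab) for lab in sorted(taxa)])
    clades = sorted(
        ((b.other if anchor in b.block else b.block, freq) for b, freq in kept.items()),
        key=lambda cf: -len(cf[0]),
    )

    def leafset(node: Node) -> frozenset:
        return node.leaf_labels()

    for clade, freq in clades:
        host = root
        descended = True
        while descended:
            descended = False
            for child in host.children:
                if not child.is_leaf and clade < leafset(child):
                    host = child
                    descended = True
                    break
        inside = [c for c in host.children if leafset(c) <= clade]
        outside = [c for c in host.children if not leafset(c) <= clade]
        host.children = outside + [Node(support=freq * 100.0, children=inside)]
    return Tree(root)


def reroot(tree: Tree, outgroup: str) -> Tree:
    """Reroot so the root separates ``outgroup`` from everything else.

    The unrooted bipartition set is unchanged; the outgroup's pendant edge
    length is split evenly across the two root edges.
    """
    if outgroup not in tree.taxa:
        raise TreeError(f"unknown outgroup taxon {outgroup!r}")
    t = tree.copy()
    parent: dict[int, Node] = {}
    target = None
    for node in t.nodes():
        for c in node.children:
            parent[id(c)] = node
        if node.is_leaf and node.label == outgroup:
            target = node
    assert target is not None

    p = parent.get(id(target))
    if p is t.root and len(t.root.children) == 2:
        return t  # already rooted on the outgroup

    def invert(node: Node, exclude: Node, length: Optional[float], support: Optional[float]) -> Node:
        """Re-orient ``node`` as a child hanging below its former child."""
        new = Node(node.label, length, support)
        new.children = [c for c in node.children if c is not exclude]
        up = parent.get(id(node))
        if up is not None:
            new.children.append(invert(up, node, node.length, node.support))
        if len(new.children) == 1:
            # the old root becomes degree-2: suppress it
            only = new.children[0]
            only.length = _merge_length(only.length, new.length)
            only.support = _merge_support(only.support, new.support)
            return only
        return new

    half = None if target.length is None else target.length / 2.0
    out_leaf = Node(target.label, half)
    rest = invert(p, target, half, None)
    return Tree(Node(children=[out_leaf, rest]))
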