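"""Synthetic gene-tree data generation under the multispecies coalescent.

This module emulates the statistical structure of transcriptome-derived
single-copy gene-tree sets: a rooted species tree with internal branch
lengths in coalescent units (CU, 1 CU = 2N generations), hundreds to
~1,400 gene trees whose discordance is produced by incomplete lineage
sorting, optionally a small number of reticulations with inheritance
probability gamma near 0.5, per-edge bootstrap-style supports, gene-tree
estimation error (random NNI moves), and missing taxa.

All randomness flows from explicit integer seeds; there is no hidden
global state.  Time runs in CU throughout: within a species-tree branch of
length ``T`` carrying ``k`` lineages, the waiting time to the next
coalescence is exponential with rate ``k(k-1)/2``; lineages that fail to
coalesce are handed to the parent branch, and the branch above the root
has infinite length.  The probability that a rooted triple spanning an
internal path of length ``t`` CU is concordant is ``1 - (2/3)exp(-t)``.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

from .treecore import (
    Node,
    Tree,
    TreeError,
    parse_newick,
    restrict_to_taxa,
    write_newick,
    write_newick_file,
)

__all__ = [
    "SpeciesTreeModel",
    "Reticulation",
    "NetworkModel",
    "SimConfig",
    "sample_yule_species_tree",
    "simulate_msc_gene_trees",
    "simulate_network_gene_trees",
    "displayed_tree",
    "perturb_gene_trees",
    "generate_dataset",
    "attach_outgroup",
    "distant_reticulation",
    "model_from_manifest",
]

DEFAULT_TERMINAL_CU = 1.0


def _canonicalize(node: Node) -> str:
    """Sort children by smallest descendant label, in place; returns it."""
    if node.is_leaf:
        return node.label
    keyed = sorted((_canonicalize(c), c) for c in node.children)
    node.children = [c for _, c in keyed]
    return keyed[0][0]


@dataclass
class SpeciesTreeModel:
    """A rooted binary species tree whose edge lengths are coalescent units."""

    tree: Tree

    def __post_init__(self):
        if not self.tree.is_rooted:
            raise TreeError("species tree model must be rooted (binary root)")
        if not self.tree.is_binary():
            raise TreeError("species tree model must be binary")
        for node in self.tree.nodes():
            if node is self.tree.root:
                continue
            if node.length is None:
                node.length = DEFAULT_TERMINAL_CU if node.is_leaf else 0.0
            elif node.length < 0:
                raise TreeError("negative coalescent-unit branch length")
        _canonicalize(self.tree.root)  # child order fixes the simulator's draw order

    @property
    def taxa(self) -> frozenset:
        return self.tree.taxa

    def copy(self) -> "SpeciesTreeModel":
        return SpeciesTreeModel(self.tree.copy())


@dataclass(frozen=True)
class Reticulation:
    """One hybridization edge: the clade below the recipient edge is, with
    probability ``gamma``, regrafted onto the donor edge (the *minor*
    displayed tree), attached by an extra pendant length ``tau`` CU."""

    recipient: frozenset
    donor: frozenset
    gamma: float
    tau: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.gamma <= 1.0:
            raise TreeError("inheritance probability gamma must lie in [0, 1]")
        if self.tau < 0:
            raise TreeError("donor-attachment length tau must be >= 0")

    def as_dict(self) -> dict:
        return {
            "recipient": sorted(self.recipient),
            "donor": sorted(self.donor),
            "gamma": self.gamma,
            "tau": self.tau,
        }


@dataclass
class NetworkModel:
    """A species tree plus one or more reticulations (edges named by the
    taxon clade below them)."""

    base: SpeciesTreeModel
    reticulations: tuple[Reticulation, ...]

    def __post_init__(self):
        self.reticulations = tuple(self.reticulations)
        # validity: every displayed tree must be constructible
        for states in _binary_states(len(self.reticulations)):
            displayed_tree(self, states)

    @property
    def taxa(self) -> frozenset:
        return self.base.taxa


def _binary_states(r: int):
    for mask in range(2 ** r):
        yield tuple(bool(mask >> i & 1) for i in range(r))


def _clade_node(tree: Tree, clade: frozenset) -> Node:
    for node in tree.nodes():
        if node is not tree.root and node.leaf_labels() == clade:
            return node
    raise TreeError(f"no edge with clade {sorted(clade)}")


def displayed_tree(model: NetworkModel, minor_states: Sequence[bool]) -> SpeciesTreeModel:
    """The displayed species tree for one choice of minor/major per
    reticulation, applied in order.

    A minor state prunes the recipient clade, suppresses the resulting
    degree-two node and regrafts the clade onto the midpoint of the donor
    edge with pendant length ``tau``.
    """
    return _displayed(model.base, model.reticulations, minor_states)


def _displayed(
    base: SpeciesTreeModel,
    reticulations: Sequence[Reticulation],
    minor_states: Sequence[bool],
) -> SpeciesTreeModel:
    tree = base.tree.copy()
    for retic, minor in zip(reticulations, minor_states):
        if not minor:
            continue
        if retic.recipient & retic.donor:
            raise TreeError("recipient and donor clades must be disjoint")
        rec = _clade_node(tree, retic.recipient)
        # detach recipient
        parent = None
        for node in tree.nodes():
            if rec in node.children:
                parent = node
                break
        assert parent is not None
        parent.children.remove(rec)
        if len(parent.children) == 1:
            only = parent.children[0]
            if parent is tree.root:
                only.length = None
                tree.root = only
            else:
                only.length = (only.length or 0.0) + (parent.length or 0.0)
                grand = next(n for n in tree.nodes() if parent in n.children)
                grand.children[grand.children.index(parent)] = only
        donor = _clade_node(tree, retic.donor)
        half = (donor.length or 0.0) / 2.0
        rec.length = retic.tau
        mid = Node(length=half, children=[donor, rec])
        donor.length = half
        grand = next(n for n in tree.nodes() if donor in n.children)
        grand.children[grand.children.index(donor)] = mid
    return SpeciesTreeModel(tree)


@dataclass
class SimConfig:
    """Knobs for one synthetic dataset.

    Defaults mirror the study conditions the generator emulates: several
    hundred gene trees, mild gene-tree estimation error, ultrafast
    bootstrap-style supports where clean edges score 80--100 and perturbed
    edges score below the conventional 50% filter cutoff, and occasional
    missing taxa.
    """

    seed: int = 0
    n_genes: int = 800
    nni_noise_prob: float = 0.0
    missing_prob: float = 0.0
    support_high: tuple[float, float] = (80.0, 100.0)
    support_low: tuple[float, float] = (0.0, 49.0)

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        for p in (self.nni_noise_prob, self.missing_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Species-tree sampling
# ---------------------------------------------------------------------------


def sample_yule_species_tree(
    n_taxa: int,
    mean_internal_cu: float,
    seed: int,
    terminal_cu: float = DEFAULT_TERMINAL_CU,
    labels: Optional[Sequence[str]] = None,
) -> SpeciesTreeModel:
    """Random rooted binary species tree on ``n_taxa`` leaves.

    The topology is a uniform coalescent shape (random sequential joins);
    internal edge lengths are i.i.d. exponential with mean
    ``mean_internal_cu`` CU, terminal edges fixed at ``terminal_cu``.
    """
    if n_taxa < 3:
        raise TreeError("need at least 3 taxa for a species tree")
    if mean_internal_cu <= 0:
        raise ValueError("mean_internal_cu must be positive")
    rng = random.Random(seed)
    if labels is None:
        labels = [f"T{i:02d}" for i in range(1, n_taxa + 1)]
    elif len(labels) != n_taxa:
        raise ValueError("labels length must equal n_taxa")
    roots = [Node(lab, terminal_cu) for lab in labels]
    while len(roots) > 1:
        i = rng.randrange(len(roots))
        j = rng.randrange(len(roots) - 1)
        if j >= i:
            j += 1
        a, b = roots[i], roots[j]
        joined = Node(length=rng.expovariate(1.0 / mean_internal_cu), children=[a, b])
        roots = [r for k, r in enumerate(roots) if k not in (i, j)]
        roots.append(joined)
    root = roots[0]
    root.length = None
    return SpeciesTreeModel(Tree(root))


# ---------------------------------------------------------------------------
# MSC simulation
# ---------------------------------------------------------------------------


def _species_depths(tree: Tree) -> dict[int, float]:
    """Depth (CU distance from the root) of every node."""
    depths = {id(tree.root): 0.0}
    stack = [tree.root]
    while stack:
        node = stack.pop()
        for c in node.children:
            depths[id(c)] = depths[id(node)] + (c.length or 0.0)
            stack.append(c)
    return depths


def _coalesce_in_branch(lineages, t_bottom, t_top, rng):
    """Run the coalescent among ``lineages`` (list of (Node, time)) from
    depth ``t_bottom`` rootward until depth ``t_top`` (-inf above the root).

    Times are depths from the species-tree root, so they decrease as
    coalescence proceeds rootward; gene-tree branch lengths are depth
    differences and hence non-negative.
    """
    t = t_bottom
    while len(lineages) > 1:
        k = len(lineages)
        t = t - rng.expovariate(k * (k - 1) / 2.0)
        if t <= t_top:
            return lineages
        i = rng.randrange(k)
        j = rng.randrange(k - 1)
        if j >= i:
            j += 1
        a, ta = lineages[i]
        b, tb = lineages[j]
        a.length = ta - t
        b.length = tb - t
        parent = Node(children=[a, b])
        lineages = [lineages[m] for m in range(k) if m not in (i, j)]
        lineages.append((parent, t))
    return lineages


def _simulate_one_gene_tree(model: SpeciesTreeModel, depths, rng) -> Tree:
    def recurse(snode: Node) -> list:
        bottom = depths[id(snode)]
        if snode.is_leaf:
            lineages = [(Node(snode.label), bottom)]
        else:
            lineages = []
            for c in snode.children:
                lineages.extend(recurse(c))
        top = -float("inf") if snode.length is None else bottom - snode.length
        if snode is model.tree.root:
            top = -float("inf")
        return _coalesce_in_branch(lineages, bottom, top, rng)

    (root, _), = recurse(model.tree.root)
    root.length = None
    return Tree(root)


def simulate_msc_gene_trees(model: SpeciesTreeModel, n: int, seed: int) -> list[Tree]:
    """Simulate ``n`` independent rooted gene trees under the multispecies
    coalescent on ``model`` (branch lengths in CU)."""
    rng = random.Random(seed)
    depths = _species_depths(model.tree)
    return [_simulate_one_gene_tree(model, depths, rng) for _ in range(n)]


def simulate_network_gene_trees(
    model: NetworkModel, n: int, seed: int
) -> tuple[list[Tree], list[tuple[str, ...]]]:
    """Simulate gene trees from a network: per gene, each reticulation
    independently resolves to its minor displayed tree with probability
    gamma; the resulting displayed tree drives the MSC.

    Returns the gene trees and, per gene, the tuple of parent labels
    ("minor"/"major") per reticulation, for downstream testing.
    """
    rng = random.Random(seed)
    cache: dict[tuple[bool, ...], tuple[SpeciesTreeModel, dict]] = {}
    trees: list[Tree] = []
    labels: list[tuple[str, ...]] = []
    for _ in range(n):
        states = tuple(rng.random() < r.gamma for r in model.reticulations)
        if states not in cache:
            disp = displayed_tree(model, states)
            cache[states] = (disp, _species_depths(disp.tree))
        disp, depths = cache[states]
        trees.append(_simulate_one_gene_tree(disp, depths, rng))
        labels.append(tuple("minor" if s else "major" for s in states))
    return trees, labels


# ---------------------------------------------------------------------------
# Estimation noise
# ---------------------------------------------------------------------------


def _internal_edges(tree: Tree) -> list[tuple[Node, Node, Node]]:
    """(parent, child, swap_partner_holder) triples, one per internal
    (non-trivial) unrooted edge.

    ``swap_partner_holder`` is the node whose children provide the subtree
    exchanged in an NNI across the edge: the child's sibling-holder (its
    parent) in general, or the opposite root child when the parent is a
    degree-two root (swapping with that child *as a unit* would merely
    reroot the tree).
    """
    n = tree.n_leaves()
    parent_of = {}
    for node in tree.nodes():
        for c in node.children:
            parent_of[id(c)] = node
    out = []
    seen_root_edge = False
    for node in tree.nodes():
        if node is tree.root or node.is_leaf:
            continue
        size = len(node.leaf_labels())
        if size < 2 or size > n - 2:
            continue
        parent = parent_of[id(node)]
        if parent is tree.root and len(tree.root.children) == 2:
            if seen_root_edge:
                continue  # same unrooted edge as the sibling's
            seen_root_edge = True
            partner_holder = next(c for c in tree.root.children if c is not node)
            if partner_holder.is_leaf:
                continue
        else:
            partner_holder = parent
        out.append((parent, node, partner_holder))
    return out


def _nni_arrangements(child: Node, partner_holder: Node) -> list:
    """The two non-identity local arrangements across the edge above
    ``child``: swap either of its subtrees with one fixed partner subtree."""
    partner = next(c for c in partner_holder.children if c is not child)
    return [(k, partner) for k in range(len(child.children))]


def _swap(child: Node, k: int, partner: Node, holder: Node) -> None:
    moved = child.children[k]
    child.children[k] = partner
    holder.children[holder.children.index(partner)] = moved


def perturb_gene_trees(trees: Sequence[Tree], config: SimConfig) -> list[Tree]:
    """Apply gene-tree estimation noise and bootstrap-style supports.

    Each internal (non-trivial) edge is independently selected with
    probability ``nni_noise_prob``; a selected edge re-draws its local
    arrangement uniformly from the three possible resolutions (the original
    and its two NNI alternatives), so a selected quartet edge actually
    changes topology two times in three.  Selected edges draw support from
    the low distribution (default uniform 0--49, below the conventional 50%
    filter), untouched edges from the high one (default 80--100).  Each
    leaf is then deleted with probability ``missing_prob`` (never dropping
    a tree below four leaves).
    """
    rng = random.Random(config.seed)
    out = []
    for tree in trees:
        t = tree.copy()
        for node in t.nodes():
            if not node.is_leaf and node is not t.root:
                node.support = rng.uniform(*config.support_high)
        selected = [
            child
            for _, child, _ in _internal_edges(t)
            if rng.random() < config.nni_noise_prob
        ]
        for child in selected:
            child.support = rng.uniform(*config.support_low)
            pick = rng.randrange(3)
            if pick == 2:
                continue  # identity arrangement
            # earlier swaps may have moved this edge: re-derive its context
            fresh = {id(c): holder for _, c, holder in _internal_edges(t)}
            holder = fresh.get(id(child))
            if holder is None:
                continue  # edge became trivial under a previous swap
            k, partner = _nni_arrangements(child, holder)[pick]
            _swap(child, k, partner, holder)
        if config.missing_prob > 0:
            taxa = sorted(t.taxa)
            keep = [x for x in taxa if rng.random() >= config.missing_prob]
            if len(keep) < 4:
                keep = rng.sample(taxa, min(4, len(taxa)))
            if len(keep) < len(taxa):
                t = restrict_to_taxa(t, keep)
        out.append(t)
    return out


# ---------------------------------------------------------------------------
# Fixture bundles
# ---------------------------------------------------------------------------


def _network_lines(reticulations: Sequence[Reticulation]) -> list[str]:
    return [
        "recipient={}, donor={}, gamma={:g}, tau={:g}".format(
            "|".join(sorted(r.recipient)), "|".join(sorted(r.donor)), r.gamma, r.tau
        )
        for r in reticulations
    ]


def generate_dataset(
    model: Union[SpeciesTreeModel, NetworkModel],
    config: SimConfig,
    out_dir,
) -> dict:
    """Write a reproducible fixture bundle into ``out_dir``.

    Files: ``gene_trees.nwk`` (one Newick per line, with supports),
    ``true_species_tree.nwk``, ``true_network.txt`` (when reticulate) and
    ``manifest.json`` (seeds, parameters, per-gene parent labels).
    Re-running with the same model and config is byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if isinstance(model, NetworkModel):
        raw, labels = simulate_network_gene_trees(model, config.n_genes, config.seed)
        base = model.base
    else:
        raw = simulate_msc_gene_trees(model, config.n_genes, config.seed)
        labels = [() for _ in raw]
        base = model
    noisy = perturb_gene_trees(raw, config)
    write_newick_file(out_dir / "gene_trees.nwk", noisy)
    write_newick_file(out_dir / "true_species_tree.nwk", [base.tree])
    manifest = {
        "seed": config.seed,
        "n_genes": config.n_genes,
        "nni_noise_prob": config.nni_noise_prob,
        "missing_prob": config.missing_prob,
        "support_high": list(config.support_high),
        "support_low": list(config.support_low),
        # full precision so manifest replay is bit-exact
        "species_tree": write_newick(base.tree, precision=17),
        "reticulations": [],
        "gene_parent_labels": [list(lab) for lab in labels],
    }
    if isinstance(model, NetworkModel):
        manifest["reticulations"] = [r.as_dict() for r in model.reticulations]
        (out_dir / "true_network.txt").write_text(
            write_newick(base.tree) + "\n" + "\n".join(_network_lines(model.reticulations)) + "\n",
            encoding="utf-8",
        )
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def attach_outgroup(
    model: SpeciesTreeModel, label: str = "OUT", stem_cu: float = 2.0
) -> SpeciesTreeModel:
    """Add a first-diverging outgroup leaf above the current root.

    The old root gains a ``stem_cu`` CU edge; the outgroup pendant edge is
    terminal and carries the default terminal length.
    """
    if label in model.taxa:
        raise TreeError(f"taxon {label!r} already present")
    old_root = model.tree.root.copy()
    old_root.length = stem_cu
    new_root = Node(children=[Node(label, DEFAULT_TERMINAL_CU), old_root])
    return SpeciesTreeModel(Tree(new_root))


def distant_reticulation(
    model: SpeciesTreeModel,
    gamma: float = 0.5,
    tau: float = 0.1,
    exclude: Sequence[str] = (),
) -> NetworkModel:
    """A one-reticulation network whose minor displayed tree is maximally
    RF-displaced from the base tree: the recipient is a single leaf and the
    donor is the edge whose regraft moves that leaf across the most splits.

    ``exclude`` lists taxa (for example the outgroup) barred from both
    recipient and donor.  Deterministic: ties break on the
    lexicographically smallest (recipient, donor) description.
    """
    from .treecore import rf_distance  # local import avoids cycle at module load

    base_tree = model.tree
    excluded = frozenset(exclude)
    taxa = sorted(base_tree.taxa - excluded)
    clades = sorted(
        {
            n.leaf_labels()
            for n in base_tree.nodes()
            if n is not base_tree.root and not (n.leaf_labels() & excluded)
        },
        key=lambda c: (len(c), sorted(c)),
    )
    best = None
    for leaf in taxa:
        rec = frozenset((leaf,))
        for donor in clades:
            if rec & donor or len(donor) == len(taxa) - 1:
                continue
            try:
                candidate = NetworkModel(
                    model, (Reticulation(rec, donor, gamma, tau),)
                )
            except TreeError:
                continue
            disp = displayed_tree(candidate, (True,))
            d = rf_distance(base_tree, disp.tree)
            key = (-d, leaf, sorted(donor))
            if best is None or key < best[0]:
                best = (key, candidate)
    if best is None:
        raise TreeError("no valid reticulation on this species tree")
    return best[1]


def model_from_manifest(manifest: dict) -> Union[SpeciesTreeModel, NetworkModel]:
    """Rebuild the generating model from a manifest (for replay tests)."""
    base = SpeciesTreeModel(parse_newick(manifest["species_tree"]))
    retics = [
        Reticulation(
            recipient=frozenset(r["recipient"]),
            donor=frozenset(r["donor"]),
            gamma=r["gamma"],
            tau=r["tau"],
        )
        for r in manifest.get("reticulations", [])
    ]
    if retics:
        return NetworkModel(base, tuple(retics))
    return base
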