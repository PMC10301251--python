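"""Per-node gene-tree/species-tree conflict: concordance counts, internode
certainty (ICA), and quartet-sampling branch support (QC/QD/QI).

Concordance mapping follows the bipartition-vote scheme: for every
non-trivial species-tree bipartition, each gene tree is classified as
concordant, conflicting (recording which alternative split it supports,
one vote per gene), uninformative (no sufficiently supported informative
edge), or missing (the bipartition is trivial on the gene's taxa).  The
conventional bootstrap filter keeps only gene-tree edges with support at
or above ``min_support`` (default 50).

ICA is the entropy-based internode certainty over the reference split and
its prevalent conflicting alternatives: with relative frequencies
``p_0..p_{n-1}`` over the retained set of size ``n``,
``ICA = 1 + sum_i p_i log_n(p_i)``, negated when the reference is not the
(weakly) most frequent split; ``ICA = 1`` when no alternative is retained.

Quartet sampling draws, per internal branch and replicate, one taxon from
each of the branch's four surrounding subtrees plus one gene tree, and
reads the induced quartet: concordant (t0), one of the two discordant
resolutions (t1/t2), or uninformative.  QC = 1 + sum p_i log3(p_i) on the
informative replicates (negated when t0 is not the strict maximum),
QD = 1 - |t1 - t2|/(t1 + t2) (undefined, rendered "-", when no discordant
replicate was seen), QI = informative fraction.
"""

from __future__ import annotations

import math
import random
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .treecore import (
    Bipartition,
    Node,
    Tree,
    TreeError,
    bipartition_set,
    bipartition_supports,
    induced_topology,
    write_newick,
)

__all__ = [
    "NodeConflictSummary",
    "QSBranchScore",
    "compute_ica",
    "map_concordance",
    "quartet_sampling",
    "conflict_table",
    "qs_table",
    "annotated_species_tree",
]


@dataclass
class NodeConflictSummary:
    """Vote counts for one species-tree bipartition across gene trees."""

    bipartition: Bipartition
    concordant: int
    conflict_top: int
    conflict_other: int
    uninformative: int
    missing: int
    top_alternative: Optional[Bipartition]
    ica: float
    alternative_counts: dict = field(default_factory=dict, repr=False)

    @property
    def n_genes(self) -> int:
        return (
            self.concordant
            + self.conflict_top
            + self.conflict_other
            + self.uninformative
            + self.missing
        )

    @property
    def conflicting(self) -> int:
        return self.conflict_top + self.conflict_other


def compute_ica(
    reference_count: int,
    alternative_counts: Sequence[int],
    prevalence: float = 0.05,
) -> float:
    """Internode certainty (all) for a reference split versus its
    conflicting alternatives.

    Alternatives whose relative frequency among all considered splits falls
    below ``prevalence`` (default 5%) are dropped before normalising.
    """
    if reference_count < 0 or any(c < 0 for c in alternative_counts):
        raise ValueError("counts must be non-negative")
    total = reference_count + sum(alternative_counts)
    if total == 0:
        raise ValueError("all-zero counts")
    retained = [c for c in alternative_counts if c / total >= prevalence and c > 0]
    counts = [reference_count] + retained
    n = len(counts)
    if n == 1:
        return 1.0
    norm = sum(counts)
    magnitude = 1.0 + sum(
        (c / norm) * math.log(c / norm, n) for c in counts if c > 0
    )
    if retained and reference_count < max(retained):
        return -magnitude
    return magnitude


ROOT_MARKER = "<root>"


def _with_root_marker(tree: Tree) -> Tree:
    """Attach a phantom leaf at the root, turning rooted-clade comparison
    into ordinary unrooted bipartition comparison."""
    t = tree.copy()
    t.root.children.append(Node(ROOT_MARKER))
    return t


def map_concordance(
    species_tree: Tree,
    gene_trees: Sequence[Tree],
    min_support: Optional[float] = 50.0,
    prevalence: float = 0.05,
    rooted: bool = False,
) -> list[NodeConflictSummary]:
    """Classify every gene tree at every non-trivial species-tree node.

    Gene trees may lack taxa (subset of the species tree's).  Per node and
    gene: *missing* when the node's bipartition restricted to the gene's
    taxa is trivial; *concordant* when the gene carries an identical
    supported split; *conflicting* when it carries a supported incompatible
    split (the strongest-supported single one is the gene's vote);
    *uninformative* otherwise.  ``min_support=None`` disables the filter.

    With ``rooted=True`` the species tree and all gene trees must be
    rooted consistently (e.g. on a shared outgroup); comparison is then on
    rooted clades, realised by attaching a phantom root-marker leaf to
    every tree, so nodes such as "everything but the first-diverging
    lineage" become scoreable even when their unrooted split is trivial.
    """
    if rooted:
        if not species_tree.is_rooted:
            raise TreeError("rooted mapping requires a rooted species tree")
        bad = [i for i, g in enumerate(gene_trees) if not g.is_rooted]
        if bad:
            raise TreeError(f"rooted mapping requires rooted gene trees (tree {bad[0]})")
        species_tree = _with_root_marker(species_tree)
        gene_trees = [_with_root_marker(g) for g in gene_trees]
    sp_taxa = species_tree.taxa
    node_bips = sorted(bipartition_set(species_tree), key=str)
    if not node_bips:
        raise TreeError("species tree has no non-trivial bipartitions")

    # per gene: taxa and supported splits (computed once)
    gene_info = []
    for g in gene_trees:
        extra = g.taxa - sp_taxa
        if extra:
            raise TreeError(f"gene tree taxa not in species tree: {sorted(extra)}")
        sups = bipartition_supports(g)
        if min_support is None:
            splits = dict(sups)
        else:
            splits = {
                b: s for b, s in sups.items() if s is not None and s >= min_support
            }
        gene_info.append((g.taxa, splits))

    summaries = []
    for bip in node_bips:
        concordant = uninformative = missing = 0
        alt_counter: Counter = Counter()
        for gtaxa, splits in gene_info:
            rbip = bip.restricted(gtaxa)
            if rbip is None:
                missing += 1
                continue
            if rbip in splits:
                concordant += 1
                continue
            best = None
            best_sup = -1.0
            for gb, sup in splits.items():
                if not gb.compatible(rbip):
                    s = sup if sup is not None else 0.0
                    if s > best_sup or (s == best_sup and (best is None or str(gb) < str(best))):
                        best, best_sup = gb, s
            if best is not None:
                alt_counter[best] += 1
            else:
                uninformative += 1
        if alt_counter:
            top_alt, top_count = max(alt_counter.items(), key=lambda kv: (kv[1], str(kv[0])))
            conflict_other = sum(alt_counter.values()) - top_count
        else:
            top_alt, top_count, conflict_other = None, 0, 0
        if concordant == 0 and not alt_counter:
            ica = 1.0  # nothing informative mapped: no conflict observed
        else:
            ica = compute_ica(concordant, list(alt_counter.values()), prevalence=prevalence)
        summaries.append(
            NodeConflictSummary(
                bipartition=bip,
                concordant=concordant,
                conflict_top=top_count,
                conflict_other=conflict_other,
                uninformative=uninformative,
                missing=missing,
                top_alternative=top_alt,
                ica=ica,
                alternative_counts=dict(alt_counter),
            )
        )
    return summaries


# ---------------------------------------------------------------------------
# Quartet sampling
# ---------------------------------------------------------------------------


@dataclass
class QSBranchScore:
    """Quartet-sampling scores for one internal species-tree branch."""

    bipartition: Bipartition
    t0: int
    t1: int
    t2: int
    uninformative: int
    replicates: int

    @property
    def qc(self) -> Optional[float]:
        informative = self.t0 + self.t1 + self.t2
        if informative == 0:
            return None
        ps = [t / informative for t in (self.t0, self.t1, self.t2) if t > 0]
        magnitude = 1.0 + sum(p * math.log(p, 3) for p in ps)
        if self.t0 <= max(self.t1, self.t2):
            return -magnitude
        return magnitude

    @property
    def qd(self) -> Optional[float]:
        disc = self.t1 + self.t2
        if disc == 0:
            return None
        return 1.0 - abs(self.t1 - self.t2) / disc

    @property
    def qi(self) -> float:
        return (self.t0 + self.t1 + self.t2) / self.replicates

    def as_triplet(self) -> str:
        """Render like the conventional "QC/QD/QI" annotation, QD "-" when
        no discordant quartet was sampled."""
        qc = "-" if self.qc is None else f"{self.qc:.2f}".rstrip("0").rstrip(".")
        qd = "-" if self.qd is None else f"{self.qd:.2f}".rstrip("0").rstrip(".")
        qi = f"{self.qi:.2f}".rstrip("0").rstrip(".")
        return f"{qc}/{qd}/{qi}"


def _unrooted_adjacent_subtrees(tree: Tree) -> list[tuple[Bipartition, list, list]]:
    """For each internal (non-trivial) edge of the unrooted topology, the
    taxon sets of the subtrees adjacent to its two endpoints.

    Returns (bipartition, subtrees_on_block_side, subtrees_on_other_side),
    each side a list of >= 2 sorted taxon lists.
    """
    taxa = tree.taxa
    n = len(taxa)
    parent_of = {}
    leafsets = {}

    def collect(node):
        if node.is_leaf:
            ls = frozenset((node.label,))
        else:
            ls = frozenset()
            for c in node.children:
                parent_of[id(c)] = node
                ls = ls | collect(c)
        leafsets[id(node)] = ls
        return ls

    collect(tree.root)
    root = tree.root
    seen = set()
    out = []
    for node in tree.nodes():
        if node is root or node.is_leaf:
            continue
        below = leafsets[id(node)]
        if len(below) < 2 or len(below) > n - 2:
            continue
        bip = Bipartition.make(below, taxa)
        if bip in seen:  # degree-2 root: same unrooted edge seen twice
            continue
        seen.add(bip)
        # child side: the node's child subtrees
        child_side = [sorted(leafsets[id(c)]) for c in node.children]
        # parent side: sibling subtrees walking up, plus everything beyond
        parent = parent_of.get(id(node))
        other_side = []
        for sib in parent.children:
            if sib is not node:
                other_side.append(sorted(leafsets[id(sib)]))
        beyond = taxa - below - frozenset().union(
            *[frozenset(s) for s in other_side]
        ) if other_side else taxa - below
        if beyond:
            other_side.append(sorted(beyond))
        if len(other_side) < 2:
            # parent is a degree-2 root: split its single remaining subtree
            # at the opposite child's children
            opp_node = next(c for c in parent.children if c is not node)
            if opp_node.is_leaf or len(opp_node.children) < 2:
                continue  # trivial on that side
            other_side = [sorted(leafsets[id(c)]) for c in opp_node.children]
        out.append((bip, child_side, other_side))
    return out


def quartet_sampling(
    species_tree: Tree,
    gene_trees: Sequence[Tree],
    replicates_per_branch: int = 1000,
    seed: int = 0,
) -> list[QSBranchScore]:
    """Quartet-sampling support for every internal species-tree branch.

    Each replicate samples one taxon from each of the four subtrees the
    branch defines and one gene tree uniformly at random, then scores the
    gene tree's induced quartet.  The orientation of the two discordant
    classes is fixed by the lexicographic order of the sampled subtrees, so
    QD is reproducible under a fixed seed.
    """
    if len(species_tree.taxa) < 4:
        raise TreeError("quartet sampling needs at least 4 taxa")
    if not gene_trees:
        raise TreeError("quartet sampling needs at least one gene tree")
    rng = random.Random(seed)
    gene_taxa = [g.taxa for g in gene_trees]
    scores = []
    for bip, side_a, side_b in _unrooted_adjacent_subtrees(species_tree):
        side_a = sorted(side_a)
        side_b = sorted(side_b)
        t0 = t1 = t2 = u = 0
        for _ in range(replicates_per_branch):
            sa = rng.sample(range(len(side_a)), 2) if len(side_a) > 2 else (0, 1)
            sb = rng.sample(range(len(side_b)), 2) if len(side_b) > 2 else (0, 1)
            a1 = side_a[min(sa)][rng.randrange(len(side_a[min(sa)]))]
            a2 = side_a[max(sa)][rng.randrange(len(side_a[max(sa)]))]
            b1 = side_b[min(sb)][rng.randrange(len(side_b[min(sb)]))]
            b2 = side_b[max(sb)][rng.randrange(len(side_b[max(sb)]))]
            gi = rng.randrange(len(gene_trees))
            quartet = {a1, a2, b1, b2}
            if not quartet <= gene_taxa[gi]:
                u += 1
                continue
            pair = induced_topology(gene_trees[gi], quartet)
            if pair is None:
                u += 1
            elif pair in ({a1, a2}, {b1, b2}):
                t0 += 1
            elif pair in ({a1, b1}, {a2, b2}):
                t1 += 1
            else:
                t2 += 1
        scores.append(
            QSBranchScore(
                bipartition=bip,
                t0=t0,
                t1=t1,
                t2=t2,
                uninformative=u,
                replicates=replicates_per_branch,
            )
        )
    return scores


# ---------------------------------------------------------------------------
# Tabular / annotated output
# ---------------------------------------------------------------------------


def conflict_table(summaries: Sequence[NodeConflictSummary]) -> pd.DataFrame:
    """Per-node table with the five counts, their proportions (the pie
    categories: concordant / top-conflict / other-conflict / uninformative
    / missing) and ICA."""
    rows = []
    for s in summaries:
        n = s.n_genes
        rows.append(
            {
                "node": str(s.bipartition),
                "concordant": s.concordant,
                "conflict_top": s.conflict_top,
                "conflict_other": s.conflict_other,
                "uninformative": s.uninformative,
                "missing": s.missing,
                "p_concordant": s.concordant / n,
                "p_conflict_top": s.conflict_top / n,
                "p_conflict_other": s.conflict_other / n,
                "p_uninformative": s.uninformative / n,
                "p_missing": s.missing / n,
                "ica": s.ica,
                "top_alternative": "" if s.top_alternative is None else str(s.top_alternative),
            }
        )
    return pd.DataFrame(rows)


def qs_table(scores: Sequence[QSBranchScore]) -> pd.DataFrame:
    rows = []
    for s in scores:
        rows.append(
            {
                "branch": str(s.bipartition),
                "t0": s.t0,
                "t1": s.t1,
                "t2": s.t2,
                "uninformative": s.uninformative,
                "qc": float("nan") if s.qc is None else s.qc,
                "qd": float("nan") if s.qd is None else s.qd,
                "qi": s.qi,
                "qs": s.as_triplet(),
            }
        )
    return pd.DataFrame(rows)


def annotated_species_tree(
    species_tree: Tree, summaries: Sequence[NodeConflictSummary]
) -> str:
    """Newick with "concordant/conflicting" labels on internal nodes,
    mirroring the convention of printing gene-tree counts below branches."""
    by_bip = {s.bipartition: s for s in summaries}
    tree = species_tree.copy()
    taxa = tree.taxa
    n = len(taxa)

    def annotate(node) -> frozenset:
        if node.is_leaf:
            return frozenset((node.label,))
        ls = frozenset().union(*(annotate(c) for c in node.children))
        if node is not tree.root and 2 <= len(ls) <= n - 2:
            s = by_bip.get(Bipartition.make(ls, taxa))
            if s is not None:
                node.support = None
                node.label = f"{s.concordant}/{s.conflicting}"
        return ls

    annotate(tree.root)
    return write_newick(tree)
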