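"""Hybridization inference from rooted-triple frequencies.

A one-reticulation phylogenetic network is modelled as a mixture of its two
displayed species trees: with inheritance probability gamma a gene follows
the minor (donor) displayed tree, else the major (base) tree.  Under the
multispecies coalescent the probability of each rooted-triple resolution in
a displayed tree has the closed form ``concordant = 1 - (2/3) e^{-t}`` and
``(1/3) e^{-t}`` for each alternative, where ``t`` is the coalescent-unit
path length between the triple's two internal nodes.  Observed triple
counts from the gene trees (rooted on a fixed outgroup) then yield a
multinomial pseudo-log-likelihood

    PL(gamma, tau) = sum_triples sum_resolutions n log p(gamma, tau)

maximised over the inheritance probability gamma in [0, 1] and the
donor-attachment length tau by grid scan plus bounded local refinement.
Candidate reticulations (ordered recipient/donor edge pairs) are fitted
exhaustively and ranked by maximised PL; further reticulations are added
greedily with earlier ones frozen, each retained only if it improves PL by
a configurable threshold.  PL values are comparable across candidates
(every triple enters every sum) but are not full network likelihoods.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .treecore import Tree, TreeError, reroot
from .synthetic_data import (
    NetworkModel,
    Reticulation,
    SpeciesTreeModel,
    _displayed,
    displayed_tree,
)

__all__ = [
    "TripleCountTable",
    "NetworkFit",
    "ScanResult",
    "count_rooted_triples",
    "expected_triple_probs",
    "tree_pseudo_likelihood",
    "fit_single_reticulation",
    "scan_and_rank_networks",
    "ranked_table",
]

TAU_MAX = 10.0
_P_FLOOR = 1e-12


# ---------------------------------------------------------------------------
# Triple counting
# ---------------------------------------------------------------------------


@dataclass
class TripleCountTable:
    """Rooted-triple resolution counts across gene trees.

    ``counts[triple]`` maps each of the three pair resolutions (frozensets)
    and ``None`` (unresolved) to a count; triples a gene lacks simply do
    not contribute, so per-triple totals can fall below ``n_trees_used``.
    """

    taxa: frozenset
    counts: dict
    n_trees_used: int
    n_trees_skipped: int

    def triples(self) -> list[frozenset]:
        return sorted(self.counts, key=lambda t: sorted(t))

    def resolved_total(self) -> int:
        return sum(
            c for table in self.counts.values() for k, c in table.items() if k is not None
        )


def _leaf_paths(tree: Tree) -> dict[str, list[int]]:
    """Root-to-leaf node-id paths (for topological LCA depths)."""
    paths: dict[str, list[int]] = {}

    def walk(node, prefix):
        prefix = prefix + [id(node)]
        if node.is_leaf:
            paths[node.label] = prefix
        else:
            for c in node.children:
                walk(c, prefix)

    walk(tree.root, [])
    return paths


def _lca_depth(pa: list[int], pb: list[int]) -> int:
    d = -1
    for x, y in zip(pa, pb):
        if x != y:
            break
        d += 1
    return d


def _resolve_triple(depth_ab: int, depth_ac: int, depth_bc: int, a, b, c):
    depths = {frozenset((a, b)): depth_ab, frozenset((a, c)): depth_ac, frozenset((b, c)): depth_bc}
    dmax = max(depths.values())
    dmin = min(depths.values())
    if dmax == dmin:
        return None
    return next(p for p, d in depths.items() if d == dmax)


def count_rooted_triples(
    gene_trees: Sequence[Tree],
    outgroup: str,
    taxa: Optional[Sequence[str]] = None,
) -> TripleCountTable:
    """Count the three rooted resolutions of every taxon triple.

    Each gene tree is rerooted on ``outgroup`` (then the outgroup is
    excluded from triples); trees lacking the outgroup, or a triple's taxa,
    skip the affected counts.
    """
    restrict = None if taxa is None else frozenset(taxa) - {outgroup}
    counts: dict[frozenset, dict] = {}
    used = skipped = 0
    all_taxa: set = set()
    for g in gene_trees:
        if outgroup not in g.taxa:
            skipped += 1
            continue
        used += 1
        rooted = reroot(g, outgroup)
        ingroup = next(
            c for c in rooted.root.children if not (c.is_leaf and c.label == outgroup)
        )
        sub = Tree(ingroup)
        gtaxa = sub.taxa if restrict is None else sub.taxa & restrict
        all_taxa |= gtaxa
        paths = _leaf_paths(sub)
        ordered = sorted(gtaxa)
        lca = {}
        for x, y in combinations(ordered, 2):
            lca[(x, y)] = _lca_depth(paths[x], paths[y])
        for a, b, c in combinations(ordered, 3):
            triple = frozenset((a, b, c))
            table = counts.setdefault(
                triple,
                {frozenset((a, b)): 0, frozenset((a, c)): 0, frozenset((b, c)): 0, None: 0},
            )
            table[_resolve_triple(lca[(a, b)], lca[(a, c)], lca[(b, c)], a, b, c)] += 1
    if used == 0:
        raise TreeError(f"outgroup {outgroup!r} absent from every gene tree")
    return TripleCountTable(
        taxa=frozenset(all_taxa), counts=counts, n_trees_used=used, n_trees_skipped=skipped
    )


# ---------------------------------------------------------------------------
# Expected triple probabilities
# ---------------------------------------------------------------------------


def _cu_depths_and_paths(tree: Tree):
    depths: dict[int, float] = {id(tree.root): 0.0}
    paths: dict[str, list[int]] = {}

    def walk(node, prefix):
        prefix = prefix + [id(node)]
        if node.is_leaf:
            paths[node.label] = prefix
        for c in node.children:
            depths[id(c)] = depths[id(node)] + (c.length or 0.0)
            walk(c, prefix)

    walk(tree.root, [])
    return depths, paths


def _displayed_triple_probs(
    model: SpeciesTreeModel, triples: Sequence[frozenset]
) -> dict[frozenset, dict[frozenset, float]]:
    """Closed-form MSC rooted-triple probabilities in one displayed tree."""
    depths, paths = _cu_depths_and_paths(model.tree)

    def lca_cu(x, y):
        pa, pb = paths[x], paths[y]
        node = pa[0]
        for u, v in zip(pa, pb):
            if u != v:
                break
            node = u
        return depths[node]

    out = {}
    for triple in triples:
        a, b, c = sorted(triple)
        d = {
            frozenset((a, b)): lca_cu(a, b),
            frozenset((a, c)): lca_cu(a, c),
            frozenset((b, c)): lca_cu(b, c),
        }
        dmax = max(d.values())
        dmin = min(d.values())
        t = dmax - dmin
        disc = (1.0 / 3.0) * math.exp(-t)
        conc_pair = next(p for p, v in d.items() if v == dmax)
        out[triple] = {
            p: (1.0 - 2.0 * disc if p == conc_pair else disc) for p in d
        }
    return out


def _all_triples(taxa: Sequence[str]) -> list[frozenset]:
    return [frozenset(t) for t in combinations(sorted(taxa), 3)]


def expected_triple_probs(
    model: NetworkModel,
    gamma: Optional[float] = None,
    tau: Optional[float] = None,
    taxa: Optional[Sequence[str]] = None,
) -> dict[frozenset, dict[frozenset, float]]:
    """Per-triple resolution probabilities under the network: the
    gamma-weighted mixture of displayed-tree MSC probabilities.

    ``gamma``/``tau`` override the *last* (focal) reticulation's values;
    probabilities sum to one per triple.
    """
    if gamma is not None and not 0.0 <= gamma <= 1.0:
        raise TreeError("gamma must lie in [0, 1]")
    if tau is not None and tau < 0:
        raise TreeError("tau must be >= 0")
    retics = list(model.reticulations)
    if retics:
        focal = retics[-1]
        retics[-1] = Reticulation(
            recipient=focal.recipient,
            donor=focal.donor,
            gamma=focal.gamma if gamma is None else gamma,
            tau=focal.tau if tau is None else tau,
        )
    work = NetworkModel(model.base, tuple(retics))
    triple_list = _all_triples(taxa if taxa is not None else sorted(work.taxa))
    mix: dict[frozenset, dict[frozenset, float]] = {}
    r = len(retics)
    for mask in range(2 ** r):
        states = tuple(bool(mask >> i & 1) for i in range(r))
        weight = 1.0
        for retic, minor in zip(retics, states):
            weight *= retic.gamma if minor else (1.0 - retic.gamma)
        if weight == 0.0:
            continue
        probs = _displayed_triple_probs(displayed_tree(work, states), triple_list)
        for triple, table in probs.items():
            acc = mix.setdefault(triple, {p: 0.0 for p in table})
            for p, v in table.items():
                acc[p] += weight * v
    return mix


# ---------------------------------------------------------------------------
# Pseudo-likelihood fitting
# ---------------------------------------------------------------------------


def _count_arrays(counts: TripleCountTable):
    """Triples with their resolution order and an (T, 3) count matrix."""
    triples = counts.triples()
    order = []
    n = np.zeros((len(triples), 3))
    for i, triple in enumerate(triples):
        pairs = sorted(
            (p for p in counts.counts[triple] if p is not None),
            key=lambda p: sorted(p),
        )
        order.append(pairs)
        for j, p in enumerate(pairs):
            n[i, j] = counts.counts[triple][p]
    return triples, order, n


def _prob_matrix(probs: dict, triples, order) -> np.ndarray:
    out = np.empty((len(triples), 3))
    for i, triple in enumerate(triples):
        for j, pair in enumerate(order[i]):
            out[i, j] = probs[triple][pair]
    return out


def _log_pl(n: np.ndarray, p: np.ndarray) -> float:
    return float(np.sum(n * np.log(np.maximum(p, _P_FLOOR))))


def tree_pseudo_likelihood(counts: TripleCountTable, base: SpeciesTreeModel) -> float:
    """Pseudo-log-likelihood of the reticulation-free species tree."""
    triples, order, n = _count_arrays(counts)
    probs = _displayed_triple_probs(base, triples)
    return _log_pl(n, _prob_matrix(probs, triples, order))


@dataclass
class NetworkFit:
    """A fitted one-reticulation candidate (possibly on top of frozen
    earlier reticulations)."""

    model: NetworkModel
    recipient: frozenset
    donor: frozenset
    gamma_hat: float
    tau_hat: float
    log_pseudolikelihood: float
    expected_probs: dict = field(repr=False, default_factory=dict)

    @property
    def gamma_pair(self) -> tuple[float, float]:
        """(minor, major) inheritance probabilities; they sum to one."""
        return (self.gamma_hat, 1.0 - self.gamma_hat)


def fit_single_reticulation(
    counts: TripleCountTable,
    base: SpeciesTreeModel,
    candidate: tuple[frozenset, frozenset],
    frozen: Sequence[Reticulation] = (),
    tau_max: float = TAU_MAX,
    grid: int = 21,
    tol: float = 1e-4,
) -> NetworkFit:
    """Maximum-pseudo-likelihood fit of (gamma, tau) for one candidate
    reticulation, earlier reticulations held fixed.

    A ``grid`` x ``grid`` scan over gamma in [0, 1] and tau in [0, tau_max]
    seeds coordinate-wise bounded refinement (tolerance ``tol``); all
    triples enter the objective so fits are comparable across candidates.
    """
    recipient, donor = (frozenset(candidate[0]), frozenset(candidate[1]))
    triples, order, n = _count_arrays(counts)
    if n.sum() == 0:
        raise TreeError("no resolved triples to fit")
    frozen = tuple(frozen)
    # validates regraft feasibility for every displayed tree once
    model0 = NetworkModel(base, frozen + (Reticulation(recipient, donor, 0.5, 0.0),))

    r_frozen = len(frozen)
    frozen_states = []
    for mask in range(2 ** r_frozen):
        states = tuple(bool(mask >> i & 1) for i in range(r_frozen))
        w = 1.0
        for retic, minor in zip(frozen, states):
            w *= retic.gamma if minor else (1.0 - retic.gamma)
        if w > 0.0:
            frozen_states.append((states, w))

    # the major side never moves the recipient: independent of tau
    p_major = np.zeros_like(n)
    for states, w in frozen_states:
        probs = _displayed_triple_probs(displayed_tree(model0, states + (False,)), triples)
        p_major += w * _prob_matrix(probs, triples, order)

    def p_minor_for(tau: float) -> np.ndarray:
        retics = frozen + (Reticulation(recipient, donor, 0.5, tau),)
        pm = np.zeros_like(n)
        for states, w in frozen_states:
            probs = _displayed_triple_probs(_displayed(base, retics, states + (True,)), triples)
            pm += w * _prob_matrix(probs, triples, order)
        return pm

    gammas = np.linspace(0.0, 1.0, grid).reshape(-1, 1, 1)
    taus = np.linspace(0.0, tau_max, grid)
    best = None
    for tau in taus:
        pm = p_minor_for(tau)
        vals = np.sum(
            n * np.log(np.maximum(gammas * pm + (1.0 - gammas) * p_major, _P_FLOOR)),
            axis=(1, 2),
        )
        k = int(np.argmax(vals))
        if best is None or vals[k] > best[0]:
            best = (float(vals[k]), float(gammas[k, 0, 0]), float(tau))
    _, g_best, tau_best = best

    # coordinate refinement: gamma is cheap (cached matrices), tau rebuilds
    def neg_pl_gamma(g, pm):
        return -_log_pl(n, g * pm + (1.0 - g) * p_major)

    def neg_pl_tau(tau, g):
        return -_log_pl(n, g * p_minor_for(tau) + (1.0 - g) * p_major)

    g_step = 1.0 / (grid - 1)
    t_step = tau_max / (grid - 1)
    for _ in range(2):
        pm = p_minor_for(tau_best)
        res = optimize.minimize_scalar(
            neg_pl_gamma,
            bounds=(max(0.0, g_best - g_step), min(1.0, g_best + g_step)),
            args=(pm,),
            method="bounded",
            options={"xatol": tol},
        )
        g_best = float(res.x)
        res = optimize.minimize_scalar(
            neg_pl_tau,
            bounds=(max(0.0, tau_best - t_step), min(tau_max, tau_best + t_step)),
            args=(g_best,),
            method="bounded",
            options={"xatol": tol},
        )
        tau_best = float(res.x)
    pm, pM = p_minor_for(tau_best), p_major
    # bounded refinement never lands exactly on a boundary; re-check the
    # endpoints so the fit is never below its nested special cases
    candidates = [
        (_log_pl(n, g * pm + (1.0 - g) * pM), g)
        for g in (g_best, 0.0, 1.0)
    ]
    final_pl, g_best = max(candidates)
    fitted = NetworkModel(
        base, frozen + (Reticulation(recipient, donor, g_best, tau_best),)
    )
    probs = {
        triple: dict(zip(order[i], (g_best * pm + (1 - g_best) * pM)[i]))
        for i, triple in enumerate(triples)
    }
    return NetworkFit(
        model=fitted,
        recipient=recipient,
        donor=donor,
        gamma_hat=g_best,
        tau_hat=tau_best,
        log_pseudolikelihood=final_pl,
        expected_probs=probs,
    )


# ---------------------------------------------------------------------------
# Candidate scan
# ---------------------------------------------------------------------------


@dataclass
class ScanResult:
    """Ranked single-reticulation fits plus the greedily selected network."""

    table: list  # round-1 NetworkFit, sorted by decreasing PL
    selected: NetworkModel
    retained: list  # NetworkFit retained greedily, in order
    tree_log_pl: float
    improvement_threshold: float

    @property
    def n_reticulations(self) -> int:
        return len(self.retained)


def _candidate_clades(base: SpeciesTreeModel, outgroup: Optional[str]) -> list[frozenset]:
    tree = base.tree
    n = len(tree.taxa)
    clades = set()
    for node in tree.nodes():
        if node is tree.root:
            continue
        ls = node.leaf_labels()
        if outgroup is not None and outgroup in ls:
            continue
        if len(ls) >= n - 1:
            continue
        clades.add(ls)
    return sorted(clades, key=lambda c: (len(c), sorted(c)))


def scan_and_rank_networks(
    gene_trees: Sequence[Tree],
    base: SpeciesTreeModel,
    outgroup: str,
    max_reticulations: int = 5,
    improvement_threshold: Optional[float] = None,
    tau_max: float = TAU_MAX,
    grid: int = 21,
) -> ScanResult:
    """Exhaustive one-reticulation scan, PL ranking, and greedy growth.

    Every ordered (recipient, donor) pair of disjoint non-root,
    non-outgroup edges is fitted; the ranked table is the single-event
    analysis.  Reticulations are then retained greedily (earlier ones
    frozen at their fitted values) while each improves the pseudo-log-
    likelihood by at least ``improvement_threshold`` (default 1% of the
    tree's |PL|), up to ``max_reticulations``.
    """
    if outgroup not in base.taxa:
        raise TreeError(f"outgroup {outgroup!r} not in the species tree")
    if len(base.taxa) - 1 < 4:
        raise TreeError("need at least 4 non-outgroup taxa")
    counts = count_rooted_triples(gene_trees, outgroup)
    tree_pl = tree_pseudo_likelihood(counts, base)
    if improvement_threshold is None:
        improvement_threshold = 0.01 * abs(tree_pl)
    clades = _candidate_clades(base, outgroup)
    candidates = [
        (rec, don)
        for rec in clades
        for don in clades
        if rec != don and not (rec & don)
    ]

    def fit_round(frozen: tuple) -> list[NetworkFit]:
        fits = []
        for rec, don in candidates:
            if any(rec == f.recipient for f in frozen_fits):
                continue
            try:
                fits.append(
                    fit_single_reticulation(
                        counts,
                        base,
                        (rec, don),
                        frozen=frozen,
                        tau_max=tau_max,
                        grid=grid,
                    )
                )
            except TreeError:
                continue
        fits.sort(
            key=lambda f: (-f.log_pseudolikelihood, sorted(f.recipient), sorted(f.donor))
        )
        return fits

    frozen_fits: list[NetworkFit] = []
    table: list[NetworkFit] = []
    current_pl = tree_pl
    for round_idx in range(max_reticulations):
        fits = fit_round(tuple(f.model.reticulations[-1] for f in frozen_fits))
        if round_idx == 0:
            table = fits
        if not fits:
            break
        best = fits[0]
        if best.log_pseudolikelihood - current_pl < improvement_threshold:
            break
        frozen_fits.append(best)
        current_pl = best.log_pseudolikelihood
    selected = NetworkModel(
        base, tuple(f.model.reticulations[-1] for f in frozen_fits)
    ) if frozen_fits else NetworkModel(base, ())
    return ScanResult(
        table=table,
        selected=selected,
        retained=frozen_fits,
        tree_log_pl=tree_pl,
        improvement_threshold=improvement_threshold,
    )


def ranked_table(result: ScanResult) -> pd.DataFrame:
    """Table-3-style ranking of all single-reticulation candidates."""
    rows = []
    for f in result.table:
        rows.append(
            {
                "recipient": "|".join(sorted(f.recipient)),
                "donor": "|".join(sorted(f.donor)),
                "gamma_minor": f.gamma_hat,
                "gamma_major": 1.0 - f.gamma_hat,
                "tau": f.tau_hat,
                "log_pseudolikelihood": f.log_pseudolikelihood,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["tree_log_pl"] = result.tree_log_pl
    return df
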