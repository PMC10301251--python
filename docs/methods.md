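# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `phylodiscord`. Everything stated here is computed by
the test suite or the pipeline itself; nothing is quoted from external
runs.

## Tree model and conventions

Trees are rooted node structures with optional branch lengths (on the node
below each edge) and optional supports on internal edges (0–100 scale, the
ML-bootstrap dialect: numeric internal-node labels in Newick are read as
supports; a flag switches to bracket-comment supports). All tree-to-tree
comparisons — bipartition sets, Robinson–Foulds (RF) distances, quartet
topologies — are on unrooted topologies with branch lengths ignored: the
discordance analyses are topological, and a degree-two root's two edges
encode a single split. Polytomies are first-class and never count as a
conflicting split, only as unresolved. Output is deterministic: children
are ordered by smallest descendant label and numbers printed at 6
significant digits (internal manifests use 17 digits so that replay is
bit-exact).

Species-tree branch lengths are coalescent units (CU; 1 CU = 2N
generations). Gene-tree branch lengths are carried through parsing and
writing but never interpreted.

One reading deserves flagging: tree-to-tree distances here are unrooted
RF. Rooted comparison (adding the root as a pseudo-taxon) would shift all
distances up by at most 2 and does not change the shape of the
distributions the ILS test compares; the unrooted convention is the common
one for RF workflows and is what the package uses throughout.

## Synthetic data: what it emulates, and what it does not

The generator stands in for transcriptome-derived single-copy gene-tree
sets: 9–26 taxa, several hundred to ~1,400 gene trees, discordance driven
by ILS on coalescent-unit internal branches, optionally a few
reticulations with inheritance probability γ near 0.5, bootstrap-style
supports, and missing taxa.

* **Species trees** are uniform-coalescent-shape random topologies with
  i.i.d. exponential internal CU lengths (default mean chosen per
  experiment, typically 1.2–2 CU — moderate ILS, 10–45% discordant triples
  per branch) and terminal branches fixed at 1 CU. Terminal lengths are
  unidentifiable from topology frequencies and never matter downstream.
* **MSC simulation** runs the standard per-branch coalescent: within a
  branch of length T carrying k lineages, waiting times are exponential
  with rate k(k−1)/2; survivors pass rootward; the branch above the root
  is infinite. Times are measured as depth from the root, so the algorithm
  is well defined for non-ultrametric species trees. The closed form
  P(concordant rooted triple) = 1 − (2/3)e^(−t) is the independent oracle
  the simulator is tested against (t ∈ {0, 0.5, 1, 2}, three binomial
  standard errors).
* **Networks** are a base species tree plus reticulations
  (recipient edge, donor edge, γ, τ), edges named by the clade below them;
  recipient and donor clades must be disjoint (this is the acyclicity
  rule). Each gene independently follows the minor displayed tree with
  probability γ: the recipient clade is pruned and regrafted onto the
  midpoint of the donor edge with pendant length τ. This is a *per-gene*
  (not per-lineage) inheritance model; the fitting stage assumes exactly
  the same mixture, so simulator and estimator are consistent by
  construction. Real hybridization with per-lineage inheritance produces
  additional mixture components that this model averages over.
* **Estimation noise** is topology-level: each internal edge is selected
  with probability `nni_noise_prob` and re-draws its local arrangement
  uniformly from the three possible resolutions (original plus the two
  NNI alternatives), so a selected quartet edge actually changes two times
  in three. Selected edges get supports from the low band (uniform 0–49),
  others from the high band (80–100), so the conventional bootstrap ≥ 50
  filter is exercised by construction. Sequence-level simulation and
  re-inference are out of scope; NNI noise reproduces the *pattern* of
  estimation error (local rearrangements with low support) but not its
  alignment-length dependence.
* All randomness flows from a single integer seed per call; `generate_dataset`
  bundles are byte-identical under manifest replay.

Consequence for interpretation: passing tests show the chain is correct
*under the MSC-plus-regraft model with these noise patterns*; they do not
certify behaviour under model violations such as substitution-rate
heterogeneity, paralogy, or alignment error.

## Conflict mapping and ICA

For each non-trivial species-tree bipartition and each gene tree:
missing (the bipartition restricted to the gene's taxa has a side with
fewer than two taxa) takes precedence; otherwise concordant if the gene
carries an identical supported split; otherwise conflicting if it carries
a supported incompatible split — each gene casts one vote, its
strongest-supported incompatible split; otherwise uninformative. The five
categories sum to the number of gene trees at every node (a tested
invariant). With `rooted=True` the comparison is on rooted clades,
implemented by attaching a phantom root-marker leaf to every tree; this is
how a node like "everything but the first-diverging lineage" is scored.

ICA uses the reference split plus the conflicting alternatives whose
relative frequency (among all considered) is at least 5% (configurable);
with normalized frequencies p over the retained set of size n,
ICA = 1 + Σ p log_n p, negated when the reference is not the weakly most
frequent. n = 1 gives ICA = 1; ties keep the positive sign so magnitude is
reported. When a node has no concordant and no conflicting gene (all
uninformative/missing), no conflict was observed and ICA is reported as 1.

## Quartet sampling

Per internal branch and replicate: one taxon from each of the four
subtrees adjacent to the branch's endpoints, one gene tree uniformly at
random, and the induced quartet read from that gene tree (missing taxa or
a polytomy count as uninformative). QC = 1 + Σ pᵢ log₃ pᵢ over the
informative counts (t₀, t₁, t₂), negated when t₀ is not the strict
maximum; QD = 1 − |t₁ − t₂| / (t₁ + t₂), undefined (rendered "−") when no
discordant replicate was seen; QI is the informative fraction. The t₁/t₂
orientation is fixed by the lexicographic order of the adjacent subtrees,
so scores are reproducible under a fixed seed. Quartets are evaluated on
the *gene trees* (not by per-quartet likelihood on an alignment, which
would require sequence machinery); the score formulas are unchanged by
this mode difference. At a polytomous endpoint, two of its subtrees are
drawn at random per replicate.

## Species-tree estimation

The quartet score of a candidate topology is the exhaustive count of
gene-tree quartets (over all four-taxon subsets present and resolved in
each gene tree) whose induced split matches the candidate. At n ≤ 26 taxa
this is at most ~15k quartets per gene and is computed exactly — no
quartet subsampling. The search starts from the majority-rule consensus
(polytomies resolved at random but deterministically by seed) and
hill-climbs over all NNI neighbours (two per internal edge), accepting
strict improvements, ties broken by canonical Newick order. The score of
the true species tree is the quartet-frequency optimum under the MSC, so
the estimator is consistent; the test suite verifies global optimality
against all 945 seven-taxon topologies on simulated data and recovery on
eight-taxon trees. NNI-only search can in principle stall on a local
optimum under extreme ILS mixed with noise; the working regimes here
(internal branches ≳ 0.3 CU, hundreds of genes) have a benign score
surface.

Branch lengths: per internal branch, the concordant fraction p̂ of sampled
informative quartets around the branch (default 2,000 draws) is inverted
through T̂ = −ln(1.5(1 − p̂)), clamped to 0 for p̂ ≤ 1/3 and capped at 10 CU
(discordance e^(−10) ≈ 4.5·10⁻⁵ is below Monte-Carlo resolution; branches
with no informative draw also get the cap, with a warning). Terminal
branches are fixed at 1 CU. The two edges of a degree-two root share one
unrooted branch; its estimate is split evenly between them. The estimator
recovers t ∈ {0.5, 1, 2} within ±0.1 CU from 5,000 genes (tested).

## ILS simulation test

The null model is the CU-scaled species tree ("guide tree"); 20,000 gene
trees are simulated from it by default. Observed and simulated trees are
reduced to normalized RF distance to the species tree — RF divided by the
binary maximum 2(n_shared − 3) on the tree's shared taxon set, so gene
trees with missing taxa are comparable — and binned at width 0.05 on
[0, 1]. The verdict statistic is the overlap coefficient
Σ_bins min(f_obs, f_sim) of the frequency-normalized histograms:
`ILS-sufficient` iff overlap ≥ 0.75. The threshold operationalizes a
judgment that is usually made visually; it is configurable and always
reported. A two-sample KS test on the raw normalized distances is reported
but deliberately not used for the verdict: with 20,000 simulated trees KS
rejects under negligible effect sizes.

Calibration and power (both tested): with the true generating guide tree,
pure-MSC observed sets of 500 genes are called ILS-sufficient in ≥ 90% of
seeds (overlap typically 0.95+), and γ = 0.5 reticulations whose minor
displayed tree is RF-displaced by several splits drive the overlap to
0.5–0.7, below threshold. **Known limitation:** when the guide tree's CU
lengths are re-estimated from reticulate observed data (the pipeline's
default when no guide is supplied), branches around the hybrid shrink and
the broadened null partially absorbs the signal; the verdict can then stay
ILS-sufficient in a minority-to-half of such runs. The triple-frequency
network scan remains sensitive in exactly this situation, which is why the
pipeline always runs both.

## Network fitting

Rooted triples are counted from gene trees rerooted on a fixed outgroup
(excluded from the triples); trees lacking the outgroup or a triple's
taxa skip those counts. Under the per-gene mixture model the expected
probability of each triple resolution is
γ · P_minor + (1 − γ) · P_major, with each displayed tree's probabilities
from the closed form (concordant 1 − (2/3)e^(−t), each alternative
(1/3)e^(−t), t the CU path between the triple's two internal nodes). The
fit maximizes PL(γ, τ) = Σ_triples Σ_resolutions n log p over γ ∈ [0, 1]
and τ ∈ [0, 10] by a 21×21 grid scan followed by two rounds of
coordinate-wise bounded refinement (tolerance 10⁻⁴), with the γ ∈ {0, 1}
endpoints re-checked at the end so the fit never falls below its nested
special cases (PL at the optimum ≥ PL of the tree, a tested invariant).
All triples enter every sum, so PL values are comparable across
candidates. Probabilities are floored at 10⁻¹² inside the log.

The scan fits every ordered (recipient, donor) pair of disjoint non-root,
non-outgroup edges, ranks by PL, and grows the network greedily: earlier
reticulations are frozen at their fitted values, one new event is fitted
per round, and an event is retained only if it improves PL by at least 1%
of |tree PL| (configurable). This threshold replaces a raw likelihood
comparison because pseudo-likelihoods across different reticulation counts
are not nested test statistics. Base CU lengths are plug-in estimates, not
co-estimated — a documented bias source under strong ILS (γ̂ shifts toward
the major edge when the guide tree was estimated from the hybrid data
itself, as in the README example). Absolute PL values are not full
gene-tree likelihoods and are not comparable to other tools' numbers; the
structural outputs (which branch is the hybrid, γ̂ near its true value) are
the estimands. γ recovery is tested: |γ̂ − γ| ≤ 0.05 at 2,000 noise-free
genes for γ = 0.45, specificity ≥ 90% of null seeds retaining zero events,
and the planted recipient ranks first in ≥ 90% of seeds at 800 genes.

## Pipeline determinism and problem sizes

Every stage derives its sub-seed as CRC32(master seed : stage name), so
stage results are invariant to adding or removing other stages, and a full
run is byte-identical under a fixed master seed (tested). Reports
serialize all numbers at 6 significant digits.

Default problem sizes follow the working conditions above: 1,000 quartet
replicates per branch, 2,000 quartet draws per branch for CU lengths,
20,000 simulated null trees, up to 5 reticulations. The test suite runs
the same experiments at the sizes its statistical assertions require
(e.g. 50,000 three-taxon simulations for the triple law, 20 seeds for
recovery rates, 300–800-gene fixtures for integration runs), chosen so
each assertion has explicit binomial/Monte-Carlo tolerances.

## Degenerate inputs and tie-breaking

Trees with fewer than four leaves have empty bipartition sets (RF 0 by
convention is not defined — callers restrict first); consensus at
threshold 1.0 keeps splits present in *every* tree (strict ">" would keep
nothing); equal-count ICA ties report positive magnitude; quartet-score
ties during hill-climbing break on canonical Newick order; the
`distant_reticulation` helper breaks ties lexicographically. Parse errors
name the character offset where one is known (unbalanced parentheses,
duplicate labels, negative lengths).
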