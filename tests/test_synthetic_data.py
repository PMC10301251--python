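"""Species-tree sampling, MSC/network simulation, noise, fixture bundles."""

import json
import math
from collections import Counter

import pytest
from scipy import stats

from phylodiscord.treecore import (
    Tree,
    TreeError,
    induced_topology,
    parse_newick,
    rf_distance,
    write_newick,
)
from phylodiscord.synthetic_data import (
    NetworkModel,
    Reticulation,
    SimConfig,
    SpeciesTreeModel,
    attach_outgroup,
    displayed_tree,
    distant_reticulation,
    generate_dataset,
    model_from_manifest,
    perturb_gene_trees,
    sample_yule_species_tree,
    simulate_msc_gene_trees,
    simulate_network_gene_trees,
)
from phylodiscord.ils_test import normalized_rf_values


def triple_frequency(trees, pair, triple):
    resolved = conc = 0
    for g in trees:
        got = induced_topology(g, triple, rooted=True)
        if got is not None:
            resolved += 1
            conc += got == pair
    return conc / resolved


class TestYuleSpeciesTree:
    def test_three_taxa_single_shape(self):
        m = sample_yule_species_tree(3, 1.0, seed=1)
        assert m.tree.n_leaves() == 3
        assert m.tree.is_rooted and m.tree.is_binary()

    def test_deterministic(self):
        a = sample_yule_species_tree(10, 0.8, seed=42)
        b = sample_yule_species_tree(10, 0.8, seed=42)
        assert write_newick(a.tree) == write_newick(b.tree)

    def test_internal_length_mean_matches_exponential(self):
        lengths = []
        for seed in range(400):
            m = sample_yule_species_tree(12, 1.5, seed=seed)
            lengths += [
                n.length
                for n in m.tree.nodes()
                if not n.is_leaf and n is not m.tree.root
            ]
        mean = sum(lengths) / len(lengths)
        se = 1.5 / math.sqrt(len(lengths))  # exponential: sd == mean
        assert abs(mean - 1.5) < 3 * se

    def test_too_few_taxa(self):
        with pytest.raises(TreeError):
            sample_yule_species_tree(2, 1.0, seed=0)


class TestMscSimulation:
    def test_star_tree_uniform_topologies(self):
        model = SpeciesTreeModel(parse_newick("((A:1,B:1):0.0,C:1);"))
        trees = simulate_msc_gene_trees(model, 30000, seed=2)
        freqs = Counter(induced_topology(g, "ABC", rooted=True) for g in trees)
        for pair in (frozenset("AB"), frozenset("AC"), frozenset("BC")):
            assert abs(freqs[pair] / 30000 - 1 / 3) < 3 * math.sqrt((1 / 3) * (2 / 3) / 30000)

    def test_triple_law_at_one_coalescent_unit(self):
        model = SpeciesTreeModel(parse_newick("((A:1,B:1):1.0,C:2);"))
        trees = simulate_msc_gene_trees(model, 20000, seed=3)
        expected = 1 - (2 / 3) * math.exp(-1)
        freq = triple_frequency(trees, frozenset("AB"), "ABC")
        assert abs(freq - expected) < 3 * math.sqrt(expected * (1 - expected) / 20000)

    @pytest.mark.parametrize("t,seed", [(0.5, 4), (2.0, 5)])
    def test_triple_law_other_lengths(self, t, seed):
        model = SpeciesTreeModel(parse_newick(f"((A:1,B:1):{t},C:2);"))
        trees = simulate_msc_gene_trees(model, 20000, seed=seed)
        expected = 1 - (2 / 3) * math.exp(-t)
        freq = triple_frequency(trees, frozenset("AB"), "ABC")
        assert abs(freq - expected) < 3 * math.sqrt(expected * (1 - expected) / 20000)

    def test_long_branch_limit_concordant(self):
        model = SpeciesTreeModel(parse_newick("((A:1,B:1):50,C:51);"))
        trees = simulate_msc_gene_trees(model, 2000, seed=6)
        assert triple_frequency(trees, frozenset("AB"), "ABC") == 1.0

    def test_deterministic_and_rooted_binary(self):
        model = sample_yule_species_tree(8, 1.0, seed=7)
        a = simulate_msc_gene_trees(model, 20, seed=8)
        b = simulate_msc_gene_trees(model, 20, seed=8)
        assert [write_newick(t) for t in a] == [write_newick(t) for t in b]
        assert all(t.is_rooted and t.is_binary() and t.taxa == model.taxa for t in a)

    def test_relabelling_exchangeability_in_distribution(self):
        """Permuting taxon labels permutes the simulated distribution: the
        discordance summary (normalized RF to the own species tree) is
        unchanged in law."""
        nwk = "(((A:1,B:1):0.7,C:1.7):0.9,(D:1,E:1):1.6);"
        perm = dict(zip("ABCDE", "EDCBA"))
        model = SpeciesTreeModel(parse_newick(nwk))
        model_perm = SpeciesTreeModel(
            parse_newick("".join(perm.get(ch, ch) for ch in nwk))
        )
        rf_a, _ = normalized_rf_values(
            model.tree, simulate_msc_gene_trees(model, 4000, seed=9)
        )
        rf_b, _ = normalized_rf_values(
            model_perm.tree, simulate_msc_gene_trees(model_perm, 4000, seed=10)
        )
        assert stats.ks_2samp(rf_a, rf_b).pvalue > 0.01


class TestNetworkSimulation:
    BASE = "(((A:1,B:1):1,(C:1,D:1):1):1,(E:1,F:1):2);"

    def base(self):
        return SpeciesTreeModel(parse_newick(self.BASE))

    def test_gamma_zero_matches_msc_in_law(self):
        base = self.base()
        net = NetworkModel(base, (Reticulation(frozenset("A"), frozenset("EF"), 0.0, 0.1),))
        net_trees, labels = simulate_network_gene_trees(net, 2000, seed=10)
        msc_trees = simulate_msc_gene_trees(base, 2000, seed=11)
        assert all(lab == ("major",) for lab in labels)
        rf_net, _ = normalized_rf_values(base.tree, net_trees)
        rf_msc, _ = normalized_rf_values(base.tree, msc_trees)
        assert stats.ks_2samp(rf_net, rf_msc).pvalue > 0.01

    def test_gamma_one_matches_minor_displayed_tree_in_law(self):
        base = self.base()
        net = NetworkModel(base, (Reticulation(frozenset("A"), frozenset("EF"), 1.0, 0.1),))
        minor = displayed_tree(net, (True,))
        net_trees, labels = simulate_network_gene_trees(net, 2000, seed=12)
        msc_trees = simulate_msc_gene_trees(minor, 2000, seed=13)
        assert all(lab == ("minor",) for lab in labels)
        rf_net, _ = normalized_rf_values(minor.tree, net_trees)
        rf_msc, _ = normalized_rf_values(minor.tree, msc_trees)
        assert stats.ks_2samp(rf_net, rf_msc).pvalue > 0.01

    def test_minor_fraction_binomial(self):
        net = NetworkModel(
            self.base(), (Reticulation(frozenset("A"), frozenset("EF"), 0.45, 0.1),)
        )
        _, labels = simulate_network_gene_trees(net, 10000, seed=14)
        frac = sum(lab == ("minor",) for lab in labels) / 10000
        assert abs(frac - 0.45) <= 0.015

    def test_displayed_tree_regraft(self):
        net = NetworkModel(
            self.base(), (Reticulation(frozenset("A"), frozenset("EF"), 0.5, 0.25),)
        )
        minor = displayed_tree(net, (True,))
        assert rf_distance(
            minor.tree, parse_newick("((B,(C,D)),(A,(E,F)));")
        ) == 0
        regrafted = next(
            n for n in minor.tree.nodes() if n.is_leaf and n.label == "A"
        )
        assert regrafted.length == 0.25

    def test_overlapping_clades_rejected(self):
        with pytest.raises(TreeError):
            NetworkModel(
                self.base(),
                (Reticulation(frozenset("AB"), frozenset("BC"), 0.5, 0.1),),
            )

    def test_distant_reticulation_moves_far_and_respects_exclusions(self):
        model = attach_outgroup(sample_yule_species_tree(8, 1.5, seed=15), "OUT")
        net = distant_reticulation(model, gamma=0.5, tau=0.1, exclude=["OUT"])
        assert "OUT" not in net.reticulations[0].recipient | net.reticulations[0].donor
        displaced = displayed_tree(net, (True,))
        assert rf_distance(model.tree, displaced.tree) >= 6  # moved across >= 3 splits


class TestPerturbation:
    def test_no_noise_preserves_topology_with_high_support(self):
        model = sample_yule_species_tree(8, 1.0, seed=16)
        out = perturb_gene_trees([model.tree] * 20, SimConfig(seed=17, nni_noise_prob=0.0))
        for t in out:
            assert rf_distance(t, model.tree) == 0
            assert all(
                n.support >= 80 for n in t.nodes() if not n.is_leaf and n is not t.root
            )

    def test_quartet_changes_two_thirds_of_the_time(self):
        base = SpeciesTreeModel(parse_newick("((A:1,B:1):1,(C:1,D:1):1);"))
        out = perturb_gene_trees([base.tree] * 3000, SimConfig(seed=18, nni_noise_prob=1.0))
        changed = sum(rf_distance(base.tree, t) > 0 for t in out)
        assert abs(changed / 3000 - 2 / 3) < 3 * math.sqrt((2 / 3) * (1 / 3) / 3000)

    def test_expected_rf_monotone_in_noise(self):
        model = sample_yule_species_tree(8, 1.0, seed=19)
        means = []
        for i, p in enumerate((0.0, 0.05, 0.2)):
            out = perturb_gene_trees(
                [model.tree] * 500, SimConfig(seed=20 + i, nni_noise_prob=p)
            )
            means.append(sum(rf_distance(model.tree, t) for t in out) / 500)
        assert means[0] < means[1] < means[2]

    def test_perturbed_edges_get_low_support(self):
        model = sample_yule_species_tree(6, 1.0, seed=21)
        out = perturb_gene_trees([model.tree] * 100, SimConfig(seed=22, nni_noise_prob=1.0))
        lows = [
            n.support
            for t in out
            for n in t.nodes()
            if not n.is_leaf and n is not t.root and n.support is not None and n.support < 50
        ]
        assert lows  # the low-support band is exercised

    def test_missing_taxa_keeps_at_least_four(self):
        model = sample_yule_species_tree(6, 1.0, seed=23)
        out = perturb_gene_trees(
            [model.tree] * 200, SimConfig(seed=24, missing_prob=0.4)
        )
        sizes = [t.n_leaves() for t in out]
        assert min(sizes) >= 4
        assert any(s < 6 for s in sizes)


class TestGenerateDataset:
    def test_bundle_contents_and_replay(self, tmp_path):
        model = attach_outgroup(sample_yule_species_tree(8, 1.2, seed=25), "OUT")
        net = distant_reticulation(model, gamma=0.5, tau=0.1, exclude=["OUT"])
        cfg = SimConfig(seed=26, n_genes=120, nni_noise_prob=0.05)
        manifest = generate_dataset(net, cfg, tmp_path / "a")
        lines = (tmp_path / "a" / "gene_trees.nwk").read_text().strip().splitlines()
        assert len(lines) == 120
        assert (tmp_path / "a" / "true_network.txt").exists()
        assert len(manifest["gene_parent_labels"]) == 120

        # replaying the manifest reproduces the bundle byte for byte
        replay_model = model_from_manifest(manifest)
        cfg2 = SimConfig(
            seed=manifest["seed"],
            n_genes=manifest["n_genes"],
            nni_noise_prob=manifest["nni_noise_prob"],
            missing_prob=manifest["missing_prob"],
        )
        generate_dataset(replay_model, cfg2, tmp_path / "b")
        for name in ("gene_trees.nwk", "true_species_tree.nwk", "manifest.json", "true_network.txt"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_msc_bundle_has_no_network_file(self, tmp_path):
        model = sample_yule_species_tree(9, 1.0, seed=27)
        generate_dataset(model, SimConfig(seed=28, n_genes=10), tmp_path)
        assert not (tmp_path / "true_network.txt").exists()
        manifest = json.loads((tmp_path / "manifest.json").read_text())
        assert manifest["reticulations"] == []
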