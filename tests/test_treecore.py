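"""Tree model, Newick round-trips, bipartitions, RF, restriction, consensus."""

import random
import string

import pytest

from phylodiscord.treecore import (
    Bipartition,
    NewickParseError,
    Tree,
    TreeError,
    bipartition_set,
    bipartition_supports,
    induced_topology,
    majority_consensus,
    parse_newick,
    reroot,
    restrict_to_taxa,
    rf_distance,
    write_newick,
)

from conftest import brute_force_rf, random_binary_tree


class TestParseNewick:
    def test_minimal_unrooted_quartet(self):
        t = parse_newick("(A,B,(C,D));")
        assert t.taxa == frozenset("ABCD")
        assert not t.is_rooted
        assert len(bipartition_set(t)) == 1

    def test_supports_and_lengths_read(self):
        t = parse_newick("((A:1,B:1)95:0.5,C:2);")
        cherry = next(n for n in t.nodes() if not n.is_leaf and n is not t.root)
        assert cherry.support == 95
        assert cherry.length == 0.5
        assert t.is_rooted

    def test_non_numeric_internal_label_kept(self):
        t = parse_newick("((A,B)cladeX,C);")
        cherry = next(n for n in t.nodes() if not n.is_leaf and n is not t.root)
        assert cherry.support is None
        assert cherry.label == "cladeX"

    def test_support_out_of_range_is_label(self):
        t = parse_newick("((A,B)250,C);")
        cherry = next(n for n in t.nodes() if not n.is_leaf and n is not t.root)
        assert cherry.support is None

    @pytest.mark.parametrize(
        "bad",
        ["((A,B);", "(A,B))C;", "(A,B)", "((A,B),(A,C));", "(A:-1,B:2);", "(A,,B);"],
    )
    def test_malformed_input_raises(self, bad):
        with pytest.raises(NewickParseError):
            parse_newick(bad)

    def test_error_carries_offset(self):
        with pytest.raises(NewickParseError, match="offset"):
            parse_newick("((A,B);")

    def test_comment_support_convention(self):
        t = parse_newick("((A,B)[85],C);", support_convention="comment")
        cherry = next(n for n in t.nodes() if not n.is_leaf and n is not t.root)
        assert cherry.support == 85


class TestWriteNewick:
    def test_canonical_child_order(self):
        assert write_newick(parse_newick("((C,D),A,B);")) == "(A,B,(C,D));"

    def test_lengths_six_significant_digits(self):
        t = parse_newick("(A:0.123456789,B:2);")
        assert write_newick(t) == "(A:0.123457,B:2);"

    def test_round_trip_property(self):
        from hypothesis import given, settings, strategies as st

        @settings(max_examples=40, deadline=None, derandomize=True)
        @given(data=st.data())
        def run(data):
            n = data.draw(st.integers(4, 15))
            labels = data.draw(
                st.lists(
                    st.text("abcdefghijklmnopqrstuvwxyz", min_size=1, max_size=6),
                    min_size=n,
                    max_size=n,
                    unique=True,
                )
            )
            rnd = random.Random(data.draw(st.integers(0, 2**20)))
            t = random_binary_tree(rnd, labels, with_lengths=True, with_supports=True)
            back = parse_newick(write_newick(t))
            assert bipartition_set(back) == bipartition_set(t)
            assert write_newick(back) == write_newick(t)

        run()

    def test_round_trip_random_trees(self, rng):
        for _ in range(100):
            n = rng.randint(4, 26)
            labels = [f"t{i}" for i in range(n)]
            t = random_binary_tree(rng, labels, with_lengths=True, with_supports=True)
            back = parse_newick(write_newick(t))
            assert bipartition_set(back) == bipartition_set(t)
            assert write_newick(back) == write_newick(t)
            assert bipartition_supports(back) == bipartition_supports(t)


class TestBipartitions:
    def test_quartet_single_split(self):
        (bip,) = bipartition_set(parse_newick("(A,B,(C,D));"))
        assert {bip.block, bip.other} == {frozenset("AB"), frozenset("CD")}

    def test_balanced_eight_taxon_count(self):
        t = parse_newick("(((A,B),(C,D)),((E,F),(G,H)));")
        assert len(bipartition_set(t)) == 5  # n - 3

    def test_support_filter(self):
        assert bipartition_set(parse_newick("(A,B,(C,D)40);"), min_support=50) == set()
        assert len(bipartition_set(parse_newick("(A,B,(C,D)60);"), min_support=50)) == 1

    def test_fewer_than_four_leaves_empty(self):
        assert bipartition_set(parse_newick("((A,B),C);")) == set()

    def test_canonical_orientation(self):
        taxa = frozenset("ABCD")
        assert Bipartition.make(frozenset("CD"), taxa) == Bipartition.make(frozenset("AB"), taxa)

    def test_compatibility(self):
        taxa = frozenset("ABCDE")
        ab = Bipartition.make(frozenset("AB"), taxa)
        cd = Bipartition.make(frozenset("CD"), taxa)
        ac = Bipartition.make(frozenset("AC"), taxa)
        assert ab.compatible(cd)
        assert not ab.compatible(ac)


class TestRfDistance:
    def test_identity_is_zero(self):
        t = parse_newick("((A,B),C,(D,E));")
        assert rf_distance(t, t) == 0

    def test_single_conflicting_split(self):
        t1 = parse_newick("((A,B),C,(D,E));")
        t2 = parse_newick("((A,C),B,(D,E));")
        assert rf_distance(t1, t2) == 2

    def test_unequal_taxa_error_names_taxa(self):
        t1 = parse_newick("((A,B),(C,D));")
        t2 = parse_newick("((A,B),(C,E));")
        with pytest.raises(TreeError, match="[DE]"):
            rf_distance(t1, t2)

    def test_brute_force_oracle_random_pairs(self, rng):
        labels = list(string.ascii_uppercase[:8])
        for _ in range(200):
            t1 = random_binary_tree(rng, labels)
            t2 = random_binary_tree(rng, labels)
            assert rf_distance(t1, t2) == brute_force_rf(t1, t2)


class TestRestrictToTaxa:
    def test_caterpillar_to_pair(self):
        t = parse_newick("((((A,B),C),D),E);")
        sub = restrict_to_taxa(t, ["A", "B"])
        assert sub.taxa == frozenset("AB")
        assert sub.n_leaves() == 2

    def test_manual_pruning_oracle(self):
        t = parse_newick("((A,B),(C,D),(E,F));")
        sub = restrict_to_taxa(t, "ACEF")
        assert bipartition_set(sub) == bipartition_set(parse_newick("(A,C,(E,F));"))

    def test_full_set_is_identity(self):
        t = parse_newick("((A:1,B:2)90:3,(C:4,D:5)80:6);")
        assert write_newick(restrict_to_taxa(t, t.taxa)) == write_newick(t)

    def test_lengths_sum_and_min_support_kept(self):
        t = parse_newick("(((A:1,B:1)90:2,C:1)40:3,(D:1,E:1):1);")
        sub = restrict_to_taxa(t, "ABDE")
        # the C-bearing node is suppressed: its length joins the AB edge,
        # and the weaker of the merged supports survives
        ab_edge = next(
            n for n in sub.nodes() if not n.is_leaf and n.leaf_labels() == frozenset("AB")
        )
        assert ab_edge.length == pytest.approx(5.0)
        assert ab_edge.support == 40

    def test_unknown_taxa_error(self):
        with pytest.raises(TreeError):
            restrict_to_taxa(parse_newick("((A,B),C);"), ["A", "Z"])


class TestInducedTopology:
    def test_rooted_triple(self):
        assert induced_topology(parse_newick("((A,B),C);"), "ABC", rooted=True) == frozenset("AB")

    def test_quartet_via_restriction(self):
        t = parse_newick("(A,B,(C,(D,E)));")
        assert induced_topology(t, "ABDE") == frozenset("AB")

    def test_star_unresolved(self):
        assert induced_topology(parse_newick("(A,B,C,D);"), "ABCD") is None
        assert induced_topology(parse_newick("((A,B,C),D);"), "ABC", rooted=True) is None

    def test_rooted_mode_requires_rooted_tree(self):
        with pytest.raises(TreeError):
            induced_topology(parse_newick("(A,B,C);"), "ABC", rooted=True)

    def test_commutes_with_restriction(self, rng):
        labels = list(string.ascii_uppercase[:10])
        for _ in range(50):
            t = random_binary_tree(rng, labels)
            quartet = rng.sample(labels, 4)
            direct = induced_topology(t, quartet)
            via_restrict = next(iter(bipartition_set(restrict_to_taxa(t, quartet)))).block
            assert direct in (via_restrict, frozenset(quartet) - via_restrict)


class TestMajorityConsensus:
    def test_identical_trees(self):
        t = parse_newick("((A,B),(C,(D,E)));")
        cons = majority_consensus([t.copy() for _ in range(40)])
        assert bipartition_set(cons) == bipartition_set(t)
        assert all(
            n.support == 100 for n in cons.nodes() if not n.is_leaf and n is not cons.root
        )

    def test_three_to_one_majority(self):
        t1 = parse_newick("((A,B),C,(D,E));")
        t2 = parse_newick("((A,C),B,(D,E));")
        cons = majority_consensus([t1, t1, t1, t2], threshold=0.5)
        blocks = {b.block for b in bipartition_set(cons)} | {
            b.other for b in bipartition_set(cons)
        }
        assert frozenset("AB") in blocks
        assert frozenset("AC") not in blocks
        split_node = next(
            n
            for n in cons.nodes()
            if not n.is_leaf and n.leaf_labels() in (frozenset("AB"), frozenset("CDE"))
        )
        assert split_node.support == 75

    def test_total_disagreement_gives_star(self):
        t1 = parse_newick("((A,B),(C,D),E);")
        t2 = parse_newick("((A,C),(B,D),E);")
        assert bipartition_set(majority_consensus([t1, t2])) == set()

    def test_idempotent_on_binary_tree(self, rng):
        t = random_binary_tree(rng, list("ABCDEFG"))
        assert bipartition_set(majority_consensus([t])) == bipartition_set(t)

    def test_mixed_taxa_error(self):
        with pytest.raises(TreeError):
            majority_consensus([parse_newick("((A,B),(C,D));"), parse_newick("((A,B),(C,E));")])


class TestReroot:
    def test_outgroup_separated(self):
        t = reroot(parse_newick("(A,B,(C,D));"), "A")
        assert t.is_rooted
        sides = {c.leaf_labels() for c in t.root.children}
        assert frozenset("A") in sides

    def test_bipartitions_invariant_for_every_leaf(self):
        t = parse_newick("(A,B,(C,(D,E)));")
        for leaf in sorted(t.taxa):
            assert rf_distance(t, reroot(t, leaf)) == 0

    def test_idempotent(self):
        t = parse_newick("(A,B,(C,(D,E)));")
        once = reroot(t, "C")
        twice = reroot(once, "C")
        assert write_newick(once) == write_newick(twice)

    def test_unknown_outgroup(self):
        with pytest.raises(TreeError):
            reroot(parse_newick("((A,B),C);"), "Z")
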