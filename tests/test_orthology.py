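"""Gene-tree event labelling, orthology verdicts and the presence matrix."""

import pytest

from hypoxiscan import orthology as orth
from hypoxiscan.simulate import (
    simulate_gene_family,
    true_verdict,
    truth_events_by_leafset,
)

SPECIES_MAP = {
    "human": "Bilateria",
    "mouse": "Bilateria",
    "sponge": "Demospongiae",
    "cteno": "Ctenophora",
    "choano": "Choanoflagellata",
}


def _labelled(newick, species_map=SPECIES_MAP):
    tree = orth.read_newick(newick)
    return orth.label_events_species_overlap(tree, species_map)


class TestReadNewick:
    def test_two_leaf_tree(self):
        tree = orth.read_newick("(A|1,B|2);")
        assert sorted(l.taxon.label for l in tree.leaf_node_iter()) == [
            "A|1",
            "B|2",
        ]

    def test_internal_support_parsed(self):
        tree = orth.read_newick("((A|1,B|1)95,C|1);")
        supports = [
            n.support
            for n in tree.preorder_internal_node_iter()
            if n.support is not None
        ]
        assert supports == [95.0]

    def test_roundtrip_topology_and_labels(self):
        nwk = "((human|a:0.1,mouse|b:0.2):0.3,sponge|c:0.5);"
        tree = orth.read_newick(nwk)
        again = orth.read_newick(orth.write_newick(tree))
        assert {l.taxon.label for l in again.leaf_node_iter()} == {
            "human|a",
            "mouse|b",
            "sponge|c",
        }
        # same nesting: the cherry is preserved
        cherry = [
            frozenset(l.taxon.label for l in n.leaf_iter())
            for n in again.preorder_internal_node_iter()
        ]
        assert frozenset({"human|a", "mouse|b"}) in cherry

    def test_unbalanced_parentheses_rejected(self):
        with pytest.raises(Exception):
            orth.read_newick("((A|1,B|2;")

    def test_out_of_range_support_rejected(self):
        with pytest.raises(ValueError):
            orth.read_newick("((A|1,B|1)150,C|1);")


class TestEventLabelling:
    def test_cross_species_cherry_is_speciation(self):
        tree = _labelled("(human|a,mouse|b);")
        assert tree.seed_node.event == "speciation"

    def test_same_species_cherry_is_duplication(self):
        tree = _labelled("(human|a,human|b);")
        assert tree.seed_node.event == "duplication"

    def test_unmapped_species_names_leaf(self):
        with pytest.raises(ValueError, match="alien"):
            _labelled("(alien|x,human|a);")

    def test_loss_free_simulations_label_every_node_exactly(
        self, species_tree
    ):
        for seed in range(40):
            fam = simulate_gene_family(species_tree, 0.15, 0.0, seed=seed)
            tree = orth.read_newick(fam.newick)
            orth.label_events_species_overlap(tree, species_tree.clades)
            truth = truth_events_by_leafset(fam)
            for node in tree.preorder_internal_node_iter():
                leafset = frozenset(
                    l.taxon.label for l in node.leaf_iter()
                )
                assert node.event == truth[leafset]

    def test_with_losses_labelled_duplications_subset_of_truth(
        self, families_with_duplications, species_tree
    ):
        # species overlap can miss duplications (when losses hide the
        # overlap) but never invent them
        for fam in families_with_duplications:
            if fam.extinct or len(fam.genes()) < 2:
                continue
            tree = orth.read_newick(fam.newick)
            orth.label_events_species_overlap(tree, species_tree.clades)
            truth = truth_events_by_leafset(fam)
            for node in tree.preorder_internal_node_iter():
                leafset = frozenset(
                    l.taxon.label for l in node.leaf_iter()
                )
                if node.event == "duplication":
                    assert truth[leafset] == "duplication"


class TestClassifyRelation:
    def test_two_leaf_one_to_one(self):
        tree = _labelled("(human|x,sponge|y);")
        assert (
            orth.classify_relation(tree, "human|x", "sponge")
            == "ortholog_1to1"
        )

    def test_hsn_sister_position_is_homolog(self):
        # sponge and ctenophore genes sister to the duplicated
        # HIF-SIM-NPAS block: homolog, not ortholog
        tree = _labelled(
            "((sponge|s1,cteno|c1),((human|HIF1A,human|SIM1),human|NPAS3));"
        )
        assert orth.classify_relation(tree, "human|HIF1A", "sponge") == "homolog"
        assert orth.classify_relation(tree, "human|HIF1A", "cteno") == "homolog"

    def test_one_to_many_for_target_side_duplication(self):
        tree = _labelled("((sponge|s1,sponge|s2),human|h1);")
        assert (
            orth.classify_relation(tree, "human|h1", "sponge")
            == "ortholog_1tomany"
        )

    def test_species_absent_from_tree(self):
        tree = _labelled("(human|x,sponge|y);")
        assert orth.classify_relation(tree, "human|x", "cteno") == "absent"

    def test_missing_reference_rejected(self):
        tree = _labelled("(human|x,sponge|y);")
        with pytest.raises(ValueError):
            orth.classify_relation(tree, "human|zzz", "sponge")

    def test_one_to_one_is_symmetric(self, families_with_duplications):
        for fam in families_with_duplications[:20]:
            if fam.extinct:
                continue
            genes = fam.genes()
            humans = [g for g in genes if g.startswith("human|")]
            tethyas = [g for g in genes if g.startswith("tethya|")]
            if not humans or not tethyas:
                continue
            tree = orth.read_newick(fam.newick)
            orth.label_events_species_overlap(
                tree, {g.split("|")[0]: "x" for g in genes}
            )
            if (
                orth.classify_relation(tree, humans[0], "tethya")
                == "ortholog_1to1"
            ):
                assert (
                    orth.classify_relation(tree, tethyas[0], "human")
                    == "ortholog_1to1"
                )

    def test_verdicts_match_truth_replay(
        self, families_with_duplications, species_tree
    ):
        checked = 0
        for fam in families_with_duplications:
            if fam.extinct or len(fam.genes()) < 2:
                continue
            refs = [g for g in fam.genes() if g.startswith("human|")]
            if not refs:
                continue
            tree = orth.read_newick(fam.newick)
            orth.label_events_species_overlap(tree, species_tree.clades)
            for sp in species_tree.species:
                if sp == "human":
                    continue
                assert orth.classify_relation(
                    tree, refs[0], sp
                ) == true_verdict(fam, refs[0], sp)
                checked += 1
        assert checked > 100


class TestSecondaryLossAndFlags:
    CONTEXT = {
        ("EGL9", "Demospongiae"): "absent",
        ("EGL9", "Ctenophora"): "absent",
        ("EGL9", "Bilateria"): "ortholog_1to1",
        ("EGL9", "Choanoflagellata"): "homolog",
        ("EGL9", "Capsaspora"): "absent",
    }

    def test_absent_with_outgroup_presence_upgrades(self):
        for clade in ("Demospongiae", "Ctenophora"):
            assert (
                orth.call_secondary_loss(
                    "EGL9", clade, self.CONTEXT,
                    ("Choanoflagellata", "Capsaspora"),
                )
                == "secondary_loss"
            )

    def test_absent_everywhere_stays_absent(self):
        ctx = {(k): "absent" for k in self.CONTEXT}
        assert (
            orth.call_secondary_loss(
                "EGL9", "Demospongiae", ctx, ("Choanoflagellata",)
            )
            == "absent"
        )

    def test_presence_only_inside_metazoa_not_secondary_loss(self):
        ctx = dict(self.CONTEXT)
        ctx[("EGL9", "Choanoflagellata")] = "absent"
        assert (
            orth.call_secondary_loss(
                "EGL9", "Ctenophora", ctx,
                ("Choanoflagellata", "Capsaspora"),
            )
            == "absent"
        )

    def test_no_outgroups_configured_rejected(self):
        with pytest.raises(ValueError):
            orth.call_secondary_loss("EGL9", "Ctenophora", self.CONTEXT, ())

    def test_lineage_duplication_flag(self):
        tree = _labelled("(((human|a,human|b),human|c),sponge|s);")
        assert orth.flag_lineage_duplications(tree, SPECIES_MAP, "Bilateria")
        assert not orth.flag_lineage_duplications(
            tree, SPECIES_MAP, "Demospongiae"
        )

    def test_single_copy_clade_unflagged(self):
        tree = _labelled("(human|a,sponge|s);")
        assert not orth.flag_lineage_duplications(
            tree, SPECIES_MAP, "Bilateria"
        )

    def test_flag_matches_truth_duplication_count(
        self, families_with_duplications, species_tree
    ):
        for fam in families_with_duplications:
            if fam.extinct or len(fam.genes()) < 2:
                continue
            tree = orth.read_newick(fam.newick)
            orth.label_events_species_overlap(tree, species_tree.clades)
            truth = truth_events_by_leafset(fam)
            for clade in ("Bilateria", "Demospongiae", "Ctenophora"):
                members = set(species_tree.clade_members(clade))
                n_true = sum(
                    1
                    for leafset, ev in truth.items()
                    if ev == "duplication"
                    and {l.split("|")[0] for l in leafset} <= members
                )
                assert orth.flag_lineage_duplications(
                    tree, species_tree.clades, clade
                ) == (n_true >= 2)


class TestMatrix:
    CALLS = [
        orth.OrthologyCall("HIFa", "Bilateria", "ortholog_1to1"),
        orth.OrthologyCall("HIFa", "Ctenophora", "homolog"),
        orth.OrthologyCall("ARNT", "Bilateria", "ortholog_1to1", True),
        orth.OrthologyCall("ARNT", "Ctenophora", "ortholog_1tomany"),
    ]

    def test_all_cells_filled(self):
        m = orth.build_matrix(self.CALLS)
        assert m.shape == (2, 2)
        assert m.loc["ARNT", "Bilateria"] == "ortholog_1to1+M"

    def test_missing_pair_listed(self):
        with pytest.raises(ValueError, match="ARNT"):
            orth.build_matrix(self.CALLS[:3])

    def test_tsv_roundtrip_identity(self, tmp_path):
        m = orth.build_matrix(self.CALLS)
        p = tmp_path / "matrix.tsv"
        orth.write_matrix_tsv(m, p)
        again = orth.read_matrix_tsv(p)
        assert again.equals(m)

    def test_unknown_verdict_rejected(self):
        with pytest.raises(ValueError):
            orth.OrthologyCall("X", "Y", "maybe")
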