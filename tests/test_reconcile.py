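import numpy as np
import pytest

from paleologs import (
    GeneTree,
    SpeciesTree,
    classify_branch_epochs,
    extract_one_to_one_orthologs,
    map_genes_to_species,
    reconcile,
    simulate_gene_family,
    split_aogs,
)
from paleologs.reconcile import (
    DUPLICATION,
    EPOCH_OTHER,
    EPOCH_POST_DB,
    EPOCH_POST_SB,
    EPOCH_PRE_DB,
    LINEAGE_SPECIFIC,
    SPECIATION,
    assign_wgd,
)
from paleologs.treedata import node_name

from tests._oracles import SpeciesTreeTable, enumerate_topologies, min_dl_cost
from tests.conftest import reconcile_newick


class TestLcaMapping:
    def test_cherry_maps_to_species_root(self, two_species_tree):
        rec = reconcile_newick("(Atha_g1,Orsa_g1);", two_species_tree)
        root_image = rec.image_name(rec.gene_tree.root)
        assert root_image == "Root"
        assert rec.n_duplications == 0 and rec.n_losses == 0

    def test_double_cherry_all_internals_map_to_root(self, two_species_tree):
        rec = reconcile_newick(
            "((Atha_g1,Orsa_g1),(Atha_g2,Orsa_g2));", two_species_tree
        )
        internals = [n for n in rec.mapping if not n.is_leaf()]
        assert all(rec.image_name(n) == "Root" for n in internals)
        # root duplicates (image equals both children's), cherries speciate
        assert rec.events[rec.gene_tree.root] == DUPLICATION
        assert rec.n_duplications == 1
        assert sum(1 for e in rec.events.values() if e == SPECIATION) == 2

    def test_single_leaf_maps_to_its_species(self, two_species_tree):
        rec = reconcile_newick("Atha_only;", two_species_tree)
        (leaf,) = rec.gene_tree.leaves()
        assert rec.image_name(leaf) == "Atha"

    def test_within_species_duplication(self, two_species_tree):
        rec = reconcile_newick("(Atha_g1,Atha_g2);", two_species_tree)
        assert rec.events[rec.gene_tree.root] == DUPLICATION
        assert rec.image_name(rec.gene_tree.root) == "Atha"

    def test_unknown_species_rejected(self, two_species_tree):
        gt = GeneTree.from_newick("(Atha_g1,Orsa_g1);")
        with pytest.raises(KeyError, match="Zzma"):
            reconcile(gt, two_species_tree, {"Atha_g1": "Zzma", "Orsa_g1": "Orsa"})


class TestLossCounting:
    def test_unbalanced_cherry_one_dup_one_loss(self, two_species_tree):
        rec = reconcile_newick("(Atha_g1,(Atha_g2,Orsa_g1));", two_species_tree)
        assert rec.n_duplications == 1
        assert rec.n_losses == 1

    def test_congruent_tree_no_losses(self, three_species_tree):
        rec = reconcile_newick("(Atha_g1,(Orsa_g1,Zzma_g1));", three_species_tree)
        assert rec.n_duplications == 0 and rec.n_losses == 0

    def test_three_species_case_matches_oracle(self, three_species_tree):
        rec = reconcile_newick("((Atha_g1,Orsa_g1),Atha_g2);", three_species_tree)
        table = SpeciesTreeTable(("Atha", ("Orsa", "Zzma")))
        expected = min_dl_cost(
            (("a1", "o1"), "a2"),
            {"a1": "Atha", "o1": "Orsa", "a2": "Atha"},
            table,
        )
        assert rec.cost == expected

    def test_monotonicity_on_simulated_families(self, angiosperm_tree, rng):
        """M(parent) is ancestral-or-equal to M(child) on random families."""
        from paleologs.reconcile import _SpeciesIndex

        idx = _SpeciesIndex(angiosperm_tree)
        for i in range(10):
            fam = simulate_gene_family(
                angiosperm_tree,
                rng,
                duplication_rate=0.1,
                loss_rate=0.1,
                wgd_retention=0.5,
                family_id=f"m{i}",
            )
            if fam.extinct:
                continue
            rec = reconcile(fam.gene_tree, angiosperm_tree, fam.gene_species_map)
            for node, image in rec.mapping.items():
                if node.parent_node is not None:
                    assert idx.is_ancestor_or_equal(
                        rec.mapping[node.parent_node], image
                    )


class TestOracleEquivalence:
    """Exhaustive-minimum reconciliation agrees with the LCA implementation.

    Full coverage up to 6 leaves runs in the acceptance suite; here a
    representative slice keeps the unit suite fast.
    """

    SPECIES = ("Atha", ("Orsa", "Zzma"))
    SPECIES_NEWICK = "(Atha,(Orsa,Zzma));"

    @pytest.mark.parametrize("n_leaves", [2, 3, 4])
    def test_all_topologies_small(self, n_leaves):
        table = SpeciesTreeTable(self.SPECIES)
        st = SpeciesTree.from_newick(self.SPECIES_NEWICK)
        species_cycle = ["Atha", "Orsa", "Zzma"]
        labels = [f"L{i}" for i in range(n_leaves)]
        assignment = {l: species_cycle[i % 3] for i, l in enumerate(labels)}
        for topo in enumerate_topologies(labels):
            if not isinstance(topo, tuple):
                continue

            def render(node):
                if isinstance(node, tuple):
                    return "(" + ",".join(render(c) for c in node) + ")"
                return f"{assignment[node]}_{node}"

            gt = GeneTree.from_newick(render(topo) + ";")
            gmap = {f"{assignment[l]}_{l}": assignment[l] for l in labels}
            rec = reconcile(gt, st, gmap)
            expected = min_dl_cost(topo, assignment, table)
            assert rec.cost == expected, f"topology {topo}"


class TestSplitAogs:
    # outgroup species Gbil sits above the Crown node
    OUTGROUP_TREE = "(Gbil,(Atha,(Orsa,Zzma)Inner)Crown)Root;"

    def make(self, newick):
        st = SpeciesTree.from_newick(self.OUTGROUP_TREE)
        rec = reconcile_newick(newick, st)
        return st, rec

    def test_pre_crown_duplication_splits_in_two(self):
        _, rec = self.make(
            "((Gbil_g1,(Atha_g1,(Orsa_g1,Zzma_g1))),(Atha_g2,(Orsa_g2,Zzma_g2)));"
        )
        aogs = split_aogs(rec, "Crown")
        assert len(aogs) == 2
        leaves = sorted(sum((a.leaf_labels() for a in aogs), []))
        assert leaves == sorted(rec.gene_tree.leaf_labels())

    def test_no_pre_crown_duplication_identity(self):
        _, rec = self.make("(Gbil_g1,(Atha_g1,(Orsa_g1,Zzma_g1)));")
        aogs = split_aogs(rec, "Crown")
        assert len(aogs) == 1
        assert sorted(aogs[0].leaf_labels()) == sorted(rec.gene_tree.leaf_labels())

    def test_nested_pre_crown_duplications_three_copies(self):
        copy = "(Atha_g{i},(Orsa_g{i},Zzma_g{i}))"
        newick = (
            "((" + copy.format(i=1) + "," + copy.format(i=2) + "),"
            + copy.format(i=3) + ");"
        )
        _, rec = self.make(newick)
        aogs = split_aogs(rec, "Crown")
        assert len(aogs) == 3

    def test_outgroup_only_subtree_discarded(self):
        # root duplication above the crown; one copy survives only in Gbil
        _, rec = self.make(
            "((Gbil_g1,(Atha_g1,(Orsa_g1,Zzma_g1))),(Gbil_g2,Gbil_g3));"
        )
        aogs = split_aogs(rec, "Crown")
        # the pure-outgroup duplicate clade is dropped
        assert len(aogs) == 1
        assert "Gbil_g2" not in aogs[0].leaf_labels()
        assert "Atha_g1" in aogs[0].leaf_labels()

    def test_split_is_idempotent(self):
        st, rec = self.make(
            "((Gbil_g1,(Atha_g1,(Orsa_g1,Zzma_g1))),(Atha_g2,(Orsa_g2,Zzma_g2)));"
        )
        for aog in split_aogs(rec, "Crown"):
            gmap = map_genes_to_species(aog, set(st.species()))
            rec2 = reconcile(aog, st, gmap)
            again = split_aogs(rec2, "Crown")
            assert len(again) == 1
            assert sorted(again[0].leaf_labels()) == sorted(aog.leaf_labels())

    def test_unknown_crown_node_rejected(self):
        _, rec = self.make("(Gbil_g1,(Atha_g1,(Orsa_g1,Zzma_g1)));")
        with pytest.raises(KeyError):
            split_aogs(rec, "NoSuchNode")


class TestWgdAssignment:
    TREE = "((Atha,Alyr)Brassicaceae,Orsa)Root;"

    def test_duplication_at_annotated_crown(self):
        st = SpeciesTree.from_newick(self.TREE, {"alpha_beta": "Brassicaceae"})
        rec = reconcile_newick("((Atha_g1,Alyr_g1),(Atha_g2,Alyr_g2));", st)
        labels = assign_wgd(rec)
        assert list(labels.values()) == ["alpha_beta"]

    def test_leaf_level_duplication_is_lineage_specific(self):
        st = SpeciesTree.from_newick(self.TREE, {"alpha_beta": "Brassicaceae"})
        rec = reconcile_newick("((Atha_g1,Atha_g2),Orsa_g1);", st)
        labels = assign_wgd(rec)
        assert list(labels.values()) == [LINEAGE_SPECIFIC]

    def test_two_independent_duplications_same_annotated_node(self):
        st = SpeciesTree.from_newick(self.TREE, {"alpha_beta": "Brassicaceae"})
        newick = (
            "(((Atha_g1,Alyr_g1),(Atha_g2,Alyr_g2)),"
            "((Atha_g3,Alyr_g3),(Atha_g4,Alyr_g4)));"
        )
        rec = reconcile_newick(newick, st)
        labels = assign_wgd(rec)
        crown_dups = [
            l for d, l in labels.items() if rec.image_name(d) == "Brassicaceae"
        ]
        assert crown_dups.count("alpha_beta") >= 2


class TestBranchEpochs:
    TREE = "((Atha,Brra)Brassicaceae,Orsa)Root;"

    def focal_setup(self, newick):
        st = SpeciesTree.from_newick(self.TREE, {"alpha_beta": "Brassicaceae"})
        rec = reconcile_newick(newick, st)
        focal = [
            d
            for d in rec.duplication_nodes
            if rec.image_name(d) == "Brassicaceae"
        ]
        return rec, focal

    def test_pair_schema(self):
        rec, focal = self.focal_setup("((Atha_g1,Brra_g1),(Atha_g2,Brra_g2));")
        labels = classify_branch_epochs(rec, focal, "Brassicaceae")
        counts = {lab: sum(1 for v in labels.values() if v == lab) for lab in set(labels.values())}
        assert counts == {EPOCH_PRE_DB: 1, EPOCH_POST_DB: 2, EPOCH_POST_SB: 4}

    def test_trio_has_three_post_db(self):
        rec, focal = self.focal_setup(
            "(((Atha_g1,Brra_g1),(Atha_g2,Brra_g2)),(Atha_g3,Brra_g3));"
        )
        assert len(focal) == 2
        labels = classify_branch_epochs(rec, focal, "Brassicaceae")
        assert sum(1 for v in labels.values() if v == EPOCH_POST_DB) == 3
        assert sum(1 for v in labels.values() if v == EPOCH_POST_SB) == 6

    def test_no_focal_duplication_all_other(self):
        rec, focal = self.focal_setup("(Atha_g1,Brra_g1);")
        assert focal == []
        labels = classify_branch_epochs(rec, focal, "Brassicaceae")
        assert set(labels.values()) == {EPOCH_OTHER}

    def test_non_duplication_focal_rejected(self):
        rec, _ = self.focal_setup("(Atha_g1,Brra_g1);")
        with pytest.raises(ValueError):
            classify_branch_epochs(rec, [rec.gene_tree.root], "Brassicaceae")

    def test_labels_partition_all_branches(self):
        rec, focal = self.focal_setup(
            "((((Atha_g1,Atha_g2),Brra_g1),(Atha_g3,Brra_g3)),Orsa_g1);"
        )
        labels = classify_branch_epochs(rec, focal, "Brassicaceae")
        all_nodes = list(rec.gene_tree.tree.preorder_node_iter())
        assert set(labels) == set(all_nodes)


class TestOneToOneOrthologs:
    def test_simple_cherry(self, two_species_tree):
        rec = reconcile_newick("(Atha_g1,Orsa_g1);", two_species_tree)
        assert extract_one_to_one_orthologs(rec, "Atha", "Orsa") == [
            ("Atha_g1", "Orsa_g1")
        ]

    def test_two_copies_in_one_species_excluded(self, two_species_tree):
        rec = reconcile_newick("((Atha_g1,Atha_g2),Orsa_g1);", two_species_tree)
        assert extract_one_to_one_orthologs(rec, "Atha", "Orsa") == []

    def test_two_independent_cherries_give_two_pairs(self, two_species_tree):
        rec = reconcile_newick(
            "((Atha_g1,Orsa_g1),(Atha_g2,Orsa_g2));", two_species_tree
        )
        pairs = extract_one_to_one_orthologs(rec, "Atha", "Orsa")
        assert sorted(pairs) == [("Atha_g1", "Orsa_g1"), ("Atha_g2", "Orsa_g2")]
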