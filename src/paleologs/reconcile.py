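"""LCA reconciliation of gene trees against a species tree.

The classical lowest-common-ancestor (LCA) mapping sends every gene-tree
node to the species-tree node spanned by its descendant species.  A node
whose image coincides with a child's image is a duplication; otherwise it is
a speciation.  Implied losses along an edge follow from the species-tree
distance between the parent and child images.  The LCA reconciliation is the
(unique) one minimizing total duplication + loss cost, which the test suite
verifies against exhaustive search on small trees.

Built on the mapping are the downstream bookkeeping steps: splitting trees
at duplications predating a crown group (yielding orthogroups each tracing
to a single crown-ancestral gene), assigning duplications to annotated WGD
events, classifying branches into pre-/post-duplication epochs, and pulling
out one-to-one ortholog pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd

from .treedata import GeneTree, SpeciesTree, node_name

__all__ = [
    "ReconciliationResult",
    "reconcile",
    "lca_map",
    "label_events",
    "count_losses",
    "split_aogs",
    "assign_wgd",
    "classify_branch_epochs",
    "extract_one_to_one_orthologs",
    "LINEAGE_SPECIFIC",
    "EPOCH_PRE_DB",
    "EPOCH_POST_DB",
    "EPOCH_POST_SB",
    "EPOCH_OTHER",
]

LINEAGE_SPECIFIC = "lineage-specific"

EPOCH_PRE_DB = "PreDB"
EPOCH_POST_DB = "PostDB"
EPOCH_POST_SB = "PostSB"
EPOCH_OTHER = "other"

LEAF = "leaf"
SPECIATION = "speciation"
DUPLICATION = "duplication"


class _SpeciesIndex:
    """Depth/parent index over a species tree for O(depth) LCA queries."""

    def __init__(self, species_tree: SpeciesTree):
        self.depth: dict[dendropy.Node, int] = {}
        self.parent: dict[dendropy.Node, dendropy.Node | None] = {}
        for node in species_tree.tree.preorder_node_iter():
            par = node.parent_node
            self.parent[node] = par
            self.depth[node] = 0 if par is None else self.depth[par] + 1
        self.leaf_by_species = {
            leaf.taxon.label: leaf for leaf in species_tree.tree.leaf_node_iter()
        }

    def lca(self, a: dendropy.Node, b: dendropy.Node) -> dendropy.Node:
        while self.depth[a] > self.depth[b]:
            a = self.parent[a]
        while self.depth[b] > self.depth[a]:
            b = self.parent[b]
        while a is not b:
            a = self.parent[a]
            b = self.parent[b]
        return a

    def distance_down(self, anc: dendropy.Node, desc: dendropy.Node) -> int:
        """Edge count from ancestor to descendant (anc must be ancestral-or-equal)."""
        d = self.depth[desc] - self.depth[anc]
        if d < 0:
            raise ValueError("anc is not ancestral to desc")
        return d

    def is_ancestor_or_equal(self, anc: dendropy.Node, desc: dendropy.Node) -> bool:
        while desc is not None and self.depth[desc] >= self.depth[anc]:
            if desc is anc:
                return True
            desc = self.parent[desc]
        return False


@dataclass
class ReconciliationResult:
    """LCA mapping, event labels and per-edge loss counts for one gene tree.

    ``mapping`` sends every gene-tree node to its species-tree image;
    ``events`` labels each node ``leaf`` / ``speciation`` / ``duplication``;
    ``losses`` gives the implied loss count on the edge *above* each node
    (keyed by the child node; the root edge carries no losses).
    """

    gene_tree: GeneTree
    species_tree: SpeciesTree
    gene_species_map: dict[str, str]
    mapping: dict[dendropy.Node, dendropy.Node]
    events: dict[dendropy.Node, str]
    losses: dict[dendropy.Node, int]

    @property
    def duplication_nodes(self) -> list[dendropy.Node]:
        return [n for n, e in self.events.items() if e == DUPLICATION]

    @property
    def n_duplications(self) -> int:
        return len(self.duplication_nodes)

    @property
    def n_losses(self) -> int:
        return sum(self.losses.values())

    @property
    def cost(self) -> int:
        """Total duplication + loss cost of the reconciliation."""
        return self.n_duplications + self.n_losses

    def image_name(self, gnode: dendropy.Node) -> str:
        return node_name(self.mapping[gnode])

    def to_frame(self) -> pd.DataFrame:
        """Tabular report: one row per gene-tree node."""
        rows = []
        for node in self.gene_tree.tree.preorder_node_iter():
            rows.append(
                {
                    "node": node_name(node),
                    "image": self.image_name(node),
                    "event": self.events[node],
                    "losses_above": self.losses.get(node, 0),
                }
            )
        return pd.DataFrame(rows)


def lca_map(
    gene_tree: GeneTree,
    species_tree: SpeciesTree,
    gene_species_map: Mapping[str, str],
) -> dict[dendropy.Node, dendropy.Node]:
    """Compute the LCA mapping M: gene-tree node -> species-tree node.

    Bottom-up: a leaf maps to its species; an internal node maps to the
    species-tree LCA of its children's images.
    """
    idx = _SpeciesIndex(species_tree)
    mapping: dict[dendropy.Node, dendropy.Node] = {}
    for node in gene_tree.tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            try:
                species = gene_species_map[label]
            except KeyError:
                raise KeyError(f"gene leaf {label!r} has no species assignment") from None
            try:
                mapping[node] = idx.leaf_by_species[species]
            except KeyError:
                raise KeyError(
                    f"species {species!r} (gene {label!r}) not in species tree"
                ) from None
        else:
            children = node.child_nodes()
            image = mapping[children[0]]
            for child in children[1:]:
                image = idx.lca(image, mapping[child])
            mapping[node] = image
    return mapping


def label_events(
    mapping: Mapping[dendropy.Node, dendropy.Node],
) -> dict[dendropy.Node, str]:
    """Label each gene-tree node: duplication iff its image equals a child's."""
    events: dict[dendropy.Node, str] = {}
    for node in mapping:
        if node.is_leaf():
            events[node] = LEAF
        elif any(mapping[c] is mapping[node] for c in node.child_nodes()):
            events[node] = DUPLICATION
        else:
            events[node] = SPECIATION
    return events


def count_losses(
    mapping: Mapping[dendropy.Node, dendropy.Node],
    events: Mapping[dendropy.Node, str],
    species_tree: SpeciesTree,
) -> dict[dendropy.Node, int]:
    """Implied losses on each gene-tree edge, keyed by the edge's child node.

    With d = species-tree edge distance between the parent and child images,
    the edge above v carries d losses when the parent is a duplication and
    d - 1 when it is a speciation (the speciation itself accounts for one
    level of descent).
    """
    idx = _SpeciesIndex(species_tree)
    losses: dict[dendropy.Node, int] = {}
    for node in mapping:
        parent = node.parent_node
        if parent is None:
            continue
        d = idx.distance_down(mapping[parent], mapping[node])
        losses[node] = d if events[parent] == DUPLICATION else d - 1
    return losses


def reconcile(
    gene_tree: GeneTree,
    species_tree: SpeciesTree,
    gene_species_map: Mapping[str, str],
) -> ReconciliationResult:
    """Full LCA reconciliation: mapping, event labels, per-edge losses."""
    mapping = lca_map(gene_tree, species_tree, gene_species_map)
    events = label_events(mapping)
    losses = count_losses(mapping, events, species_tree)
    return ReconciliationResult(
        gene_tree=gene_tree,
        species_tree=species_tree,
        gene_species_map=dict(gene_species_map),
        mapping=mapping,
        events=events,
        losses=losses,
    )


def _subtree_to_gene_tree(node: dendropy.Node) -> GeneTree:
    """Deep-copy the subtree rooted at ``node`` into a fresh GeneTree."""

    def render(n: dendropy.Node) -> str:
        length = "" if n.edge.length is None else f":{n.edge.length}"
        if n.is_leaf():
            return f"{n.taxon.label}{length}"
        inner = ",".join(render(c) for c in n.child_nodes())
        return f"({inner}){length}"

    return GeneTree.from_newick(render(node) + ";")


def split_aogs(
    reconciliation: ReconciliationResult,
    crown_node_name: str,
) -> list[GeneTree]:
    """Split a gene tree at duplications predating a crown group.

    The tree is cut at every duplication node whose species-tree image is
    an ancestor-or-equal of the crown node, so that each returned subtree
    descends from a single gene copy in the crown ancestor: a duplication
    *mapping to* the crown node precedes the crown speciation in time, so
    leaving it uncut would put two crown-ancestral copies in one
    orthogroup.  Subtrees whose leaves all belong to outgroup species
    (species not under the crown node) are discarded.  With no pre-crown
    duplication the input comes back as a single orthogroup.
    """
    species_tree = reconciliation.species_tree
    crown = species_tree.node(crown_node_name)
    idx = _SpeciesIndex(species_tree)
    cut_images = {crown}
    anc = idx.parent[crown]
    while anc is not None:
        cut_images.add(anc)
        anc = idx.parent[anc]
    ingroup_species = {
        leaf.taxon.label for leaf in crown.leaf_iter()
    }

    roots: list[dendropy.Node] = []

    def descend(node: dendropy.Node) -> None:
        if (
            reconciliation.events[node] == DUPLICATION
            and reconciliation.mapping[node] in cut_images
        ):
            for child in node.child_nodes():
                descend(child)
        else:
            roots.append(node)

    descend(reconciliation.gene_tree.root)

    gmap = reconciliation.gene_species_map
    out: list[GeneTree] = []
    for r in roots:
        leaf_species = {gmap[l.taxon.label] for l in r.leaf_iter()}
        if leaf_species & ingroup_species:
            out.append(_subtree_to_gene_tree(r))
    return out


def assign_wgd(reconciliation: ReconciliationResult) -> dict[dendropy.Node, str]:
    """Assign each duplication to a WGD event or call it lineage-specific.

    A duplication is attributed to WGD ``w`` when its species-tree image is
    the node subtending the branch annotated with ``w``.  Node-image equality
    is the only requirement; survival of both duplicate copies in every
    descendant lineage is not demanded.
    """
    species_tree = reconciliation.species_tree
    labels: dict[dendropy.Node, str] = {}
    for dup in reconciliation.duplication_nodes:
        events = species_tree.wgds_on_branch(reconciliation.image_name(dup))
        labels[dup] = events[0] if events else LINEAGE_SPECIFIC
    return labels


def classify_branch_epochs(
    reconciliation: ReconciliationResult,
    focal_duplications: Sequence[dendropy.Node],
    family_crown: str,
) -> dict[dendropy.Node, str]:
    """Partition gene-tree branches into duplication epochs.

    Relative to a focal WGD duplication at the crown of a family:

    * ``PreDB`` — the branch entering a focal duplication (including the
      branch between two nested focal duplications of a trio);
    * ``PostDB`` — branches from a focal duplication down to, and ending at,
      the first speciation (or leaf) on each descendant path;
    * ``PostSB`` — branches below those first speciations;
    * ``other`` — everything else.

    Branches are keyed by their child node (the root's entry branch by the
    root node).  A focal pair yields 2 PostDB branches and a nested trio 3,
    matching how pairs/trios are tallied downstream.
    """
    crown = reconciliation.species_tree.node(family_crown)
    focal = set(focal_duplications)
    for node in focal:
        if reconciliation.events.get(node) != DUPLICATION:
            raise ValueError(f"focal node {node_name(node)!r} is not a duplication")
        if reconciliation.mapping[node] is not crown:
            raise ValueError(
                f"focal duplication {node_name(node)!r} does not map to {family_crown!r}"
            )

    labels: dict[dendropy.Node, str] = {
        n: EPOCH_OTHER for n in reconciliation.gene_tree.tree.preorder_node_iter()
    }

    def mark_post_sb(node: dendropy.Node) -> None:
        for child in node.child_nodes():
            labels[child] = EPOCH_POST_SB
            mark_post_sb(child)

    def walk_post_db(node: dendropy.Node) -> None:
        """Label PostDB from a focal duplication down to the first speciation."""
        for child in node.child_nodes():
            if child in focal:
                labels[child] = EPOCH_PRE_DB
                walk_post_db(child)
            elif child.is_leaf() or reconciliation.events[child] == SPECIATION:
                labels[child] = EPOCH_POST_DB
                mark_post_sb(child)
            else:  # non-focal duplication before the first speciation
                labels[child] = EPOCH_POST_DB
                walk_post_db_through(child)

    def walk_post_db_through(node: dendropy.Node) -> None:
        for child in node.child_nodes():
            if child.is_leaf() or reconciliation.events[child] == SPECIATION:
                labels[child] = EPOCH_POST_DB
                mark_post_sb(child)
            else:
                labels[child] = EPOCH_POST_DB
                walk_post_db_through(child)

    # topmost focal duplications: no focal ancestor
    def has_focal_ancestor(node: dendropy.Node) -> bool:
        p = node.parent_node
        while p is not None:
            if p in focal:
                return True
            p = p.parent_node
        return False

    for node in focal:
        if not has_focal_ancestor(node):
            labels[node] = EPOCH_PRE_DB
            walk_post_db(node)

    return labels


def extract_one_to_one_orthologs(
    reconciliation: ReconciliationResult,
    species_a: str,
    species_b: str,
) -> list[tuple[str, str]]:
    """One-to-one ortholog pairs between two species.

    A pair (a, b) qualifies when the gene-tree MRCA of a and b is a
    speciation node and neither species has a second copy beneath that MRCA.
    """
    gmap = reconciliation.gene_species_map
    tree = reconciliation.gene_tree.tree

    # per-node copy counts for the two species, postorder
    counts: dict[dendropy.Node, tuple[int, int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            sp = gmap[node.taxon.label]
            counts[node] = (int(sp == species_a), int(sp == species_b))
        else:
            a = sum(counts[c][0] for c in node.child_nodes())
            b = sum(counts[c][1] for c in node.child_nodes())
            counts[node] = (a, b)

    pairs: list[tuple[str, str]] = []
    for node in tree.postorder_node_iter():
        if node.is_leaf() or reconciliation.events[node] != SPECIATION:
            continue
        if counts[node] != (1, 1):
            continue
        children = node.child_nodes()
        # the MRCA of the pair is this node iff a and b sit in different subtrees
        left, right = counts[children[0]], counts[children[1]]
        if {left, right} == {(1, 0), (0, 1)}:
            a_leaf = next(
                l.taxon.label for l in node.leaf_iter() if gmap[l.taxon.label] == species_a
            )
            b_leaf = next(
                l.taxon.label for l in node.leaf_iter() if gmap[l.taxon.label] == species_b
            )
            pairs.append((a_leaf, b_leaf))
    return pairs
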