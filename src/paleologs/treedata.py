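"""Core tree containers and I/O shared by every analysis stage.

Trees are stored as rooted :class:`dendropy.Tree` objects wrapped in thin
domain types.  Gene leaves follow the four-letter species-code convention:
the first four characters of a gene identifier name its species (first two
letters of the genus plus first two of the species epithet), e.g.
``AthaERF017`` is an *Arabidopsis thaliana* gene.

Whole-genome duplication (WGD) events are annotated on species-tree branches
through a sidecar TSV rather than Newick comments, keeping the tree files
standard.  Each annotation names the branch by its child node.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import pandas as pd

__all__ = [
    "TreeParseError",
    "UnmappedGeneError",
    "MultifurcationError",
    "SpeciesInfo",
    "GeneTree",
    "SpeciesTree",
    "read_tree",
    "write_tree",
    "read_gene_tree",
    "read_species_tree",
    "read_wgd_table",
    "read_species_metadata",
    "map_genes_to_species",
    "SPECIES_CODE_LENGTH",
]

SPECIES_CODE_LENGTH = 4

CLADE_GROUPS = ("basal", "eudicot", "monocot")


class TreeParseError(ValueError):
    """Raised when Newick input cannot be parsed into a valid rooted tree."""


class UnmappedGeneError(KeyError):
    """Raised when a gene leaf label matches no known species code."""


class MultifurcationError(ValueError):
    """Raised when a gene tree contains a node with more than two children."""


@dataclass(frozen=True)
class SpeciesInfo:
    """Per-species metadata used by the retention classifier.

    Parameters
    ----------
    clade_group:
        One of ``"basal"``, ``"eudicot"``, ``"monocot"``.  Basal angiosperms
        (e.g. *Amborella*) are excluded from the multi-copy majority test.
    recent_wgd:
        True for species with a recent, lineage-specific WGD; such species
        are excluded from the low-copy (Group 2b) majority test.
    """

    clade_group: str
    recent_wgd: bool = False

    def __post_init__(self) -> None:
        if self.clade_group not in CLADE_GROUPS:
            raise ValueError(
                f"clade_group must be one of {CLADE_GROUPS}, got {self.clade_group!r}"
            )


def _parse_newick(source: str | Path) -> dendropy.Tree:
    """Parse Newick from a string or a path; underscores are literal."""
    if isinstance(source, Path):
        data = source.read_text()
    elif isinstance(source, str) and ("(" in source or ";" in source):
        data = source
    elif isinstance(source, str) and os.path.exists(source):
        data = Path(source).read_text()
    else:
        raise TreeParseError(f"not Newick text and not an existing path: {source!r}")
    stripped = data.strip()
    if not stripped.endswith(";"):
        raise TreeParseError("Newick source must end with ';'")
    if stripped.count("(") != stripped.count(")"):
        raise TreeParseError(
            f"unbalanced parentheses: {stripped.count('(')} '(' vs {stripped.count(')')} ')'"
        )
    try:
        tree = dendropy.Tree.get(
            data=data,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=False,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise TreeParseError(f"malformed Newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise TreeParseError(f"duplicate leaf labels: {sorted(dupes)}")
    return tree


def _autoname_internal_nodes(tree: dendropy.Tree, prefix: str = "N") -> None:
    """Give every unnamed internal node a deterministic preorder name."""
    taken = {n.taxon.label for n in tree if n.taxon is not None}
    counter = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        if node.taxon is None or not node.taxon.label:
            counter += 1
            name = f"{prefix}{counter}"
            while name in taken:
                counter += 1
                name = f"{prefix}{counter}"
            taken.add(name)
            node.label = name


def node_name(node: dendropy.Node) -> str:
    """Human-readable name of a node (taxon label for leaves)."""
    if node.taxon is not None and node.taxon.label:
        return node.taxon.label
    return node.label or ""


class GeneTree:
    """A rooted binary gene tree with unique leaf labels.

    Thin wrapper over :class:`dendropy.Tree` that enforces the invariants
    downstream reconciliation relies on: a single root, two children per
    internal node, and unique leaf labels (gene identifiers).
    """

    def __init__(self, tree: dendropy.Tree):
        for node in tree.preorder_node_iter():
            n = len(node.child_nodes())
            if n not in (0, 2):
                raise MultifurcationError(
                    f"gene tree node {node_name(node) or '<unnamed>'} has {n} children; "
                    "gene trees must be strictly binary"
                )
        _autoname_internal_nodes(tree, prefix="g")
        self.tree = tree

    @classmethod
    def from_newick(cls, source: str | Path) -> "GeneTree":
        return cls(_parse_newick(source))

    @property
    def root(self) -> dendropy.Node:
        return self.tree.seed_node

    def leaves(self) -> list[dendropy.Node]:
        return list(self.tree.leaf_node_iter())

    def leaf_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def __len__(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    def as_newick(self) -> str:
        return write_tree(self)

    def __repr__(self) -> str:  # pragma: no cover
        return f"GeneTree({len(self)} leaves)"


class SpeciesTree:
    """Rooted species tree with optional WGD branch annotations and metadata.

    WGD events attach to branches; each event is stored as
    ``event name -> child-node name`` of the annotated branch.
    """

    def __init__(
        self,
        tree: dendropy.Tree,
        wgd_events: Mapping[str, str] | None = None,
        metadata: Mapping[str, SpeciesInfo] | None = None,
    ):
        _autoname_internal_nodes(tree, prefix="N")
        self.tree = tree
        self._by_name: dict[str, dendropy.Node] = {}
        for node in tree.preorder_node_iter():
            name = node_name(node)
            if name in self._by_name:
                raise TreeParseError(f"duplicate node name in species tree: {name!r}")
            self._by_name[name] = node
        self.wgd_events: dict[str, str] = {}
        for event, child in (wgd_events or {}).items():
            self.add_wgd(event, child)
        self.metadata: dict[str, SpeciesInfo] = dict(metadata or {})
        unknown = set(self.metadata) - set(self.species())
        if unknown:
            raise ValueError(f"metadata for species not in tree: {sorted(unknown)}")

    @classmethod
    def from_newick(
        cls,
        source: str | Path,
        wgd_events: Mapping[str, str] | None = None,
        metadata: Mapping[str, SpeciesInfo] | None = None,
    ) -> "SpeciesTree":
        return cls(_parse_newick(source), wgd_events, metadata)

    @property
    def root(self) -> dendropy.Node:
        return self.tree.seed_node

    def species(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def node(self, name: str) -> dendropy.Node:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"no species-tree node named {name!r}") from None

    def add_wgd(self, event_name: str, child_node_name: str) -> None:
        self.node(child_node_name)  # validates existence
        if event_name in self.wgd_events:
            raise ValueError(f"WGD event {event_name!r} already annotated")
        self.wgd_events[event_name] = child_node_name

    def wgds_on_branch(self, child_node_name: str) -> list[str]:
        """Events annotated on the branch subtending the named node."""
        return sorted(e for e, c in self.wgd_events.items() if c == child_node_name)

    def __repr__(self) -> str:  # pragma: no cover
        return f"SpeciesTree({len(self.species())} species, {len(self.wgd_events)} WGDs)"


def read_tree(source: str | Path) -> dendropy.Tree:
    """Read a rooted tree from Newick text or a file path.

    Returns the raw :class:`dendropy.Tree`; use :func:`read_gene_tree` /
    :func:`read_species_tree` for the validated domain wrappers.
    """
    return _parse_newick(source)


def write_tree(tree, path: str | Path | None = None) -> str:
    """Serialize a tree (wrapper or raw dendropy) to Newick.

    Round-trips topology, labels and branch lengths; quoted labels are used
    where needed by the Newick dialect.
    """
    dtree = tree.tree if isinstance(tree, (GeneTree, SpeciesTree)) else tree
    text = dtree.as_string(
        schema="newick",
        unquoted_underscores=True,
        preserve_spaces=True,  # spaces stay quoted instead of becoming underscores
        suppress_rooting=True,
    )
    text = text.strip() + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def read_gene_tree(source: str | Path) -> GeneTree:
    return GeneTree.from_newick(source)


def read_species_tree(
    source: str | Path,
    wgd_table: str | Path | None = None,
    metadata_table: str | Path | None = None,
) -> SpeciesTree:
    """Read a species tree plus optional WGD and metadata sidecar TSVs."""
    wgd = read_wgd_table(wgd_table) if wgd_table is not None else None
    meta = read_species_metadata(metadata_table) if metadata_table is not None else None
    return SpeciesTree.from_newick(source, wgd, meta)


def read_wgd_table(path: str | Path) -> dict[str, str]:
    """Read a WGD sidecar TSV with columns ``event_name``, ``child_node_name``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"event_name", "child_node_name"}
    if not required.issubset(df.columns):
        raise ValueError(f"WGD table needs columns {sorted(required)}, got {list(df.columns)}")
    return dict(zip(df["event_name"], df["child_node_name"]))


def read_species_metadata(path: str | Path) -> dict[str, SpeciesInfo]:
    """Read species metadata TSV: species_code, clade_group, recent_wgd (0/1)."""
    df = pd.read_csv(path, sep="\t", dtype={"species_code": str, "clade_group": str})
    required = {"species_code", "clade_group", "recent_wgd"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"metadata table needs columns {sorted(required)}, got {list(df.columns)}"
        )
    return {
        row.species_code: SpeciesInfo(row.clade_group, bool(int(row.recent_wgd)))
        for row in df.itertuples()
    }


def write_wgd_table(events: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"event_name": list(events), "child_node_name": list(events.values())}
    ).to_csv(path, sep="\t", index=False)


def write_species_metadata(meta: Mapping[str, SpeciesInfo], path: str | Path) -> None:
    pd.DataFrame(
        {
            "species_code": list(meta),
            "clade_group": [m.clade_group for m in meta.values()],
            "recent_wgd": [int(m.recent_wgd) for m in meta.values()],
        }
    ).to_csv(path, sep="\t", index=False)


def map_genes_to_species(
    gene_tree: GeneTree, known_codes: Iterable[str]
) -> dict[str, str]:
    """Assign each gene leaf its species by four-letter prefix.

    The convention is positional, not delimiter-based: the first
    ``SPECIES_CODE_LENGTH`` characters of the leaf label must equal a known
    species code.  Total: every leaf is mapped or an error names the
    offenders — leaves are never silently dropped.
    """
    codes = set(known_codes)
    for c in codes:
        if len(c) != SPECIES_CODE_LENGTH:
            raise ValueError(f"species codes must be {SPECIES_CODE_LENGTH} chars: {c!r}")
    mapping: dict[str, str] = {}
    unmatched: list[str] = []
    for label in gene_tree.leaf_labels():
        prefix = label[:SPECIES_CODE_LENGTH]
        if prefix in codes:
            mapping[label] = prefix
        else:
            unmatched.append(label)
    if unmatched:
        raise UnmappedGeneError(
            f"gene leaves with no known species-code prefix: {sorted(unmatched)}"
        )
    return mapping
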