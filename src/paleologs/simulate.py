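"""Synthetic data generator: gene families, expression matrices, codon pairs.

This module is the test harness for the whole pipeline.  It emulates the
structure of the real data without pretending to be it:

* **Gene families** evolve top-down along a species tree under a linear
  birth-death process (duplication rate ``lam``, loss rate ``mu`` per unit
  branch length) with instantaneous WGD bursts at the midpoint of annotated
  branches, where each surviving lineage duplicates with retention
  probability ``r``.  Every event is written to a truth log from which the
  gene tree can be replayed exactly.
* **Expression** draws per-gene tissue proportions from a symmetric
  Dirichlet — concentration ``alpha`` large for broadly expressed classes
  (tau near 0) and small for tissue-specific classes (tau near 1) — scaled
  by a lognormal total; tau is scale-invariant, so the total only adds
  realism.
* **Codon pairs** evolve a uniformly drawn sense-codon ancestor by mutation
  attempts accepted with probability 1 (synonymous), ``omega``
  (non-synonymous) or 0 (stop), with divergence ``t`` = expected mutation
  attempts per nucleotide site.

Two family classes form the stated world of the acceptance fixture:
``broad`` (WGD retention r = 0.9, Dirichlet alpha = 5.0) and ``narrow``
(r = 0.1, alpha = 0.1), 30 families per class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .treedata import (
    GeneTree,
    SpeciesInfo,
    SpeciesTree,
    map_genes_to_species,
    node_name,
    write_species_metadata,
    write_tree,
    write_wgd_table,
)

__all__ = [
    "SimulationConfig",
    "SimulatedFamily",
    "default_species_tree",
    "simulate_gene_family",
    "simulate_dataset",
    "simulate_expression",
    "simulate_codon_pair",
    "replay_events",
    "write_dataset",
]

#: stated-world class parameters: WGD retention r and Dirichlet alpha
CLASS_PARAMS = {
    "broad": {"retention": 0.9, "alpha": 5.0},
    "narrow": {"retention": 0.1, "alpha": 0.1},
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic world.

    Defaults encode the acceptance fixture: two retention/expression
    classes, 30 families each, on the bundled angiosperm-like species tree.
    """

    seed: int = 0
    duplication_rate: float = 0.05  # lineage duplications per unit branch length
    loss_rate: float = 0.05
    wgd_retention: dict[str, float] = field(
        default_factory=lambda: {c: p["retention"] for c, p in CLASS_PARAMS.items()}
    )
    families_per_class: int = 30
    n_tissues: int = 6
    dirichlet_alpha: dict[str, float] = field(
        default_factory=lambda: {c: p["alpha"] for c, p in CLASS_PARAMS.items()}
    )
    expr_log_mean: float = 2.0  # lognormal total expression, log scale
    expr_log_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.duplication_rate < 0 or self.loss_rate < 0:
            raise ValueError("rates must be >= 0")
        for c, r in self.wgd_retention.items():
            if not 0 <= r <= 1:
                raise ValueError(f"retention probability for {c!r} must be in [0,1]")
        if self.n_tissues < 2:
            raise ValueError("need at least 2 tissues")


def default_species_tree() -> SpeciesTree:
    """Bundled 14-species angiosperm species tree with annotated WGDs.

    One basal angiosperm (Amtr, *Amborella*), eight eudicots and five
    monocots, with WGD events placed the way the angiosperm record places
    them: gamma at the core-eudicot crown; alpha and beta nested inside the
    Brassicaceae; family-level events at the Fabaceae and Asteraceae
    crowns; and the tau / sigma / rho series nested along the Commelinid -
    Poales - Poaceae backbone.  Most lineages therefore sit below two or
    three events, so families that retain WGD duplicates become multi-copy
    in most species — the structure the copy-number retention classes are
    defined against — while Amborella and duckweed (Spol) stay single-copy.
    """
    newick = (
        "(Amtr,(((((((Atha,Alyr)Camelineae,Brra)Brassicaceae,Thca)Malvids,"
        "(Metr,Glma)Fabaceae)Rosids,Hean)SuperRosids,Vitv)Eudicots,"
        "((((Orsa,Brdi)Poaceae,Anco)Poales,Muac)Commelinids,Spol)Monocots)"
        "Mesangiospermae)Angiosperms;"
    )
    wgd = {
        "gamma": "Eudicots",
        "alpha": "Camelineae",
        "beta": "Brassicaceae",
        "fabaceae": "Fabaceae",
        "asteraceae": "Hean",
        "tau": "Commelinids",
        "sigma": "Poales",
        "rho": "Poaceae",
    }
    meta = {
        "Amtr": SpeciesInfo("basal"),
        "Atha": SpeciesInfo("eudicot"),
        "Alyr": SpeciesInfo("eudicot"),
        "Brra": SpeciesInfo("eudicot", recent_wgd=True),
        "Thca": SpeciesInfo("eudicot"),
        "Metr": SpeciesInfo("eudicot"),
        "Glma": SpeciesInfo("eudicot", recent_wgd=True),
        "Vitv": SpeciesInfo("eudicot"),
        "Hean": SpeciesInfo("eudicot"),
        "Orsa": SpeciesInfo("monocot"),
        "Brdi": SpeciesInfo("monocot"),
        "Anco": SpeciesInfo("monocot"),
        "Muac": SpeciesInfo("monocot"),
        "Spol": SpeciesInfo("monocot"),
    }
    return SpeciesTree.from_newick(newick, wgd, meta)


class _SimNode:
    """A gene lineage while the family is being grown."""

    __slots__ = ("uid", "children", "length", "label", "extinct", "birth")

    def __init__(self, uid: int, birth: float):
        self.uid = uid
        self.children: list[_SimNode] = []
        self.length: float = 0.0
        self.label: str | None = None
        self.extinct = False
        self.birth = birth


@dataclass
class SimulatedFamily:
    """One synthetic gene family with its complete truth log."""

    family_id: str
    class_label: str
    gene_tree: GeneTree | None  # None when the family went extinct
    events: list[dict]
    copy_number: dict[str, int]
    gene_species_map: dict[str, str]

    @property
    def extinct(self) -> bool:
        return self.gene_tree is None

    @property
    def n_duplications(self) -> int:
        """Duplications in the truth log (rate events plus retained WGD copies)."""
        return sum(1 for e in self.events if e["event"] in ("dup", "wgd_dup"))


def _sim_to_newick(node: _SimNode) -> str:
    if not node.children:
        return f"{node.label}:{node.length:.6f}"
    inner = ",".join(_sim_to_newick(c) for c in node.children)
    return f"({inner}):{node.length:.6f}"


def _prune(node: _SimNode) -> _SimNode | None:
    """Drop extinct lineages and suppress the resulting unifurcations."""
    if not node.children:
        return None if node.extinct else node
    kept = [c for c in (_prune(c) for c in node.children) if c is not None]
    if not kept:
        return None
    if len(kept) == 1:
        child = kept[0]
        child.length += node.length
        return child
    node.children = kept
    return node


def simulate_gene_family(
    species_tree: SpeciesTree,
    rng: np.random.Generator,
    duplication_rate: float = 0.05,
    loss_rate: float = 0.05,
    wgd_retention: float = 0.9,
    family_id: str = "fam1",
    class_label: str = "broad",
) -> SimulatedFamily:
    """Grow one gene family along the species tree.

    Within each species branch (length defaulting to 1.0 when the tree has
    none), every lineage independently experiences duplications and losses
    as Poisson processes; at the midpoint of a WGD-annotated branch each
    surviving lineage duplicates with probability ``wgd_retention``.  At
    species-tree nodes every lineage splits into all child branches; at
    species leaves survivors are sampled as genes named
    ``<code>_<family>_g<k>``.
    """
    events: list[dict] = []
    uid_counter = 0

    def new_node(birth: float) -> _SimNode:
        nonlocal uid_counter
        uid_counter += 1
        return _SimNode(uid_counter, birth)

    total_rate = duplication_rate + loss_rate
    gene_counter: dict[str, int] = {}
    copy_number: dict[str, int] = dict.fromkeys(species_tree.species(), 0)
    gene_map: dict[str, str] = {}

    root_lineage = new_node(0.0)
    events.append({"event": "origin", "lineage": root_lineage.uid, "time": 0.0})

    def evolve_on_branch(
        node: _SimNode,
        sp_child_name: str,
        t: float,
        branch_len: float,
        global_start: float,
        wgds: list[tuple[float, str]],
    ) -> list[_SimNode]:
        """Evolve one lineage from local time t to the end of the branch."""
        pending = [w for w in wgds if w[0] >= t]
        while True:
            wait = rng.exponential(1.0 / total_rate) if total_rate > 0 else np.inf
            t_event = t + wait
            if pending and pending[0][0] <= min(t_event, branch_len):
                wgd_time, wgd_name = pending.pop(0)
                t = wgd_time
                if rng.random() < wgd_retention:
                    node.length = global_start + t - node.birth
                    c1, c2 = new_node(global_start + t), new_node(global_start + t)
                    node.children = [c1, c2]
                    events.append(
                        {
                            "event": "wgd_dup",
                            "lineage": node.uid,
                            "children": (c1.uid, c2.uid),
                            "species_branch": sp_child_name,
                            "wgd": wgd_name,
                            "time": global_start + t,
                        }
                    )
                    survivors: list[_SimNode] = []
                    for child in (c1, c2):
                        survivors.extend(
                            evolve_on_branch(
                                child, sp_child_name, t, branch_len, global_start, list(pending)
                            )
                        )
                    return survivors
                continue
            if t_event <= branch_len:
                t = t_event
                if rng.random() < duplication_rate / total_rate:
                    node.length = global_start + t - node.birth
                    c1, c2 = new_node(global_start + t), new_node(global_start + t)
                    node.children = [c1, c2]
                    events.append(
                        {
                            "event": "dup",
                            "lineage": node.uid,
                            "children": (c1.uid, c2.uid),
                            "species_branch": sp_child_name,
                            "wgd": None,
                            "time": global_start + t,
                        }
                    )
                    survivors = []
                    for child in (c1, c2):
                        survivors.extend(
                            evolve_on_branch(
                                child, sp_child_name, t, branch_len, global_start, list(pending)
                            )
                        )
                    return survivors
                node.length = global_start + t - node.birth
                node.extinct = True
                events.append(
                    {
                        "event": "loss",
                        "lineage": node.uid,
                        "species_branch": sp_child_name,
                        "time": global_start + t,
                    }
                )
                return []
            node.length = global_start + branch_len - node.birth
            return [node]

    def traverse(sp_node, lineages: list[_SimNode], global_time: float) -> None:
        """Recurse over species-tree children of sp_node with live lineages."""
        for sp_child in sp_node.child_nodes():
            branch_len = sp_child.edge.length if sp_child.edge.length else 1.0
            child_name = node_name(sp_child)
            wgds = [
                (branch_len / 2.0, ev)
                for ev in species_tree.wgds_on_branch(child_name)
            ]
            # lineages entering this species branch
            entering: list[_SimNode] = []
            for lin in lineages:
                branch_copy = new_node(global_time)
                lin.children.append(branch_copy)
                entering.append(branch_copy)
            for lin, copy in zip(lineages, entering):
                events.append(
                    {
                        "event": "descend",
                        "lineage": lin.uid,
                        "children": (copy.uid,),
                        "species_branch": child_name,
                        "time": global_time,
                    }
                )
            survivors: list[_SimNode] = []
            for lin in entering:
                survivors.extend(
                    evolve_on_branch(lin, child_name, 0.0, branch_len, global_time, wgds)
                )
            if sp_child.is_leaf():
                code = sp_child.taxon.label
                for lin in survivors:
                    gene_counter[code] = gene_counter.get(code, 0) + 1
                    label = f"{code}_{family_id}_g{gene_counter[code]}"
                    lin.label = label
                    copy_number[code] += 1
                    gene_map[label] = code
                    events.append(
                        {
                            "event": "sample",
                            "lineage": lin.uid,
                            "species_branch": code,
                            "gene": label,
                            "time": global_time + branch_len,
                        }
                    )
            else:
                traverse(sp_child, survivors, global_time + branch_len)

    # evolve along the root branch first (WGDs may be annotated on it)
    root_branch_len = (
        species_tree.root.edge.length if species_tree.root.edge.length else 1.0
    )
    root_name = node_name(species_tree.root)
    root_wgds = [
        (root_branch_len / 2.0, ev) for ev in species_tree.wgds_on_branch(root_name)
    ]
    survivors = evolve_on_branch(
        root_lineage, root_name, 0.0, root_branch_len, 0.0, root_wgds
    )
    traverse(species_tree.root, survivors, root_branch_len)

    pruned = _prune(root_lineage)
    if pruned is None:
        tree = None
    else:
        tree = GeneTree.from_newick(_sim_to_newick(pruned) + ";")
    return SimulatedFamily(
        family_id=family_id,
        class_label=class_label,
        gene_tree=tree,
        events=events,
        copy_number=copy_number,
        gene_species_map=gene_map,
    )


def replay_events(family: SimulatedFamily) -> str | None:
    """Rebuild the gene tree from the truth log alone (topology + labels).

    Returns the replayed Newick (without branch lengths), or None for an
    extinct family.  Used to assert that the log fully determines the tree.
    """
    nodes: dict[int, _SimNode] = {}
    root_uid = None
    for ev in family.events:
        kind = ev["event"]
        if kind == "origin":
            root_uid = ev["lineage"]
            nodes[root_uid] = _SimNode(root_uid, 0.0)
        elif kind in ("dup", "wgd_dup", "descend"):
            parent = nodes[ev["lineage"]]
            for uid in ev["children"]:
                child = _SimNode(uid, 0.0)
                parent.children.append(child)
                nodes[uid] = child
        elif kind == "loss":
            nodes[ev["lineage"]].extinct = True
        elif kind == "sample":
            nodes[ev["lineage"]].label = ev["gene"]
    assert root_uid is not None
    pruned = _prune(nodes[root_uid])
    if pruned is None:
        return None

    def render(n: _SimNode) -> str:
        if not n.children:
            return n.label or f"lin{n.uid}"
        return "(" + ",".join(render(c) for c in n.children) + ")"

    return render(pruned) + ";"


def simulate_dataset(
    config: SimulationConfig | None = None,
    species_tree: SpeciesTree | None = None,
) -> list[SimulatedFamily]:
    """Simulate all families of the configured classes, deterministically."""
    config = config or SimulationConfig()
    species_tree = species_tree or default_species_tree()
    rng = np.random.default_rng(config.seed)
    families: list[SimulatedFamily] = []
    for class_label in sorted(config.wgd_retention):
        r = config.wgd_retention[class_label]
        for i in range(config.families_per_class):
            fam = simulate_gene_family(
                species_tree,
                rng,
                duplication_rate=config.duplication_rate,
                loss_rate=config.loss_rate,
                wgd_retention=r,
                family_id=f"{class_label[:1]}{i + 1:03d}",
                class_label=class_label,
            )
            families.append(fam)
    return families


def simulate_expression(
    families: Sequence[SimulatedFamily],
    config: SimulationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Class-structured expression matrix for every sampled gene.

    Per gene: tissue proportions ~ symmetric Dirichlet with the class's
    concentration, scaled by a lognormal total.  Returns the genes x
    tissues matrix and the per-gene class labels.
    """
    config = config or SimulationConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    rows, classes, index = [], [], []
    for fam in families:
        if fam.extinct:
            continue
        alpha = config.dirichlet_alpha[fam.class_label]
        for gene in fam.gene_tree.leaf_labels():
            props = rng.dirichlet(np.full(config.n_tissues, alpha))
            total = rng.lognormal(config.expr_log_mean, config.expr_log_sd)
            rows.append(props * total)
            classes.append(fam.class_label)
            index.append(gene)
    tissues = [f"tissue{i + 1}" for i in range(config.n_tissues)]
    matrix = pd.DataFrame(rows, index=index, columns=tissues)
    return matrix, pd.Series(classes, index=index, name="class")


# --- codon-pair simulation -------------------------------------------------

_SENSE_CODONS: list[str] | None = None


def _sense_codons(code_id: int = 1) -> list[str]:
    from Bio.Data import CodonTable

    table = CodonTable.unambiguous_dna_by_id[code_id]
    return sorted(table.forward_table)


def simulate_codon_pair(
    omega: float,
    t: float,
    length: int,
    rng: np.random.Generator | int,
    code_id: int = 1,
) -> tuple[str, str]:
    """Evolve an ancestor/descendant codon pair at a controlled omega.

    The ancestor is uniform over sense codons.  Each codon of the
    descendant receives Poisson(3t) mutation attempts (t = expected
    attempts per nucleotide site); an attempt proposes a random single-
    nucleotide change and is accepted with probability 1 if synonymous,
    ``omega`` if non-synonymous, never if it creates a stop codon.
    """
    if omega < 0:
        raise ValueError("omega must be >= 0")
    if t < 0:
        raise ValueError("divergence t must be >= 0")
    if length < 1:
        raise ValueError("length must be >= 1 codon")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    from Bio.Data import CodonTable

    table = CodonTable.unambiguous_dna_by_id[code_id]
    aa_of = dict(table.forward_table)
    for stop in table.stop_codons:
        aa_of[stop] = "*"
    sense = _sense_codons(code_id)
    nts = "ACGT"

    ancestor = [sense[i] for i in rng.integers(0, len(sense), size=length)]
    descendant = []
    for codon in ancestor:
        current = codon
        for _ in range(rng.poisson(3.0 * t)):
            pos = int(rng.integers(3))
            alt = nts[int(rng.integers(4))]
            if alt == current[pos]:
                continue
            candidate = current[:pos] + alt + current[pos + 1 :]
            if aa_of[candidate] == "*":
                continue
            if aa_of[candidate] == aa_of[current] or rng.random() < omega:
                current = candidate
        descendant.append(current)
    return "".join(ancestor), "".join(descendant)


def write_dataset(
    out_dir: str | Path,
    families: Sequence[SimulatedFamily],
    species_tree: SpeciesTree,
    expression: pd.DataFrame | None = None,
    config: SimulationConfig | None = None,
) -> dict[str, Path]:
    """Write a simulated dataset in the same formats the pipeline reads.

    Emits per-family Newick gene trees, the species tree with its WGD and
    metadata sidecars, the expression TSV, a truth-log TSV and the config
    as YAML.  Returns the paths written.
    """
    out = Path(out_dir)
    (out / "gene_trees").mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    log_rows = []
    for fam in families:
        if not fam.extinct:
            p = out / "gene_trees" / f"{fam.family_id}.nwk"
            write_tree(fam.gene_tree, p)
        for ev in fam.events:
            log_rows.append({"family": fam.family_id, **{k: v for k, v in ev.items()}})
    paths["species_tree"] = out / "species_tree.nwk"
    write_tree(species_tree, paths["species_tree"])
    paths["wgd_table"] = out / "wgd_events.tsv"
    write_wgd_table(species_tree.wgd_events, paths["wgd_table"])
    paths["metadata"] = out / "species_metadata.tsv"
    write_species_metadata(species_tree.metadata, paths["metadata"])
    paths["truth_log"] = out / "truth_log.tsv"
    pd.DataFrame(log_rows).to_csv(paths["truth_log"], sep="\t", index=False)
    if expression is not None:
        paths["expression"] = out / "expression.tsv"
        expression.to_csv(paths["expression"], sep="\t")
    if config is not None:
        paths["config"] = out / "config.yaml"
        with open(paths["config"], "w") as fh:
            yaml.safe_dump(
                {
                    "seed": config.seed,
                    "duplication_rate": config.duplication_rate,
                    "loss_rate": config.loss_rate,
                    "wgd_retention": config.wgd_retention,
                    "families_per_class": config.families_per_class,
                    "n_tissues": config.n_tissues,
                    "dirichlet_alpha": config.dirichlet_alpha,
                },
                fh,
            )
    paths["gene_trees"] = out / "gene_trees"
    return paths
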