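"""Copy-number profiling and duplicate-retention classes.

Orthogroups (AOGs — gene clades tracing to a single copy in the crown
ancestor) differ sharply in how they retain WGD duplicates.  A copy-number
profile matrix (AOG x species) is clustered with Ward's minimum-variance
method, and rule-based classes mirror the field's multi-/low-copy groups:

* ``multi``   — >= 3 copies in most (non-basal) species (Group 1);
* ``low_2a``  — low copy, 0-3 genes in the majority of species;
* ``low_2b``  — 0 or 1 copy in the majority, excluding recent-WGD species;
* ``low_2c``  — 0 or 1 copy in eudicots but two copies in monocots.

The prose definitions hedge with "generally" and "most"; the operational
thresholds here (strict >50% majority, copy bounds as printed, rule order
2c -> 2b -> 2a) are fixed so the classifier is deterministic.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .reconcile import LINEAGE_SPECIFIC, ReconciliationResult, assign_wgd
from .treedata import GeneTree, SpeciesInfo

__all__ = [
    "build_copy_matrix",
    "ward_cluster",
    "ward_linkage",
    "classify_profile",
    "classify_matrix",
    "retention_rate",
    "partition_paralog_clades",
    "CLASS_MULTI",
    "CLASS_LOW_2A",
    "CLASS_LOW_2B",
    "CLASS_LOW_2C",
]

CLASS_MULTI = "multi"
CLASS_LOW_2A = "low_2a"
CLASS_LOW_2B = "low_2b"
CLASS_LOW_2C = "low_2c"

#: majority fraction used by the multi-copy and 2b rules ("most species")
MAJORITY_FRACTION = 0.5
#: minimum copy number for the multi-copy rule ("generally >= 3 copies")
MULTI_MIN_COPY = 3


def build_copy_matrix(
    aogs: Sequence[GeneTree],
    gene_species_maps: Sequence[Mapping[str, str]],
    species: Sequence[str],
    aog_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Count gene copies per species for each orthogroup.

    Returns an AOG x species DataFrame of non-negative integers; each row
    sums to the AOG's leaf count.
    """
    if len(aogs) != len(gene_species_maps):
        raise ValueError("one gene-species map required per AOG")
    if aog_ids is None:
        aog_ids = [f"AOG{i + 1}" for i in range(len(aogs))]
    rows = []
    for tree, gmap in zip(aogs, gene_species_maps):
        counts = dict.fromkeys(species, 0)
        for label in tree.leaf_labels():
            try:
                sp = gmap[label]
            except KeyError:
                raise KeyError(f"gene leaf {label!r} has no species assignment") from None
            if sp not in counts:
                raise KeyError(f"species {sp!r} (gene {label!r}) not in species list")
            counts[sp] += 1
        rows.append(counts)
    return pd.DataFrame(rows, index=list(aog_ids), columns=list(species), dtype=int)


def ward_linkage(matrix: pd.DataFrame) -> np.ndarray:
    """Ward minimum-variance linkage of AOG copy-number profiles.

    Euclidean distance on raw counts (profiles share a common scale, so no
    standardization); equivalent to the Ward.D2 criterion.
    """
    if matrix.empty:
        raise ValueError("copy-number matrix is empty")
    return linkage(matrix.to_numpy(dtype=float), method="ward")


def ward_cluster(matrix: pd.DataFrame, k: int) -> pd.Series:
    """Cut the Ward dendrogram into k clusters; deterministic given input.

    Returns integer labels (1..k) indexed by AOG id.  Labels are arbitrary
    up to permutation, but memberships do not depend on row order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(matrix):
        raise ValueError(f"k={k} exceeds the number of AOGs ({len(matrix)})")
    # sort rows for order invariance of the agglomeration, then restore
    order = np.argsort(matrix.index.to_numpy())
    sorted_matrix = matrix.iloc[order]
    labels = fcluster(ward_linkage(sorted_matrix), t=k, criterion="maxclust")
    out = pd.Series(labels, index=sorted_matrix.index, name="cluster")
    return out.reindex(matrix.index)


def classify_profile(
    profile: Mapping[str, int] | pd.Series,
    metadata: Mapping[str, SpeciesInfo],
    majority_fraction: float = MAJORITY_FRACTION,
    multi_min_copy: int = MULTI_MIN_COPY,
) -> str:
    """Classify one copy-number profile into a retention class.

    Rules, applied in order:

    1. ``multi`` if more than half of the non-basal species carry >= 3
       copies (basal angiosperms, typically single-copy even in multi-copy
       orthogroups, sit out this vote);
    2. ``low_2c`` if the median eudicot count is <= 1 and the median
       monocot count equals 2;
    3. ``low_2b`` if more than half of the species carry <= 1 copy once
       recent-WGD species are excluded;
    4. ``low_2a`` otherwise.
    """
    profile = dict(profile)
    if not profile:
        raise ValueError("empty copy-number profile")
    missing = set(profile) - set(metadata)
    if missing:
        raise KeyError(f"species without metadata: {sorted(missing)}")

    def counts(pred) -> list[int]:
        return [c for sp, c in profile.items() if pred(metadata[sp])]

    non_basal = counts(lambda m: m.clade_group != "basal")
    pool = non_basal if non_basal else list(profile.values())
    if sum(c >= multi_min_copy for c in pool) > majority_fraction * len(pool):
        return CLASS_MULTI

    eudicot = counts(lambda m: m.clade_group == "eudicot")
    monocot = counts(lambda m: m.clade_group == "monocot")
    if (
        eudicot
        and monocot
        and np.median(eudicot) <= 1
        and np.median(monocot) == 2
    ):
        return CLASS_LOW_2C

    stable = counts(lambda m: not m.recent_wgd)
    pool = stable if stable else list(profile.values())
    if sum(c <= 1 for c in pool) > majority_fraction * len(pool):
        return CLASS_LOW_2B

    return CLASS_LOW_2A


def classify_matrix(
    matrix: pd.DataFrame, metadata: Mapping[str, SpeciesInfo]
) -> pd.Series:
    """Apply :func:`classify_profile` to every row of a copy-number matrix."""
    return pd.Series(
        {aog: classify_profile(row, metadata) for aog, row in matrix.iterrows()},
        name="retention_class",
    ).reindex(matrix.index)


def retention_rate(
    wgd_labels_per_aog: Mapping[str, Iterable[str]],
    wgd_name: str,
    known_wgds: Iterable[str],
) -> float:
    """Fraction of AOGs retaining at least one duplicate from a given WGD.

    ``wgd_labels_per_aog`` maps each AOG id to the WGD labels of its
    duplication nodes (the output of ``assign_wgd`` collected per AOG).
    """
    known = set(known_wgds)
    if wgd_name not in known:
        raise KeyError(f"unknown WGD event {wgd_name!r}; known: {sorted(known)}")
    if not wgd_labels_per_aog:
        return 0.0
    hits = sum(
        1 for labels in wgd_labels_per_aog.values() if wgd_name in set(labels)
    )
    return hits / len(wgd_labels_per_aog)


def wgd_labels_by_aog(
    reconciliations: Mapping[str, ReconciliationResult],
) -> dict[str, list[str]]:
    """Collect per-AOG WGD labels for all duplication nodes."""
    return {
        aog: sorted(assign_wgd(rec).values())
        for aog, rec in reconciliations.items()
    }


def partition_paralog_clades(
    reference_counts: tuple[int, int],
) -> tuple[int, int] | None:
    """Order a duplicate pair's clades into (D1, D2) by reference-species copies.

    D1 is the clade with strictly more copies in the designated reference
    species; ties are excluded (``None``).  Returns the (D1, D2) indices
    into the input pair.
    """
    c0, c1 = reference_counts
    if c0 == c1:
        return None
    return (0, 1) if c0 > c1 else (1, 0)
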