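"""Tissue specificity, rank tests, cis-element overlap and ancestral states.

Tissue specificity uses the tau index: with expression x over N tissues and
x_hat = x / max(x),

    tau = sum_i (1 - x_hat_i) / (N - 1)

so tau = 0 for perfectly uniform expression and tau = 1 for expression
confined to a single tissue.  tau is scale-invariant and computed on
linear-scale values as given.

Ancestral expressed/not-expressed states per organ are reconstructed by
Sankoff dynamic programming with asymmetric costs: a gain (0 -> 1) costs
more than a loss (1 -> 0), encoding that degenerative (loss-of-expression)
mutations are far more frequent than gains — a Dollo-leaning parsimony.
Missing leaf observations contribute zero cost to either state.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .treedata import GeneTree, node_name

__all__ = [
    "tau",
    "expression_breadth",
    "rank_test",
    "element_partition",
    "AncestralConfig",
    "reconstruct_ancestral_states",
    "AncestralStates",
    "EXPRESSED",
    "NOT_EXPRESSED",
]

EXPRESSED = 1
NOT_EXPRESSED = 0

#: group sizes up to which exact rank-test p-values are computed
EXACT_CUTOFF = 25


def tau(profile: Sequence[float] | np.ndarray) -> float:
    """Tissue-specificity index tau of one expression profile.

    Raises for vectors of fewer than two tissues, negative values, or
    all-zero expression (tau undefined).
    """
    x = np.asarray(profile, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("tau needs a 1-D profile over at least 2 tissues")
    if np.any(x < 0):
        raise ValueError("expression values must be non-negative")
    top = x.max()
    if top == 0:
        raise ValueError("tau undefined for an all-zero expression profile")
    return float(np.sum(1.0 - x / top) / (x.size - 1))


def tau_table(matrix: pd.DataFrame) -> pd.Series:
    """tau per gene for a genes x tissues expression matrix."""
    return pd.Series(
        {gene: tau(row.to_numpy()) for gene, row in matrix.iterrows()}, name="tau"
    )


def expression_breadth(
    profile: Sequence[float] | np.ndarray, presence_threshold: float = 0.0
) -> int:
    """Number of tissues with expression strictly above the threshold.

    The default threshold of 0 treats any signal as presence; detected /
    not-detected calls in expression atlases carry no universal cutoff, so
    it is configurable.
    """
    if presence_threshold < 0:
        raise ValueError("presence threshold must be >= 0")
    x = np.asarray(profile, dtype=float)
    return int(np.sum(x > presence_threshold))


def rank_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    mode: str = "rank-sum",
    exact_cutoff: int = EXACT_CUTOFF,
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank test between two groups.

    ``rank-sum`` (Mann-Whitney) compares independent groups; ``signed-rank``
    compares paired, equal-length vectors.  Exact p-values are used for
    small samples without ties (up to ``exact_cutoff`` per group), otherwise
    the normal approximation with tie correction.

    Returns ``(statistic, p)``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if mode == "rank-sum":
        if a.size == 0 or b.size == 0:
            raise ValueError("rank-sum test needs two non-empty groups")
        small = max(a.size, b.size) <= exact_cutoff
        ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
        method = "exact" if (small and not ties) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        return float(res.statistic), float(res.pvalue)
    if mode == "signed-rank":
        if a.size != b.size:
            raise ValueError("signed-rank test needs equal-length paired vectors")
        if a.size == 0:
            raise ValueError("signed-rank test needs non-empty vectors")
        diffs = a - b
        if np.all(diffs == 0):
            # no signal at all: the null cannot be rejected
            return 0.0, 1.0
        nonzero = diffs[diffs != 0]
        small = nonzero.size <= exact_cutoff
        ties = len(np.unique(np.abs(nonzero))) < nonzero.size
        method = "exact" if (small and not ties) else "approx"
        res = stats.wilcoxon(a, b, alternative="two-sided", method=method)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown mode {mode!r}; use 'rank-sum' or 'signed-rank'")


def element_partition(
    set_a: Iterable[str], set_b: Iterable[str]
) -> tuple[int, int, int]:
    """Partition two cis-element multisets into shared and copy-exclusive counts.

    Returns ``(shared, unique_a, unique_b)`` with multiset semantics: an
    element occurring twice in A and once in B contributes one shared and
    one A-exclusive count.
    """
    ca, cb = Counter(set_a), Counter(set_b)
    shared = sum((ca & cb).values())
    return shared, sum(ca.values()) - shared, sum(cb.values()) - shared


@dataclass(frozen=True)
class AncestralConfig:
    """Costs and tie-break policy for ancestral-state reconstruction.

    ``gain_cost`` (0 -> 1) must be at least ``loss_cost`` (1 -> 0): losses
    of expression are treated as the cheap, frequent event.  Ties are broken
    toward not-expressed by default — conservative about inferring gains.
    """

    gain_cost: float = 2.0
    loss_cost: float = 1.0
    tie_break: int = NOT_EXPRESSED

    def __post_init__(self) -> None:
        if self.gain_cost <= 0 or self.loss_cost <= 0:
            raise ValueError("gain and loss costs must be positive")
        if self.gain_cost < self.loss_cost:
            raise ValueError("gain cost must be >= loss cost (Dollo-leaning parsimony)")
        if self.tie_break not in (EXPRESSED, NOT_EXPRESSED):
            raise ValueError("tie_break must be 0 or 1")

    def edge_cost(self, parent_state: int, child_state: int) -> float:
        if parent_state == child_state:
            return 0.0
        return self.gain_cost if child_state == EXPRESSED else self.loss_cost


@dataclass
class AncestralStates:
    """Sankoff reconstruction result: states per node x organ plus DP costs."""

    states: pd.DataFrame  # node x organ, values 0/1 (or NaN for skipped organs)
    costs: dict[str, float]  # organ -> minimum labeling cost
    skipped_organs: list[str]


def reconstruct_ancestral_states(
    gene_tree: GeneTree,
    organ_states: pd.DataFrame,
    config: AncestralConfig | None = None,
) -> AncestralStates:
    """Minimum-cost ancestral expressed/not-expressed states per organ.

    ``organ_states`` is a genes x organs frame with values 1 (expressed),
    0 (not expressed) or NaN (no data).  Each organ is solved independently
    by Sankoff bottom-up/top-down dynamic programming under the asymmetric
    costs in ``config``; an organ with no observed state on any leaf is
    skipped with a warning.

    Returns states for every node (leaves echo their observations; missing
    leaf states are imputed by the DP) and the minimum cost per organ.
    """
    config = config or AncestralConfig()
    tree = gene_tree.tree
    leaf_labels = set(gene_tree.leaf_labels())
    unknown = set(organ_states.index) - leaf_labels
    if unknown:
        raise KeyError(f"organ-state rows not matching any leaf: {sorted(unknown)}")

    nodes = list(tree.preorder_node_iter())
    node_names = [node_name(n) for n in nodes]
    result = pd.DataFrame(index=node_names, columns=list(organ_states.columns), dtype=float)
    costs: dict[str, float] = {}
    skipped: list[str] = []

    for organ in organ_states.columns:
        observed = organ_states[organ].dropna()
        if observed.empty:
            warnings.warn(f"organ {organ!r}: all leaf states missing; skipped")
            skipped.append(organ)
            continue

        # bottom-up: cost[node][s] = min cost of the subtree given state s
        cost: dict[object, np.ndarray] = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                label = node.taxon.label
                value = organ_states[organ].get(label, np.nan) if label in organ_states.index else np.nan
                if pd.isna(value):
                    cost[node] = np.zeros(2)
                else:
                    state = int(value)
                    vec = np.full(2, np.inf)
                    vec[state] = 0.0
                    cost[node] = vec
            else:
                vec = np.zeros(2)
                for s in (0, 1):
                    for child in node.child_nodes():
                        vec[s] += min(
                            config.edge_cost(s, t) + cost[child][t] for t in (0, 1)
                        )
                cost[node] = vec

        # top-down: pick states, ties toward config.tie_break
        chosen: dict[object, int] = {}
        root = tree.seed_node
        root_costs = cost[root]
        if root_costs[config.tie_break] <= root_costs[1 - config.tie_break]:
            chosen[root] = config.tie_break
        else:
            chosen[root] = 1 - config.tie_break
        for node in tree.preorder_node_iter():
            if node is root:
                continue
            s = chosen[node.parent_node]
            totals = [config.edge_cost(s, t) + cost[node][t] for t in (0, 1)]
            if totals[config.tie_break] <= totals[1 - config.tie_break]:
                chosen[node] = config.tie_break
            else:
                chosen[node] = 1 - config.tie_break

        costs[organ] = float(min(root_costs))
        for node, name in zip(nodes, node_names):
            result.loc[name, organ] = chosen[node]

    return AncestralStates(states=result, costs=costs, skipped_organs=skipped)
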