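"""Independent brute-force oracles used to validate the implementation.

Each oracle solves its problem by exhaustive search or direct enumeration,
sharing no code with the implementation paths it checks.
"""

from __future__ import annotations

from itertools import combinations, product

from Bio.Seq import Seq

# ---------------------------------------------------------------------------
# exhaustive duplication/loss reconciliation


def enumerate_topologies(labels: list[str]):
    """All rooted binary leaf-labelled topologies as nested tuples."""
    if len(labels) == 1:
        yield labels[0]
        return
    first, rest = labels[0], labels[1:]
    # first label stays in the left subtree to avoid mirrored duplicates
    for k in range(0, len(rest)):
        for left_rest in combinations(rest, k):
            right = [x for x in rest if x not in left_rest]
            if not right:
                continue
            for lt in enumerate_topologies([first, *left_rest]):
                for rt in enumerate_topologies(right):
                    yield (lt, rt)


class SpeciesTreeTable:
    """Parent/descendant tables for a nested-tuple species tree."""

    def __init__(self, topology):
        self.parent = {}
        self.children = {}
        self.nodes = []

        def walk(node, par):
            self.nodes.append(node)
            self.parent[node] = par
            if isinstance(node, tuple):
                self.children[node] = list(node)
                for child in node:
                    walk(child, node)
            else:
                self.children[node] = []

        walk(topology, None)
        self.root = topology

    def ancestors_or_self(self, node):
        out = []
        while node is not None:
            out.append(node)
            node = self.parent[node]
        return out

    def is_ancestor_or_equal(self, anc, desc):
        return anc in self.ancestors_or_self(desc)

    def distance(self, anc, desc):
        d = 0
        while desc != anc:
            desc = self.parent[desc]
            d += 1
        return d

    def lca(self, a, b):
        anc_a = self.ancestors_or_self(a)
        while b is not None:
            if b in anc_a:
                return b
            b = self.parent[b]
        raise AssertionError("no LCA")

    def child_subtree_of(self, node, desc):
        """Which child of ``node`` contains ``desc`` (desc strictly below)."""
        for child in self.children[node]:
            if self.is_ancestor_or_equal(child, desc):
                return child
        return None


def min_dl_cost(gene_topology, leaf_species: dict, species_table: SpeciesTreeTable):
    """Minimum duplication + loss cost over all valid reconciliations.

    Enumerates every mapping of internal gene-tree nodes to species-tree
    nodes satisfying the ancestor constraint, classifies each internal node
    as speciation (children's images in distinct child subtrees of its own
    image) or duplication, adds the per-edge losses, and returns the
    minimum total cost.
    """
    internals = []
    leaves = []

    def collect(node):
        if isinstance(node, tuple):
            internals.append(node)
            for child in node:
                collect(child)
        else:
            leaves.append(node)

    collect(gene_topology)

    leaf_image = {leaf: leaf_species[leaf] for leaf in leaves}

    def subtree_species_lca(node):
        if not isinstance(node, tuple):
            return leaf_image[node]
        images = [subtree_species_lca(c) for c in node]
        out = images[0]
        for im in images[1:]:
            out = species_table.lca(out, im)
        return out

    candidates = {
        node: species_table.ancestors_or_self(subtree_species_lca(node))
        for node in internals
    }

    best = None
    for assignment in product(*(candidates[n] for n in internals)):
        mapping = dict(zip(internals, assignment))
        mapping.update(leaf_image)

        def image(n):
            return mapping[n]

        valid = True
        cost = 0
        for node in internals:
            for child in node:
                if not species_table.is_ancestor_or_equal(image(node), image(child)):
                    valid = False
                    break
            if not valid:
                break
        if not valid:
            continue
        for node in internals:
            c1, c2 = node
            sub1 = (
                species_table.child_subtree_of(image(node), image(c1))
                if image(c1) != image(node)
                else None
            )
            sub2 = (
                species_table.child_subtree_of(image(node), image(c2))
                if image(c2) != image(node)
                else None
            )
            is_speciation = sub1 is not None and sub2 is not None and sub1 != sub2
            if not is_speciation:
                cost += 1  # duplication
            for child in (c1, c2):
                d = species_table.distance(image(node), image(child))
                cost += d if not is_speciation else d - 1
        if best is None or cost < best:
            best = cost
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# NG86 brute force


def _translate(codon: str) -> str:
    return str(Seq(codon).translate())


def ng86_sites_bruteforce(codon: str) -> float:
    """Synonymous site count of one codon by direct neighbour enumeration."""
    syn = 0.0
    for pos in range(3):
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if _translate(alt) != "*" and _translate(alt) == _translate(codon):
                syn += 1.0 / 3.0
    return syn


def ng86_diffs_bruteforce(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(Sd, Nd) between two sense codons by DFS over all mutation paths."""
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return 0.0, 0.0

    completed: list[tuple[int, int]] = []

    def dfs(current: str, remaining: list[int], syn: int, non: int, allow_stop: bool):
        if not remaining:
            completed.append((syn, non))
            return
        for i, pos in enumerate(remaining):
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if _translate(nxt) == "*" and not allow_stop:
                continue
            step_syn = _translate(nxt) == _translate(current)
            dfs(
                nxt,
                remaining[:i] + remaining[i + 1 :],
                syn + step_syn,
                non + (not step_syn),
                allow_stop,
            )

    dfs(codon_a, diff, 0, 0, False)
    if not completed:
        dfs(codon_a, diff, 0, 0, True)
    s = sum(c[0] for c in completed) / len(completed)
    n = sum(c[1] for c in completed) / len(completed)
    return s, n


def ng86_bruteforce(seq_a: str, seq_b: str) -> tuple[float, float, float, float]:
    """(N, S, Nd, Sd) for a gap-free pair of sense-codon sequences."""
    assert len(seq_a) == len(seq_b) and len(seq_a) % 3 == 0
    s_sites = n_sites = sd = nd = 0.0
    ncodons = 0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
        if _translate(ca) == "*" or _translate(cb) == "*":
            continue
        ncodons += 1
        s_sites += (ng86_sites_bruteforce(ca) + ng86_sites_bruteforce(cb)) / 2.0
        ds, dn = ng86_diffs_bruteforce(ca, cb)
        sd += ds
        nd += dn
    n_sites = 3.0 * ncodons - s_sites
    return n_sites, s_sites, nd, sd


# ---------------------------------------------------------------------------
# Sankoff brute force


def sankoff_bruteforce(
    topology,
    leaf_states: dict,
    gain_cost: float,
    loss_cost: float,
) -> float:
    """Minimum labelling cost over all assignments of {0,1} to every node.

    ``leaf_states`` maps leaf name -> 0/1/None (None = missing, free).
    """
    internals = []
    leaves = []

    def collect(node):
        if isinstance(node, tuple):
            internals.append(node)
            for c in node:
                collect(c)
        else:
            leaves.append(node)

    collect(topology)

    free_leaves = [l for l in leaves if leaf_states.get(l) is None]
    all_free = internals + free_leaves
    # include the root explicitly if it is a single leaf
    if not internals and not free_leaves and len(leaves) == 1:
        return 0.0

    def edge_cost(parent_state, child_state):
        if parent_state == child_state:
            return 0.0
        return gain_cost if child_state == 1 else loss_cost

    best = float("inf")
    for states in product((0, 1), repeat=len(all_free)):
        label = dict(zip(all_free, states))
        for l in leaves:
            if leaf_states.get(l) is not None:
                label[l] = leaf_states[l]

        cost = 0.0

        def walk(node):
            nonlocal cost
            if isinstance(node, tuple):
                for child in node:
                    cost += edge_cost(label[node], label[child])
                    walk(child)

        walk(topology)
        best = min(best, cost)
    return best


# ---------------------------------------------------------------------------
# exact rank-sum test by enumeration


def ranksum_exact_p(a: list[float], b: list[float]) -> float:
    """Two-sided exact Mann-Whitney p by enumerating all group assignments.

    Assumes no ties across the pooled sample.
    """
    pooled = sorted(a + b)
    assert len(set(pooled)) == len(pooled), "oracle assumes no ties"
    rank = {v: i + 1 for i, v in enumerate(pooled)}
    n_a = len(a)

    def u_stat(group):
        r = sum(rank[v] for v in group)
        return r - n_a * (n_a + 1) / 2.0

    u_obs = u_stat(a)
    us = [
        sum(rank[pooled[i]] for i in comb) - n_a * (n_a + 1) / 2.0
        for comb in combinations(range(len(pooled)), n_a)
    ]
    total = len(us)
    p_le = sum(u <= u_obs for u in us) / total
    p_ge = sum(u >= u_obs for u in us) / total
    return min(1.0, 2.0 * min(p_le, p_ge))


def signed_rank_exact_p(diffs: list[float]) -> float:
    """Two-sided exact Wilcoxon signed-rank p by enumerating sign flips.

    Zero differences are dropped (the ``wilcox`` convention); assumes no
    ties among the absolute differences.
    """
    nonzero = [d for d in diffs if d != 0]
    if not nonzero:
        return 1.0
    mags = sorted(abs(d) for d in nonzero)
    assert len(set(mags)) == len(mags), "oracle assumes no tied magnitudes"
    rank = {m: i + 1 for i, m in enumerate(mags)}
    w_obs = sum(rank[abs(d)] for d in nonzero if d > 0)
    n = len(nonzero)
    ws = []
    for signs in product((0, 1), repeat=n):
        ws.append(sum(rank[abs(d)] * s for d, s in zip(nonzero, signs)))
    total = len(ws)
    p_le = sum(w <= w_obs for w in ws) / total
    p_ge = sum(w >= w_obs for w in ws) / total
    return min(1.0, 2.0 * min(p_le, p_ge))
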