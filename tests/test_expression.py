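import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paleologs import (
    AncestralConfig,
    GeneTree,
    element_partition,
    expression_breadth,
    rank_test,
    reconstruct_ancestral_states,
    tau,
)

from tests._oracles import ranksum_exact_p, sankoff_bruteforce, signed_rank_exact_p


class TestTau:
    @pytest.mark.parametrize(
        "profile,expected",
        [
            ((5, 5, 5, 5), 0.0),
            ((7, 0, 0, 0), 1.0),
            ((1, 0.5, 0), 0.75),
        ],
        ids=["uniform", "one-hot", "graded"],
    )
    def test_reference_values(self, profile, expected):
        assert tau(profile) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "bad", [(0, 0, 0), (5,), (1, -1, 2)], ids=["all-zero", "one-tissue", "negative"]
    )
    def test_invalid_profiles_rejected(self, bad):
        with pytest.raises(ValueError):
            tau(bad)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        st.lists(st.floats(0.0, 1e6), min_size=2, max_size=20).filter(
            lambda x: max(x) > 0
        ),
        st.floats(1e-3, 1e3),
    )
    def test_bounds_and_scale_invariance(self, profile, c):
        value = tau(profile)
        assert 0.0 <= value <= 1.0
        assert tau([c * x for x in profile]) == pytest.approx(value, abs=1e-9)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0.01, 100), min_size=2, max_size=12))
    def test_extremes_characterised(self, values):
        # uniform <=> 0
        assert tau([values[0]] * len(values)) == pytest.approx(0.0)
        # exactly one nonzero tissue <=> 1
        one_hot = [0.0] * len(values)
        one_hot[0] = values[0]
        assert tau(one_hot) == pytest.approx(1.0)


class TestBreadth:
    @pytest.mark.parametrize(
        "profile,threshold,expected",
        [((5, 5, 5, 5), 0, 4), ((7, 0, 0, 0), 0, 1), ((2, 0.5, 0), 1, 1)],
    )
    def test_counts_tissues_above_threshold(self, profile, threshold, expected):
        assert expression_breadth(profile, threshold) == expected


class TestRankTests:
    def test_rank_sum_exact_small_case(self):
        _, p = rank_test([1, 2], [3, 4])
        assert p == pytest.approx(1 / 3)

    def test_signed_rank_all_zero_differences(self):
        stat, p = rank_test([1, 2, 3], [1, 2, 3], mode="signed-rank")
        assert (stat, p) == (0.0, 1.0)

    def test_two_sided_symmetry(self, rng):
        a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 9)
        _, p_ab = rank_test(a, b)
        _, p_ba = rank_test(b, a)
        assert p_ab == pytest.approx(p_ba)

    def test_signed_rank_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            rank_test([1, 2], [1, 2, 3], mode="signed-rank")

    @pytest.mark.parametrize("n_a,n_b", [(2, 2), (3, 4), (5, 5), (4, 2)])
    def test_rank_sum_matches_enumeration_oracle(self, n_a, n_b, rng):
        """Exact rank-sum p equals full enumeration for all group sizes <= 5."""
        for trial in range(20):
            pooled = rng.choice(np.arange(1, 200), size=n_a + n_b, replace=False)
            a, b = list(pooled[:n_a].astype(float)), list(pooled[n_a:].astype(float))
            _, p = rank_test(a, b)
            assert p == pytest.approx(ranksum_exact_p(a, b))

    @pytest.mark.parametrize("n", [3, 5])
    def test_signed_rank_matches_enumeration_oracle(self, n, rng):
        for trial in range(20):
            mags = rng.choice(np.arange(1, 100), size=n, replace=False).astype(float)
            signs = rng.choice([-1.0, 1.0], size=n)
            diffs = mags * signs
            a = rng.normal(0, 1, n)
            b = a - diffs
            _, p = rank_test(list(a), list(b), mode="signed-rank")
            assert p == pytest.approx(signed_rank_exact_p(list(diffs)))


class TestElementPartition:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (["a", "b", "c"], ["c", "d"], (1, 2, 1)),
            (["a", "b"], ["a", "b"], (2, 0, 0)),
            (["a"], ["b"], (0, 1, 1)),
            (["a", "a", "b"], ["a"], (1, 2, 0)),
        ],
        ids=["overlap", "identical", "disjoint", "multiset"],
    )
    def test_shared_and_exclusive_counts(self, a, b, expected):
        assert element_partition(a, b) == expected


class TestAncestralStates:
    def tree(self, newick):
        return GeneTree.from_newick(newick)

    def states(self, genes, organs, data):
        return pd.DataFrame(data, index=genes, columns=organs, dtype=float)

    def test_all_expressed_everywhere(self):
        gt = self.tree("((g1,g2),(g3,g4));")
        m = self.states(["g1", "g2", "g3", "g4"], ["root", "leaf"], np.ones((4, 2)))
        res = reconstruct_ancestral_states(gt, m)
        assert (res.states == 1).all().all()
        assert res.costs == {"root": 0.0, "leaf": 0.0}

    def test_broad_ancestor_under_asymmetric_costs(self):
        """Two pairs of (all-organ, single-organ) duplicates: with gains twice
        the price of losses the crown ancestor is inferred expressed in all
        organs — the subfunctionalization reading."""
        gt = self.tree("((broad1,flower_only),(broad2,stem_only));")
        organs = ["flower", "stem", "leaf", "root"]
        m = self.states(
            ["broad1", "flower_only", "broad2", "stem_only"],
            organs,
            [
                [1, 1, 1, 1],
                [1, 0, 0, 0],
                [1, 1, 1, 1],
                [0, 1, 0, 0],
            ],
        )
        res = reconstruct_ancestral_states(gt, m, AncestralConfig(gain_cost=2, loss_cost=1))
        root_row = res.states.loc[res.states.index[0]]
        assert root_row.tolist() == [1.0, 1.0, 1.0, 1.0]

    def test_single_leaf_ancestor_equals_leaf(self):
        gt = self.tree("lone;")
        m = self.states(["lone"], ["flower"], [[1]])
        res = reconstruct_ancestral_states(gt, m)
        assert res.states["flower"].tolist() == [1.0]

    def test_missing_organ_skipped_with_warning(self):
        gt = self.tree("(g1,g2);")
        m = self.states(["g1", "g2"], ["a", "b"], [[1, np.nan], [0, np.nan]])
        with pytest.warns(UserWarning, match="'b'"):
            res = reconstruct_ancestral_states(gt, m)
        assert res.skipped_organs == ["b"]
        assert "b" not in res.costs

    def test_invalid_costs_rejected(self):
        with pytest.raises(ValueError):
            AncestralConfig(gain_cost=1, loss_cost=2)  # gains must cost >= losses
        with pytest.raises(ValueError):
            AncestralConfig(gain_cost=0, loss_cost=0)

    @pytest.mark.parametrize(
        "newick,leaves",
        [
            ("((a,b),(c,d));", "abcd"),
            ("(((a,b),(c,d)),((e,f),(g,h)));", "abcdefgh"),
            ("((a,(b,c)),d);", "abcd"),
        ],
    )
    def test_cost_matches_bruteforce(self, newick, leaves, rng):
        """Sankoff DP cost equals brute-force minimum over all labelings,
        including trees with missing leaf observations."""
        gt = self.tree(newick)

        def to_tuple(text):
            import re

            return eval(re.sub(r"([a-z]+)", r"'\1'", text.rstrip(";")))

        topo = to_tuple(newick)
        for trial in range(10):
            obs = {
                l: rng.choice([0.0, 1.0, np.nan], p=[0.4, 0.4, 0.2]) for l in leaves
            }
            if all(np.isnan(v) for v in obs.values()):
                continue
            m = pd.DataFrame({"organ": obs}).astype(float)
            res = reconstruct_ancestral_states(
                gt, m, AncestralConfig(gain_cost=2, loss_cost=1)
            )
            leaf_states = {
                l: (None if np.isnan(v) else int(v)) for l, v in obs.items()
            }
            expected = sankoff_bruteforce(topo, leaf_states, 2.0, 1.0)
            assert res.costs["organ"] == pytest.approx(expected)
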