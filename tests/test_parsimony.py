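"""Weighted-parsimony gain-loss mapping: worked examples, exhaustive oracle,
tie-breaking and monotonicity."""

import math

import numpy as np
import pytest

import mln
from conftest import (
    brute_force_min_cost,
    random_character,
    random_tree,
    replay_scenario,
)


@pytest.fixture
def count_column(fig2_tree, fig2_matrix):
    return dict(zip(fig2_matrix.taxa, fig2_matrix.column("lat")))


class TestWorkedExample:
    def test_two_gain_scenario_at_low_penalty(self, fig2_tree, count_column):
        sc = mln.sankoff_gain_loss(count_column, fig2_tree, mln.CostScheme(1.0), "lat")
        assert set(sc.gains) == {"English", "N5"}
        assert sc.losses == ()
        assert sc.cost == pytest.approx(2.0)

    def test_loss_only_scenario_at_high_penalty(self, fig2_tree, count_column):
        # cost 5 = one root gain (3) + losses in German and Danish (2),
        # beating two gains at cost 6; brute force confirms 5 is minimal
        sc = mln.sankoff_gain_loss(count_column, fig2_tree, mln.CostScheme(3.0), "lat")
        assert sc.gains == ("N0",)
        assert set(sc.losses) == {"German", "Danish"}
        assert sc.cost == pytest.approx(5.0)
        assert brute_force_min_cost(fig2_tree, count_column, 3.0, 1.0) == pytest.approx(5.0)

    def test_ubiquitous_character_gets_root_gain(self, fig2_tree):
        col = {t: mln.PRESENT for t in fig2_tree.taxa}
        for g in (0.5, 1.0, 7.0):
            sc = mln.sankoff_gain_loss(col, fig2_tree, mln.CostScheme(g))
            assert sc.gains == ("N0",) and sc.losses == ()
            assert sc.cost == pytest.approx(g)


class TestOracleAgreement:
    @pytest.mark.parametrize("seed", range(10))
    def test_dp_cost_matches_exhaustive_minimum(self, seed):
        rng = np.random.default_rng(100 + seed)
        tree = random_tree(rng, n_leaves=int(rng.integers(2, 9)))
        for _ in range(6):
            col = random_character(rng, tree.taxa)
            g = float(rng.choice([0.5, 1.0, 1.7, 3.0]))
            sc = mln.sankoff_gain_loss(col, tree, mln.CostScheme(g))
            assert sc.cost == pytest.approx(
                brute_force_min_cost(tree, col, g, 1.0)
            )

    @pytest.mark.parametrize("seed", range(10))
    def test_scenarios_regenerate_observed_states(self, seed):
        rng = np.random.default_rng(200 + seed)
        tree = random_tree(rng, n_leaves=int(rng.integers(2, 11)))
        for _ in range(6):
            col = random_character(rng, tree.taxa)
            sc = mln.sankoff_gain_loss(col, tree, mln.CostScheme(1.5))
            replayed = replay_scenario(tree, sc)
            for t in tree.taxa:
                if col[t] != mln.MISSING:
                    assert replayed[t] == col[t]
                else:
                    assert replayed[t] == sc.imputed[t]


class TestTieBreaking:
    def test_equal_cost_prefers_fewer_gains(self, fig2_tree, fig2_matrix):
        # at gain_cost 1 the Germanic set ties: two leaf gains vs one clade
        # gain plus an English loss, both cost 2 — fewer gains must win
        col = dict(zip(fig2_matrix.taxa, fig2_matrix.column("germ")))
        sc = mln.sankoff_gain_loss(col, fig2_tree, mln.CostScheme(1.0), "germ")
        assert sc.gains == ("N1",)
        assert sc.losses == ("English",)

    def test_gains_pushed_toward_root_on_exact_tie(self):
        # present in both leaves of a cherry inside a larger tree: a single
        # gain can sit at the cherry ancestor or deeper; the shallowest
        # admissible node must be chosen deterministically
        tree = mln.read_newick("((A,B),(C,D));")
        col = {"A": 1, "B": 1, "C": 0, "D": 0}
        sc = mln.sankoff_gain_loss(col, tree, mln.CostScheme(1.0))
        assert sc.gains == ("N1",)

    def test_missing_leaves_are_imputed_at_zero_cost(self, fig2_tree):
        col = {"German": 1, "English": -1, "Danish": 1,
               "French": 0, "Italian": 0, "Spanish": 0}
        sc = mln.sankoff_gain_loss(col, fig2_tree, mln.CostScheme(2.0))
        # imputing English present avoids any loss: one clade gain only
        assert sc.imputed == {"English": 1}
        assert sc.gains == ("N1",) and sc.losses == ()
        assert sc.cost == pytest.approx(2.0)


class TestMapAll:
    def test_grid_of_two_schemes_on_worked_example(self, fig2_tree, fig2_matrix):
        grid = [mln.CostScheme(1.0), mln.CostScheme(3.0)]
        ss = mln.map_all(fig2_matrix, fig2_tree, grid)
        assert len(ss.at_scheme(grid[0])) == 2
        assert ss[("lat", grid[0])].n_gains == 2
        assert ss[("lat", grid[1])].n_gains == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_total_gains_non_increasing_in_gain_cost(self, seed):
        rng = np.random.default_rng(300 + seed)
        tree = random_tree(rng, n_leaves=8)
        cols, chars = [], []
        for i in range(40):
            col = random_character(rng, tree.taxa)
            chars.append(mln.Character(f"c{i}"))
            cols.append([col[t] for t in tree.taxa])
        m = mln.CharacterMatrix(tree.taxa, chars, np.array(cols, dtype=np.int8))
        grid = mln.default_grid()
        ss = mln.map_all(m, tree, grid)
        totals = [ss.total_gains(s) for s in grid]
        assert all(a >= b for a, b in zip(totals, totals[1:]))
        # per-character monotonicity as well
        for cid in m.character_ids:
            gains = [ss[(cid, s)].n_gains for s in grid]
            assert all(a >= b for a, b in zip(gains, gains[1:]))

    def test_high_penalty_forces_single_origins(self, fig2_tree, fig2_matrix):
        bound = mln.CostScheme(1.0 + len(fig2_tree.taxa))
        ss = mln.map_all(fig2_matrix, fig2_tree, [bound])
        assert all(s.n_gains == 1 for s in ss.at_scheme(bound))

    def test_infinite_penalty_forces_single_origins(self, fig2_tree, fig2_matrix):
        scheme = mln.CostScheme(math.inf)
        ss = mln.map_all(fig2_matrix, fig2_tree, [scheme])
        assert all(s.n_gains == 1 for s in ss.at_scheme(scheme))

    def test_single_leaf_tree(self):
        tree = mln.read_newick("A;")
        m = mln.CharacterMatrix(
            ["A"], [mln.Character("c")], np.array([[1]], dtype=np.int8)
        )
        ss = mln.map_all(m, tree, [mln.CostScheme(2.0)])
        (sc,) = ss.at_scheme(mln.CostScheme(2.0))
        assert sc.gains == ("A",) and sc.losses == ()

    def test_errors(self, fig2_tree, fig2_matrix):
        with pytest.raises(mln.ScenarioError, match="empty"):
            mln.map_all(fig2_matrix, fig2_tree, [])
        other = mln.CharacterMatrix(
            ["X"], [mln.Character("c")], np.array([[1]], dtype=np.int8)
        )
        with pytest.raises(mln.ScenarioError, match="differ"):
            mln.map_all(other, fig2_tree, [mln.CostScheme(1.0)])
        with pytest.raises(mln.ScenarioError, match="no present"):
            mln.sankoff_gain_loss(
                {t: mln.ABSENT for t in fig2_tree.taxa}, fig2_tree, mln.CostScheme(1.0)
            )
        with pytest.raises(mln.ScenarioError, match="no present"):
            mln.sankoff_gain_loss(
                {t: mln.MISSING for t in fig2_tree.taxa}, fig2_tree, mln.CostScheme(1.0)
            )

    def test_scenario_dump_is_machine_readable(self, fig2_tree, fig2_matrix):
        grid = [mln.CostScheme(1.0), mln.CostScheme(3.0)]
        lines = mln.map_all(fig2_matrix, fig2_tree, grid).to_tsv().strip().splitlines()
        assert lines[0].split("\t") == [
            "CHAR", "GAIN_COST", "LOSS_COST", "GAINS", "LOSSES", "COST", "FLAG",
        ]
        assert len(lines) == 1 + 2 * 2


class TestScenarioInvariants:
    @pytest.mark.parametrize("seed", range(4))
    def test_gain_loss_structure(self, seed):
        """Every scenario has >= 1 gain, cost = g*|gains| + l*|losses|, no node
        both gain and loss, and each maximal present-subtree has exactly one
        gain at its top."""
        rng = np.random.default_rng(400 + seed)
        tree = random_tree(rng, n_leaves=9)
        for _ in range(10):
            col = random_character(rng, tree.taxa)
            g = float(rng.choice([1.0, 2.0]))
            sc = mln.sankoff_gain_loss(col, tree, mln.CostScheme(g))
            assert sc.n_gains >= 1
            assert sc.cost == pytest.approx(g * sc.n_gains + sc.n_losses)
            assert not (set(sc.gains) & set(sc.losses))
            for label in sc.gains:
                node = tree[label]
                assert sc.states[label] == 1
                if node.parent is not None:
                    assert sc.states[node.parent.label] == 0
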