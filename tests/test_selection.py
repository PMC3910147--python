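"""Ancestral size profiles, scheme selection and the parallel-evolution
allowance."""

import math

import numpy as np
import pytest

import mln
from conftest import random_character, random_tree


@pytest.fixture
def fig2_scenarios(fig2_tree, fig2_matrix):
    grid = [mln.CostScheme(1.0), mln.CostScheme(3.0)]
    return grid, mln.map_all(fig2_matrix, fig2_tree, grid)


class TestSizeProfile:
    def test_loss_only_scheme_inflates_the_germanic_ancestor(
        self, fig2_tree, fig2_matrix, fig2_scenarios
    ):
        """Under the rejected loss-only mapping the Germanic ancestor must
        carry two synonyms for 'to count'."""
        grid, ss = fig2_scenarios
        prof = mln.size_profile(ss.at_scheme(grid[1]), fig2_tree, fig2_matrix)
        assert prof.node_totals["N1"] == 2
        assert prof.concept_counts.loc["N1", "to count"] == 2

    def test_two_gain_scheme_balances_synonym_counts(
        self, fig2_tree, fig2_matrix, fig2_scenarios
    ):
        """Under the preferred two-gain mapping every ancestral language holds
        at most one sampled word for the concept — in balance with the
        moderns, which all hold exactly one."""
        grid, ss = fig2_scenarios
        prof = mln.size_profile(ss.at_scheme(grid[0]), fig2_tree, fig2_matrix)
        internal = prof.concept_counts.loc[list(prof.internal_labels)]
        assert internal.to_numpy().max() == 1
        for taxon in fig2_tree.taxa:
            assert prof.node_totals[taxon] == 1

    def test_leaf_entries_equal_observed_counts_at_any_scheme(
        self, fig2_tree, fig2_matrix, fig2_scenarios
    ):
        grid, ss = fig2_scenarios
        leaf = mln.leaf_profile(fig2_matrix, fig2_tree)
        for scheme in grid:
            prof = mln.size_profile(ss.at_scheme(scheme), fig2_tree, fig2_matrix)
            for t in fig2_tree.taxa:
                assert prof.node_totals[t] == leaf.node_totals[t]

    def test_empty_character_set_gives_zero_profile(self, fig2_tree):
        m = mln.CharacterMatrix(fig2_tree.taxa, [], np.zeros((0, 6), np.int8))
        prof = mln.size_profile([], fig2_tree, m)
        assert (prof.node_totals == 0).all()

    def test_scenario_matrix_mismatch_raises(self, fig2_tree, fig2_matrix, fig2_scenarios):
        grid, ss = fig2_scenarios
        other = mln.CharacterMatrix(
            fig2_tree.taxa,
            [mln.Character("zzz", "x")],
            np.array([[1, 0, 0, 0, 0, 0]], dtype=np.int8),
        )
        with pytest.raises(ValueError, match="cover"):
            mln.size_profile(ss.at_scheme(grid[0]), fig2_tree, other)

    def test_per_concept_counts_sum_to_node_totals(self, fig2_tree, fig2_matrix, fig2_scenarios):
        grid, ss = fig2_scenarios
        prof = mln.size_profile(ss.at_scheme(grid[0]), fig2_tree, fig2_matrix)
        assert (prof.concept_counts.sum(axis=1) == prof.node_totals).all()


class TestSelectScheme:
    def test_worked_example_prefers_the_two_gain_scheme(
        self, fig2_tree, fig2_matrix, fig2_scenarios
    ):
        grid, ss = fig2_scenarios
        report, profiles = mln.select_scheme(ss, fig2_matrix, mode="language")
        assert report.selected == grid[0]
        assert report.row_for(grid[0]).distance == pytest.approx(0.0)
        assert report.row_for(grid[1]).distance > 0
        assert report.row_for(grid[0]).total_lateral_events == 1

    def test_single_scheme_is_selected(self, fig2_tree, fig2_matrix):
        grid = [mln.CostScheme(2.0)]
        ss = mln.map_all(fig2_matrix, fig2_tree, grid)
        report, _ = mln.select_scheme(ss, fig2_matrix, mode="language")
        assert report.selected == grid[0]

    def test_identical_profiles_resolved_by_fewer_lateral_events(self, fig2_tree):
        # a single tree-compatible character: every scheme maps it to one
        # clade gain, profiles coincide, and the degenerate rule returns the
        # largest penalty (which also has minimal lateral events) flagged
        m = mln.CharacterMatrix(
            fig2_tree.taxa,
            [mln.Character("g", "hand")],
            np.array([[1, 1, 1, 0, 0, 0]], dtype=np.int8),
        )
        grid = [mln.CostScheme(1.5), mln.CostScheme(3.0)]
        ss = mln.map_all(m, fig2_tree, grid)
        report, _ = mln.select_scheme(ss, m, mode="language")
        assert report.selected == grid[1]
        assert report.warning is not None
        events = [r.total_lateral_events for r in report.rows]
        assert report.row_for(report.selected).total_lateral_events == min(events)

    def test_selected_scheme_minimizes_lateral_events_at_equal_distance(
        self, fig2_tree, fig2_matrix
    ):
        ss = mln.map_all(fig2_matrix, fig2_tree, mln.default_grid())
        report, _ = mln.select_scheme(ss, fig2_matrix, mode="language")
        dsel = report.row_for(report.selected).distance
        esel = report.row_for(report.selected).total_lateral_events
        for r in report.rows:
            if abs(r.distance - dsel) <= 1e-9:
                assert esel <= r.total_lateral_events

    def test_genome_mode_pools_node_totals(self, fig2_tree):
        # no concepts: language mode must refuse, genome mode must work
        m = mln.CharacterMatrix(
            fig2_tree.taxa,
            [mln.Character("g1"), mln.Character("g2")],
            np.array([[1, 1, 1, 0, 0, 0], [0, 1, 0, 1, 1, 1]], dtype=np.int8),
        )
        ss = mln.map_all(m, fig2_tree, [mln.CostScheme(1.0), mln.CostScheme(3.0)])
        with pytest.raises(ValueError, match="concept"):
            mln.select_scheme(ss, m, mode="language")
        report, _ = mln.select_scheme(ss, m, mode="genome")
        assert report.selected in [r.scheme for r in report.rows]

    def test_ancestral_totals_grow_toward_the_single_origin_extreme(self):
        """As the gain penalty rises, inferred ancestral inventories are
        (weakly) monotone non-decreasing: forcing single origins piles
        characters onto deep nodes."""
        tree = mln.random_ultrametric_tree(10, seed=7, depth=3.0)
        params = mln.SimulationParams(
            tree=tree, n_concepts=80, replacement_rate=0.5,
            borrowing_rate=0.4, seed=7,
        )
        _, matrix, _ = mln.simulate(params)
        grid = mln.default_grid()
        ss = mln.map_all(matrix, tree, grid)
        totals = []
        for scheme in grid:
            prof = mln.size_profile(ss.at_scheme(scheme), tree, matrix)
            totals.append(
                prof.node_totals.loc[list(prof.internal_labels)].sum()
            )
        assert all(a <= b for a, b in zip(totals, totals[1:]))

    def test_mannwhitney_statistic_available(self, fig2_tree, fig2_matrix, fig2_scenarios):
        grid, ss = fig2_scenarios
        report, _ = mln.select_scheme(
            ss, fig2_matrix, mode="language", statistic="mannwhitney"
        )
        assert report.selected in grid


class TestParallelAllowance:
    def _multi_gain_setup(self, seed=11, n_chars=60):
        rng = np.random.default_rng(seed)
        tree = random_tree(rng, n_leaves=8, polytomies=False)
        cols, chars = [], []
        for i in range(n_chars):
            col = random_character(rng, tree.taxa, p_missing=0.0)
            chars.append(mln.Character(f"c{i}", f"con{i}"))
            cols.append([col[t] for t in tree.taxa])
        m = mln.CharacterMatrix(tree.taxa, chars, np.array(cols, dtype=np.int8))
        scheme = mln.CostScheme(1.0)
        ss = mln.map_all(m, tree, [scheme])
        return tree, m, scheme, ss

    def test_fraction_zero_flags_nothing(self):
        _, _, scheme, ss = self._multi_gain_setup()
        flagged = mln.apply_parallel_allowance(ss, scheme, 0.0)
        assert all(s.flag == mln.BORROWING_CANDIDATE for s in flagged)

    def test_fraction_one_collapses_network_to_tree(self):
        tree, _, scheme, ss = self._multi_gain_setup()
        flagged = mln.apply_parallel_allowance(ss, scheme, 1.0)
        multi = [s for s in flagged if s.is_multi_origin]
        assert multi and all(s.flag == mln.PARALLEL_CANDIDATE for s in multi)
        net = mln.build_mln(flagged, tree)
        assert net.lateral_edges == []

    def test_flag_count_is_floor_of_fraction(self):
        _, _, scheme, ss = self._multi_gain_setup()
        n_multi = sum(1 for s in ss.at_scheme(scheme) if s.is_multi_origin)
        assert n_multi >= 10
        flagged = mln.apply_parallel_allowance(ss, scheme, 0.2)
        n_parallel = sum(1 for s in flagged if s.flag == mln.PARALLEL_CANDIDATE)
        assert n_parallel == math.floor(0.2 * n_multi)

    def test_adjacent_origins_ranked_most_parallel_like(self):
        # two two-gain characters with origins at {A, E} and {A, D}:
        # patristic distances 5 vs 6, so with an allowance of half the
        # multi-origin characters only the closer pair is called parallel
        tree = mln.read_newick("(((A:1,B:1):1,C:2):1,(D:2,E:1):1);")
        chars = [mln.Character("near", "x"), mln.Character("far", "y")]
        #                  A  B  C  D  E
        states = np.array([[1, 0, 0, 0, 1], [1, 0, 0, 1, 0]], dtype=np.int8)
        m = mln.CharacterMatrix(tree.taxa, chars, states)
        scheme = mln.CostScheme(1.0)
        ss = mln.map_all(m, tree, [scheme])
        assert all(s.n_gains == 2 for s in ss.at_scheme(scheme))
        flagged = mln.apply_parallel_allowance(ss, scheme, 0.5)
        flags = {s.char_id: s.flag for s in flagged}
        assert flags["near"] == mln.PARALLEL_CANDIDATE
        assert flags["far"] == mln.BORROWING_CANDIDATE

    def test_invalid_fraction_rejected(self):
        _, _, scheme, ss = self._multi_gain_setup()
        with pytest.raises(ValueError, match="fraction"):
            mln.apply_parallel_allowance(ss, scheme, 1.2)
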