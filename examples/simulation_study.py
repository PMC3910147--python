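"""Validate detection on simulated borrowing with known ground truth.

Simulates 300 concepts on a 12-leaf ultrametric tree with replacement and
borrowing, runs the full inference, and scores the multi-origin flags
against the recorded borrowing events: how many borrowings were detectable
in principle (patchy patterns), how many of those were found, and how often
non-borrowed characters were wrongly flagged.
"""

import mln

tree = mln.random_ultrametric_tree(12, seed=2024, depth=1.0)
params = mln.SimulationParams(
    tree=tree,
    n_concepts=300,
    replacement_rate=0.3,  # per concept per lineage per unit time
    borrowing_rate=0.1,
    p_syn=0.5,
    seed=11,
)
wordlist, matrix, truth = mln.simulate(params)
print(
    f"simulated {len(wordlist)} words -> {matrix.n_characters} cognate sets, "
    f"{len(truth.events)} borrowing events "
    f"({len(truth.borrowed_characters())} sets carry a surviving borrowing)\n"
)

scenario_set = mln.map_all(matrix, tree, mln.default_grid())
report, _ = mln.select_scheme(scenario_set, matrix, mode="language")
sel = report.selected
print(
    f"selected gain penalty: {sel.gain_cost:g} "
    f"({report.row_for(sel).total_lateral_events} lateral events, "
    f"KS distance {report.row_for(sel).distance:.3f})"
)

flagged = mln.apply_parallel_allowance(scenario_set, sel, 0.0)
network = mln.build_mln(flagged, tree)
summary = mln.summarize(network, matrix)
print(
    f"network: {summary.n_lateral_edges} lateral edges, total weight "
    f"{summary.total_lateral_weight:.1f}; {summary.n_multi_origin} of "
    f"{summary.n_characters} characters multi-origin "
    f"({100 * summary.proportion_multi_origin:.1f}%)\n"
)

metrics = mln.evaluate_detection(network, flagged, truth, matrix)
print(f"detectability classes: {metrics.class_counts}")
print(
    f"{metrics.n_borrowed} borrowed sets: {metrics.n_borrowed_detectable} "
    f"patchy (detectable), {metrics.n_borrowed_undetectable} singleton/"
    "tree-compatible (invisible to any pattern-based method)"
)
print(
    f"recall on detectable borrowings: {metrics.recall_detectable:.2f}; "
    f"false-flag rate on non-borrowed sets: {metrics.false_flag_rate:.3f}"
)
print(
    "\nA recall below one is expected: the selection deliberately prefers\n"
    "the fewest lateral events compatible with balanced ancestral\n"
    "inventories, so weakly supported borrowings are absorbed into\n"
    "vertical explanations rather than over-called."
)
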