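"""Shared fixtures: the six-language worked example and small random-instance
generators with an exhaustive parsimony oracle."""

from __future__ import annotations

import numpy as np
import pytest

import mln

FIG2_NEWICK = "((German,English,Danish),(French,Italian,Spanish));"

# Two cognate sets for "to count": the Latin-derived set (English borrowed
# from Old French) and the Germanic *tal- set.
FIG2_WORDLIST = (
    "ID\tDOCULECT\tCONCEPT\tFORM\tCOGID\n"
    "1\tEnglish\tto count\tcount\tlat\n"
    "2\tFrench\tto count\tcompter\tlat\n"
    "3\tItalian\tto count\tcontare\tlat\n"
    "4\tSpanish\tto count\tcontar\tlat\n"
    "5\tGerman\tto count\tzaehlen\tgerm\n"
    "6\tDanish\tto count\ttaelle\tgerm\n"
)


@pytest.fixture
def fig2_tree() -> mln.ReferenceTree:
    return mln.read_newick(FIG2_NEWICK)


@pytest.fixture
def fig2_wordlist() -> mln.Wordlist:
    return mln.read_wordlist(FIG2_WORDLIST)


@pytest.fixture
def fig2_matrix(fig2_tree, fig2_wordlist) -> mln.CharacterMatrix:
    return mln.to_character_matrix(fig2_wordlist, fig2_tree.taxa)


def random_tree(
    rng: np.random.Generator, n_leaves: int, polytomies: bool = True
) -> mln.ReferenceTree:
    """Random rooted tree (not necessarily binary or ultrametric) with random
    branch lengths, built by merging 2-3 subtrees at a time."""
    nodes = [mln.Node(label=f"T{i + 1}") for i in range(n_leaves)]
    while len(nodes) > 1:
        k = int(rng.integers(2, 4)) if (polytomies and len(nodes) > 2) else 2
        k = min(k, len(nodes))
        picks = sorted(rng.choice(len(nodes), size=k, replace=False))
        parent = mln.Node(label="")
        for i in picks:
            child = nodes[i]
            child.parent = parent
            child.length = float(np.round(rng.uniform(0.1, 2.0), 3))
            parent.children.append(child)
        nodes = [n for i, n in enumerate(nodes) if i not in picks] + [parent]
    return mln.ReferenceTree(nodes[0])


def random_character(
    rng: np.random.Generator, taxa: list[str], p_missing: float = 0.15
) -> dict[str, int]:
    """Random leaf-state column with at least one present taxon."""
    while True:
        states = {}
        for t in taxa:
            u = rng.random()
            if u < p_missing:
                states[t] = mln.MISSING
            elif u < p_missing + (1 - p_missing) * 0.5:
                states[t] = mln.ABSENT
            else:
                states[t] = mln.PRESENT
        if any(s == mln.PRESENT for s in states.values()):
            return states


def brute_force_min_cost(
    tree: mln.ReferenceTree,
    column: dict[str, int],
    gain_cost: float,
    loss_cost: float,
) -> float:
    """Exhaustive minimum over all ancestral-state assignments (and all states
    of missing leaves).  Root presence is one gain; transitions along edges
    cost gain_cost (0->1) or loss_cost (1->0).  Independent of the dynamic
    program it checks."""
    free = [n.label for n in tree.internal_nodes] + [
        t for t in tree.taxa if column[t] == mln.MISSING
    ]
    fixed = {t: s for t, s in column.items() if s != mln.MISSING}
    n_assign = 2 ** len(free)
    # enumerate every assignment as a bit matrix, one column per free node
    bits = (np.arange(n_assign)[:, None] >> np.arange(len(free))) & 1
    states = {lab: bits[:, i] for i, lab in enumerate(free)}
    for lab, s in fixed.items():
        states[lab] = np.full(n_assign, s)
    cost = gain_cost * states[tree.root.label].astype(float)
    for node in tree.preorder():
        if node.parent is None:
            continue
        ps, cs = states[node.parent.label], states[node.label]
        cost = cost + gain_cost * ((ps == 0) & (cs == 1)) + loss_cost * (
            (ps == 1) & (cs == 0)
        )
    return float(cost.min())


def replay_scenario(
    tree: mln.ReferenceTree, scenario: mln.GainLossScenario
) -> dict[str, int]:
    """Re-simulate the scenario's gains and losses down the tree and return
    the implied leaf states."""
    gains, losses = set(scenario.gains), set(scenario.losses)
    state: dict[str, int] = {}
    for node in tree.preorder():
        inherited = 0 if node.parent is None else state[node.parent.label]
        if node.label in gains:
            assert inherited == 0, "gain at an already-present node"
            state[node.label] = 1
        elif node.label in losses:
            assert inherited == 1, "loss at an already-absent node"
            state[node.label] = 0
        else:
            state[node.label] = inherited
    return {t: state[t] for t in tree.taxa}
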