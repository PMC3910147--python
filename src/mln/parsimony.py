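"""Weighted-parsimony gain-loss mapping of binary characters on a rooted tree.

For each character, a gain-loss scenario assigns presence/absence to every
internal node so that the observed leaf pattern is explained by gain events
(0 -> 1 along a branch, penalty ``gain_cost``) and loss events (1 -> 0,
penalty ``loss_cost``, the fixed reference of 1).  Presence at the root
counts as one gain — the character originated on the root stem.  Low gain
penalties favour multiple independent origins (the lateral extreme); high
penalties force a single origin with compensating losses (the vertical
extreme).  Sweeping a grid of penalties spans the continuum between the two,
and a separate selection step picks the penalty whose ancestral inventories
best match the contemporary ones.

The reconstruction is the classic two-state Sankoff dynamic program
(post-order cost tables, pre-order backtrace), vectorized over characters.
Ties are broken deterministically: among equal-cost scenarios the one with
fewer gains wins, and among those the backtrace places presence at the
shallowest admissible node, pushing gains toward the root — the choice that
maximizes the vertical component of the explanation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .characters import ABSENT, MISSING, PRESENT, CharacterMatrix
from .tree import ReferenceTree

__all__ = [
    "CostScheme",
    "GainLossScenario",
    "ScenarioSet",
    "ScenarioError",
    "DEFAULT_GAIN_COSTS",
    "default_grid",
    "sankoff_gain_loss",
    "map_all",
    "BORROWING_CANDIDATE",
    "PARALLEL_CANDIDATE",
]

_EPS = 1e-9
_INF = 1e18

BORROWING_CANDIDATE = "borrowing_candidate"
PARALLEL_CANDIDATE = "parallel_candidate"

#: default gain-penalty ladder; ``inf`` forces single-origin scenarios
DEFAULT_GAIN_COSTS: tuple[float, ...] = (1.0, 1.5, 2.0, 2.5, 3.0, 4.0, 6.0, math.inf)


class ScenarioError(ValueError):
    pass


@dataclass(frozen=True, order=True)
class CostScheme:
    """Asymmetric penalty pair for the two-state parsimony.

    ``gain_cost`` is the penalty of a 0 -> 1 transition relative to the loss
    penalty (fixed reference 1).  ``math.inf`` is accepted and forces
    single-origin scenarios; internally it is replaced by the finite bound
    ``loss_cost * (n_leaves + 1)``, above which a root gain plus losses always
    beats any second gain.
    """

    gain_cost: float
    loss_cost: float = 1.0

    def __post_init__(self) -> None:
        if not self.gain_cost > 0:
            raise ScenarioError(f"gain_cost must be > 0, got {self.gain_cost}")
        if not self.loss_cost > 0:
            raise ScenarioError(f"loss_cost must be > 0, got {self.loss_cost}")

    def effective_gain_cost(self, n_leaves: int) -> float:
        if math.isinf(self.gain_cost):
            return self.loss_cost * (n_leaves + 1)
        return self.gain_cost

    def label(self) -> str:
        g = "inf" if math.isinf(self.gain_cost) else f"{self.gain_cost:g}"
        return f"g{g}_l{self.loss_cost:g}"


def default_grid(loss_cost: float = 1.0) -> list[CostScheme]:
    return [CostScheme(g, loss_cost) for g in DEFAULT_GAIN_COSTS]


@dataclass(frozen=True)
class GainLossScenario:
    """Minimum-cost gain-loss explanation of one character.

    ``states`` maps every node label (internal and leaf) to 0/1; missing
    leaves appear additionally in ``imputed`` with the state the backtrace
    chose for them at zero cost.  ``gains`` are nodes present while the
    parent is absent (the root counts when present); ``losses`` the reverse.
    """

    char_id: str
    scheme: CostScheme
    states: Mapping[str, int]
    gains: tuple[str, ...]
    losses: tuple[str, ...]
    cost: float
    imputed: Mapping[str, int] = field(default_factory=dict)
    flag: str = BORROWING_CANDIDATE

    @property
    def n_gains(self) -> int:
        return len(self.gains)

    @property
    def n_losses(self) -> int:
        return len(self.losses)

    @property
    def lateral_events(self) -> int:
        """Transfers implied beyond the first origin: max(0, gains - 1)."""
        return max(0, self.n_gains - 1)

    @property
    def is_multi_origin(self) -> bool:
        return self.n_gains >= 2


def _sankoff_states(
    tree: ReferenceTree,
    leaf_states: np.ndarray,
    gain_cost: float,
    loss_cost: float,
) -> np.ndarray:
    """Vectorized Sankoff over characters.

    ``leaf_states``: (n_leaves, n_chars) int array aligned with ``tree.taxa``,
    entries PRESENT/ABSENT/MISSING.  Returns (n_nodes, n_chars) 0/1 states in
    tree preorder.
    """
    n_nodes = len(tree.nodes)
    n_chars = leaf_states.shape[1]
    leaf_row = {t: i for i, t in enumerate(tree.taxa)}

    cost = np.zeros((n_nodes, 2, n_chars))
    gains = np.zeros((n_nodes, 2, n_chars), dtype=np.int32)

    for node in tree.postorder():
        i = node.index
        if node.is_leaf:
            obs = leaf_states[leaf_row[node.label]]
            cost[i, 0] = np.where((obs == ABSENT) | (obs == MISSING), 0.0, _INF)
            cost[i, 1] = np.where((obs == PRESENT) | (obs == MISSING), 0.0, _INF)
        else:
            for s in (0, 1):
                tot_c = np.zeros(n_chars)
                tot_g = np.zeros(n_chars, dtype=np.int64)
                for child in node.children:
                    j = child.index
                    c0 = cost[j, 0] + (loss_cost if s == 1 else 0.0)
                    g0 = gains[j, 0]
                    c1 = cost[j, 1] + (gain_cost if s == 0 else 0.0)
                    g1 = gains[j, 1] + (1 if s == 0 else 0)
                    pick1 = (c1 < c0 - _EPS) | (
                        (np.abs(c1 - c0) <= _EPS) & (g1 < g0)
                    )
                    tot_c += np.where(pick1, c1, c0)
                    tot_g += np.where(pick1, g1, g0)
                cost[i, s] = tot_c
                gains[i, s] = tot_g

    states = np.zeros((n_nodes, n_chars), dtype=np.int8)
    r = tree.root.index
    c0, g0 = cost[r, 0], gains[r, 0]
    c1, g1 = cost[r, 1] + gain_cost, gains[r, 1] + 1
    # tie on (cost, gains) -> present: gains sit as close to the root as possible
    states[r] = (c1 < c0 - _EPS) | ((np.abs(c1 - c0) <= _EPS) & (g1 <= g0))
    for node in tree.preorder():
        if node.parent is None:
            continue
        i = node.index
        s = states[node.parent.index]
        c0 = cost[i, 0] + np.where(s == 1, loss_cost, 0.0)
        g0 = gains[i, 0]
        c1 = cost[i, 1] + np.where(s == 0, gain_cost, 0.0)
        g1 = gains[i, 1] + (s == 0)
        states[i] = (c1 < c0 - _EPS) | ((np.abs(c1 - c0) <= _EPS) & (g1 <= g0))
    return states


def _scenarios_from_states(
    tree: ReferenceTree,
    states: np.ndarray,
    leaf_states: np.ndarray,
    char_ids: Sequence[str],
    scheme: CostScheme,
    gain_cost: float,
    loss_cost: float,
) -> list[GainLossScenario]:
    leaf_row = {t: i for i, t in enumerate(tree.taxa)}
    labels = [n.label for n in tree.nodes]
    parent_idx = np.array(
        [(n.parent.index if n.parent is not None else -1) for n in tree.nodes]
    )
    out: list[GainLossScenario] = []
    for k, cid in enumerate(char_ids):
        col = states[:, k]
        gains: list[str] = []
        losses: list[str] = []
        for i, lab in enumerate(labels):
            p = parent_idx[i]
            parent_state = 0 if p < 0 else col[p]
            if col[i] == 1 and parent_state == 0:
                gains.append(lab)
            elif col[i] == 0 and parent_state == 1:
                losses.append(lab)
        imputed = {
            n.label: int(col[n.index])
            for n in tree.leaves
            if leaf_states[leaf_row[n.label], k] == MISSING
        }
        cost = gain_cost * len(gains) + loss_cost * len(losses)
        out.append(
            GainLossScenario(
                char_id=cid,
                scheme=scheme,
                states={lab: int(col[i]) for i, lab in enumerate(labels)},
                gains=tuple(gains),
                losses=tuple(losses),
                cost=cost,
                imputed=imputed,
            )
        )
    return out


def _leaf_state_array(
    tree: ReferenceTree, column: Mapping[str, int] | Sequence[int] | np.ndarray
) -> np.ndarray:
    if isinstance(column, Mapping):
        missing_taxa = set(tree.taxa) - set(column)
        if missing_taxa:
            raise ScenarioError(f"no state given for taxa: {sorted(missing_taxa)}")
        arr = np.array([column[t] for t in tree.taxa], dtype=np.int8)
    else:
        arr = np.asarray(column, dtype=np.int8)
        if arr.shape != (len(tree.taxa),):
            raise ScenarioError(
                f"state vector length {arr.shape} != number of taxa {len(tree.taxa)}"
            )
    return arr


def sankoff_gain_loss(
    column: Mapping[str, int] | Sequence[int] | np.ndarray,
    tree: ReferenceTree,
    costs: CostScheme,
    char_id: str = "char",
) -> GainLossScenario:
    """Minimum-cost gain-loss scenario for a single character.

    ``column`` gives the observed leaf states, either as a mapping
    ``taxon -> state`` or as a vector aligned with ``tree.taxa``; states are
    PRESENT/ABSENT/MISSING.  Missing leaves cost nothing in either state and
    are reported in the scenario's ``imputed`` map.
    """
    arr = _leaf_state_array(tree, column)
    if not (arr == PRESENT).any():
        raise ScenarioError(
            f"character {char_id!r} has no present, non-missing taxon"
        )
    g = costs.effective_gain_cost(len(tree.taxa))
    states = _sankoff_states(tree, arr[:, None], g, costs.loss_cost)
    return _scenarios_from_states(
        tree, states, arr[:, None], [char_id], costs, g, costs.loss_cost
    )[0]


class ScenarioSet:
    """All gain-loss scenarios of an analysis, indexed by (character, scheme)."""

    def __init__(
        self,
        tree: ReferenceTree,
        schemes: Sequence[CostScheme],
        scenarios: Mapping[tuple[str, CostScheme], GainLossScenario],
        char_ids: Sequence[str],
    ):
        self.tree = tree
        self.schemes = list(schemes)
        self._scenarios = dict(scenarios)
        self.char_ids = list(char_ids)

    def __getitem__(self, key: tuple[str, CostScheme]) -> GainLossScenario:
        return self._scenarios[key]

    def at_scheme(self, scheme: CostScheme) -> list[GainLossScenario]:
        return [self._scenarios[(c, scheme)] for c in self.char_ids]

    def total_gains(self, scheme: CostScheme) -> int:
        return sum(s.n_gains for s in self.at_scheme(scheme))

    def total_lateral_events(self, scheme: CostScheme) -> int:
        return sum(s.lateral_events for s in self.at_scheme(scheme))

    def replace(self, scenario: GainLossScenario) -> None:
        """Swap in an updated scenario (used for flag assignment)."""
        self._scenarios[(scenario.char_id, scenario.scheme)] = scenario

    def to_tsv(self) -> str:
        """Machine-readable dump: one row per (character, scheme)."""
        lines = ["CHAR\tGAIN_COST\tLOSS_COST\tGAINS\tLOSSES\tCOST\tFLAG"]
        for scheme in self.schemes:
            for s in self.at_scheme(scheme):
                g = "inf" if math.isinf(scheme.gain_cost) else f"{scheme.gain_cost:g}"
                lines.append(
                    "\t".join(
                        (
                            s.char_id,
                            g,
                            f"{scheme.loss_cost:g}",
                            ",".join(s.gains),
                            ",".join(s.losses),
                            f"{s.cost:g}",
                            s.flag,
                        )
                    )
                )
        return "\n".join(lines) + "\n"


def map_all(
    matrix: CharacterMatrix,
    tree: ReferenceTree,
    grid: Sequence[CostScheme] | None = None,
) -> ScenarioSet:
    """Gain-loss scenarios for every character at every cost scheme in the grid.

    The matrix taxa must coincide with the tree's leaf set.  Total gains
    summed over characters are non-increasing along an increasing gain-cost
    grid (weak monotonicity of the vertical/lateral trade-off).
    """
    if grid is None:
        grid = default_grid()
    if not grid:
        raise ScenarioError("empty cost-scheme grid")
    if set(matrix.taxa) != set(tree.taxa):
        raise ScenarioError(
            "matrix taxa and tree leaves differ: "
            f"only-in-matrix={sorted(set(matrix.taxa) - set(tree.taxa))}, "
            f"only-in-tree={sorted(set(tree.taxa) - set(matrix.taxa))}"
        )
    # reorder matrix columns to tree taxon order
    order = [matrix.taxa.index(t) for t in tree.taxa]
    leaf_states = matrix.states[:, order].T  # (n_leaves, n_chars)

    scenarios: dict[tuple[str, CostScheme], GainLossScenario] = {}
    for scheme in grid:
        g = scheme.effective_gain_cost(len(tree.taxa))
        states = _sankoff_states(tree, leaf_states, g, scheme.loss_cost)
        for s in _scenarios_from_states(
            tree,
            states,
            leaf_states,
            matrix.character_ids,
            scheme,
            g,
            scheme.loss_cost,
        ):
            scenarios[(s.char_id, scheme)] = s
    return ScenarioSet(tree, grid, scenarios, matrix.character_ids)
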