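"""Scenario selection by the ancestral size criterion.

If every character is forced to originate once, inferred ancestral
inventories swell: ancestral genomes hold far more gene families than any
contemporary genome, or ancestral languages hold implausibly many synonyms
per meaning.  If every shared character is explained by transfer instead, the
vertical signal vanishes and ancestral inventories shrink toward nothing.
The selection step sweeps the gain-penalty grid, compares the distribution of
inferred ancestral inventory sizes against the observed contemporary one, and
picks the penalty — and thereby the amount of lateral transfer — that brings
the two distributions together, preferring the scheme with the fewest lateral
events among those in closest agreement.

Pooling differs by mode.  Genome mode pools per-node family totals, zeros
included: a genome's size is physical.  Language mode pools per-(node,
concept) synonym counts and drops zeros from both pools: a language with no
sampled word for a concept is a sample gap (its word lies outside the meaning
list), not a language unable to express the meaning — the same convention the
leaf matrix applies to missing data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .characters import PRESENT, CharacterMatrix
from .parsimony import (
    BORROWING_CANDIDATE,
    PARALLEL_CANDIDATE,
    CostScheme,
    GainLossScenario,
    ScenarioSet,
)
from .tree import ReferenceTree

__all__ = [
    "AncestralSizeProfile",
    "SchemeReport",
    "SelectionReport",
    "size_profile",
    "leaf_profile",
    "select_scheme",
    "apply_parallel_allowance",
]

Mode = Literal["language", "genome"]


@dataclass(frozen=True)
class AncestralSizeProfile:
    """Inventory sizes per tree node.

    ``node_totals``: characters present per node.  ``concept_counts`` (language
    mode): per-(node, concept) synonym counts, nodes x concepts; per-concept
    counts sum to the node total.  Leaf entries reflect observed data only;
    internal entries come from the reconstructed ancestral states.
    """

    node_totals: pd.Series
    concept_counts: pd.DataFrame | None
    internal_labels: tuple[str, ...]
    leaf_labels: tuple[str, ...]

    def pool(self, mode: Mode, which: Literal["internal", "leaves"]) -> np.ndarray:
        """Flat count sample entering the two-sample comparison."""
        labels = self.internal_labels if which == "internal" else self.leaf_labels
        if mode == "language":
            if self.concept_counts is None:
                raise ValueError("language-mode pooling requires concept counts")
            values = self.concept_counts.loc[list(labels)].to_numpy().ravel()
            return values[values > 0]  # zero = word outside the sample
        return self.node_totals.loc[list(labels)].to_numpy()


def _profile_from_states(
    tree: ReferenceTree,
    matrix: CharacterMatrix,
    present: np.ndarray,
) -> AncestralSizeProfile:
    """``present``: (n_chars, n_nodes) 0/1 presence per tree node."""
    labels = [n.label for n in tree.nodes]
    totals = pd.Series(present.sum(axis=0), index=labels, dtype=int)
    concept_counts: pd.DataFrame | None = None
    if matrix.has_concepts and matrix.n_characters:
        concepts = matrix.concepts()
        cidx = {c: i for i, c in enumerate(concepts)}
        acc = np.zeros((len(labels), len(concepts)), dtype=int)
        for i, char in enumerate(matrix.characters):
            acc[:, cidx[char.concept]] += present[i]
        concept_counts = pd.DataFrame(acc, index=labels, columns=concepts)
    return AncestralSizeProfile(
        node_totals=totals,
        concept_counts=concept_counts,
        internal_labels=tuple(n.label for n in tree.internal_nodes),
        leaf_labels=tuple(tree.taxa),
    )


def leaf_profile(matrix: CharacterMatrix, tree: ReferenceTree) -> AncestralSizeProfile:
    """Observed contemporary inventory sizes (scheme-independent).

    Internal-node entries are zero placeholders; only leaf entries are
    meaningful here.
    """
    n_nodes = len(tree.nodes)
    present = np.zeros((matrix.n_characters, n_nodes), dtype=np.int8)
    col_of = {t: matrix.taxa.index(t) for t in matrix.taxa}
    for node in tree.leaves:
        if node.label in col_of:
            present[:, node.index] = (
                matrix.states[:, col_of[node.label]] == PRESENT
            )
    return _profile_from_states(tree, matrix, present)


def size_profile(
    scenarios: Sequence[GainLossScenario],
    tree: ReferenceTree,
    matrix: CharacterMatrix,
) -> AncestralSizeProfile:
    """Inventory-size profile under one scheme's scenarios.

    Internal nodes count characters whose reconstructed ancestral state is
    present; leaf entries use the observed states (missing is not counted),
    so the leaf part of every profile is identical across schemes.
    """
    ids = {s.char_id for s in scenarios}
    if ids != set(matrix.character_ids):
        raise ValueError(
            "scenario set does not cover the matrix characters exactly: "
            f"missing={sorted(set(matrix.character_ids) - ids)[:5]}, "
            f"extra={sorted(ids - set(matrix.character_ids))[:5]}"
        )
    schemes = {s.scheme for s in scenarios}
    if len(schemes) > 1:
        raise ValueError(f"scenarios span multiple cost schemes: {schemes}")
    n_nodes = len(tree.nodes)
    by_id = {s.char_id: s for s in scenarios}
    present = np.zeros((matrix.n_characters, n_nodes), dtype=np.int8)
    col_of = {t: j for j, t in enumerate(matrix.taxa)}
    for i, char in enumerate(matrix.characters):
        sc = by_id[char.id]
        for node in tree.nodes:
            if node.is_leaf:
                present[i, node.index] = (
                    matrix.states[i, col_of[node.label]] == PRESENT
                )
            else:
                present[i, node.index] = sc.states[node.label]
    return _profile_from_states(tree, matrix, present)


@dataclass(frozen=True)
class SchemeReport:
    scheme: CostScheme
    distance: float
    pvalue: float
    total_gains: int
    total_lateral_events: int
    selected: bool = False


@dataclass(frozen=True)
class SelectionReport:
    """Per-scheme fit statistics and the selected gain penalty."""

    rows: tuple[SchemeReport, ...]
    selected: CostScheme
    warning: str | None = None

    def row_for(self, scheme: CostScheme) -> SchemeReport:
        for r in self.rows:
            if r.scheme == scheme:
                return r
        raise KeyError(scheme)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gain_cost": [r.scheme.gain_cost for r in self.rows],
                "loss_cost": [r.scheme.loss_cost for r in self.rows],
                "distance": [r.distance for r in self.rows],
                "pvalue": [r.pvalue for r in self.rows],
                "total_gains": [r.total_gains for r in self.rows],
                "total_lateral_events": [r.total_lateral_events for r in self.rows],
                "selected": [r.selected for r in self.rows],
            }
        )

    def to_tsv(self) -> str:
        return self.to_frame().to_csv(sep="\t", index=False)

    def to_json(self) -> dict:
        df = self.to_frame()
        return {
            "schemes": df.to_dict(orient="records"),
            "selected_gain_cost": self.selected.gain_cost,
            "selected_loss_cost": self.selected.loss_cost,
            "warning": self.warning,
        }


def _two_sample(
    ancestral: np.ndarray, leaves: np.ndarray, statistic: str
) -> tuple[float, float]:
    if len(ancestral) == 0 or len(leaves) == 0:
        return math.nan, math.nan
    if statistic == "ks":
        res = stats.ks_2samp(ancestral, leaves, method="auto")
        return float(res.statistic), float(res.pvalue)
    if statistic == "mannwhitney":
        res = stats.mannwhitneyu(ancestral, leaves, alternative="two-sided")
        # distance: deviation of the common-language effect size from 1/2
        cles = res.statistic / (len(ancestral) * len(leaves))
        return float(abs(cles - 0.5) * 2.0), float(res.pvalue)
    raise ValueError(f"unknown statistic {statistic!r}")


def select_scheme(
    scenario_set: ScenarioSet,
    matrix: CharacterMatrix,
    mode: Mode = "language",
    alpha: float = 0.05,
    statistic: str = "ks",
    tolerance: Literal["exact", "pvalue"] = "exact",
) -> tuple[SelectionReport, dict[CostScheme, AncestralSizeProfile]]:
    """Pick the gain penalty whose ancestral size distribution best matches
    the contemporary one, with minimal lateral transfer.

    For every scheme the pooled ancestral counts are compared to the pooled
    leaf counts with a two-sample test (Kolmogorov-Smirnov by default).
    Candidate schemes are those at the minimum distance (``tolerance="exact"``),
    or those whose test does not reject agreement at ``alpha``
    (``tolerance="pvalue"``); among candidates the scheme with the fewest
    total lateral events wins, ties resolved toward the largest gain penalty.
    Returns the report and the per-scheme profiles.
    """
    if len(scenario_set.schemes) < 1:
        raise ValueError("no schemes to select from")
    tree = scenario_set.tree
    if mode == "language" and not matrix.has_concepts:
        raise ValueError("language mode requires concept labels on all characters")

    profiles: dict[CostScheme, AncestralSizeProfile] = {}
    leaf_pool: np.ndarray | None = None
    stats_rows: list[SchemeReport] = []
    for scheme in scenario_set.schemes:
        prof = size_profile(scenario_set.at_scheme(scheme), tree, matrix)
        profiles[scheme] = prof
        if leaf_pool is None:
            leaf_pool = prof.pool(mode, "leaves")
        anc = prof.pool(mode, "internal")
        d, p = _two_sample(anc, leaf_pool, statistic)
        stats_rows.append(
            SchemeReport(
                scheme=scheme,
                distance=d,
                pvalue=p,
                total_gains=scenario_set.total_gains(scheme),
                total_lateral_events=scenario_set.total_lateral_events(scheme),
            )
        )

    warning: str | None = None
    largest = max(scenario_set.schemes, key=lambda s: s.gain_cost)
    pools = [profiles[s].pool(mode, "internal") for s in scenario_set.schemes]
    degenerate = (
        all(math.isnan(r.distance) for r in stats_rows)
        or all(np.array_equal(pools[0], p) for p in pools[1:])
    )
    if degenerate and len(scenario_set.schemes) > 1:
        warning = (
            "degenerate selection: ancestral pools identical (or empty) across "
            "schemes; returning the largest gain penalty"
        )
        chosen = largest
    else:
        finite = [r for r in stats_rows if not math.isnan(r.distance)]
        dmin = min(r.distance for r in finite)
        if tolerance == "pvalue":
            candidates = [r for r in finite if r.pvalue >= alpha]
            if not candidates:
                candidates = [r for r in finite if r.distance <= dmin + 1e-9]
        else:
            candidates = [r for r in finite if r.distance <= dmin + 1e-9]
        emin = min(r.total_lateral_events for r in candidates)
        chosen = max(
            (r.scheme for r in candidates if r.total_lateral_events == emin),
            key=lambda s: s.gain_cost,
        )

    rows = tuple(
        SchemeReport(
            scheme=r.scheme,
            distance=r.distance,
            pvalue=r.pvalue,
            total_gains=r.total_gains,
            total_lateral_events=r.total_lateral_events,
            selected=(r.scheme == chosen),
        )
        for r in stats_rows
    )
    return SelectionReport(rows=rows, selected=chosen, warning=warning), profiles


def apply_parallel_allowance(
    scenario_set: ScenarioSet,
    scheme: CostScheme,
    fraction: float,
) -> list[GainLossScenario]:
    """Flag a proportion of multi-origin characters as parallel evolution.

    Among multi-gain characters at ``scheme``, the ``floor(fraction * count)``
    most parallel-like are flagged ``parallel_candidate`` and excluded from
    lateral-edge construction.  Parallel-likeness is ranked by *increasing*
    minimal pairwise patristic distance between a character's gain nodes:
    near-identical innovations in adjacent lineages are the most plausible
    independent developments, while origins far apart on the tree are better
    explained by transfer.  ``fraction=0`` flags nothing; ``fraction=1``
    removes every lateral edge.  Returns the flagged scenarios at ``scheme``
    (the scenario set is updated in place).
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    tree = scenario_set.tree
    scenarios = scenario_set.at_scheme(scheme)
    multi = [s for s in scenarios if s.is_multi_origin]
    n_flag = math.floor(fraction * len(multi))

    def min_gain_distance(s: GainLossScenario) -> float:
        nodes = s.gains
        best = math.inf
        for i in range(len(nodes)):
            for j in range(i + 1, len(nodes)):
                best = min(best, tree.patristic(nodes[i], nodes[j]))
        return best

    ranked = sorted(multi, key=lambda s: (min_gain_distance(s), s.char_id))
    parallel_ids = {s.char_id for s in ranked[:n_flag]}

    out: list[GainLossScenario] = []
    for s in scenarios:
        flag = PARALLEL_CANDIDATE if s.char_id in parallel_ids else BORROWING_CANDIDATE
        if s.flag != flag:
            s = GainLossScenario(
                char_id=s.char_id,
                scheme=s.scheme,
                states=s.states,
                gains=s.gains,
                losses=s.losses,
                cost=s.cost,
                imputed=s.imputed,
                flag=flag,
            )
            scenario_set.replace(s)
        out.append(s)
    return out
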