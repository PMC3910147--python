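"""Minimal lateral network: the reference tree plus weighted lateral edges.

Characters whose selected gain-loss scenario needs k >= 2 gains imply k-1
transfer events.  Each such character links its gain nodes pairwise; because
neither donor nor direction is identifiable from presence/absence patterns,
all C(k,2) unordered pairs are drawn, each carrying weight (k-1)/C(k,2) so
the character's total contribution equals its k-1 events.  Coincident pairs
across characters are merged into single weighted edges.  Node sizes record
the number of characters inferred present at each node under the selected
scheme (ancestral inventory sizes).
"""

from __future__ import annotations

import io
import itertools
from dataclasses import dataclass
from typing import Literal, Sequence

import networkx as nx
import pandas as pd

from .characters import CharacterMatrix
from .parsimony import BORROWING_CANDIDATE, CostScheme, GainLossScenario
from .tree import ReferenceTree

__all__ = [
    "LateralEdge",
    "LateralNetwork",
    "NetworkSummary",
    "build_mln",
    "export_network",
    "read_edge_list",
    "summarize",
]


@dataclass(frozen=True)
class LateralEdge:
    """Aggregated lateral link between two tree nodes (order-insensitive)."""

    nodes: tuple[str, str]  # sorted pair
    weight: float
    characters: tuple[str, ...]
    per_character_weight: tuple[float, ...]


class LateralNetwork:
    """Reference tree (vertical backbone, immutable) plus lateral edges."""

    def __init__(
        self,
        tree: ReferenceTree,
        scheme: CostScheme,
        lateral_edges: Sequence[LateralEdge],
        node_sizes: dict[str, int],
        origins: dict[str, tuple[str, ...]],
        n_parallel_flagged: int = 0,
    ):
        self.tree = tree
        self.scheme = scheme
        self.lateral_edges = list(lateral_edges)
        self.node_sizes = dict(node_sizes)
        self.origins = dict(origins)  # per borrowing-candidate character
        self.n_parallel_flagged = n_parallel_flagged

    @property
    def total_lateral_weight(self) -> float:
        return sum(e.weight for e in self.lateral_edges)

    @property
    def multi_origin_characters(self) -> list[str]:
        """Borrowing-candidate characters with more than one origin."""
        return sorted(c for c, g in self.origins.items() if len(g) >= 2)

    def to_multigraph(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        for node in self.tree.preorder():
            g.add_node(
                node.label,
                size=int(self.node_sizes.get(node.label, 0)),
                leaf=int(node.is_leaf),
            )
        for node in self.tree.preorder():
            if node.parent is not None:
                attrs = {"kind": "vertical"}
                if node.length is not None:
                    attrs["length"] = float(node.length)
                g.add_edge(node.parent.label, node.label, **attrs)
        for e in self.lateral_edges:
            g.add_edge(
                e.nodes[0],
                e.nodes[1],
                kind="lateral",
                weight=float(e.weight),
                n_characters=len(e.characters),
                characters=",".join(e.characters),
            )
        return g

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<LateralNetwork {len(self.tree.taxa)} taxa, "
            f"{len(self.lateral_edges)} lateral edges, "
            f"total weight {self.total_lateral_weight:g}>"
        )


def build_mln(
    scenarios: Sequence[GainLossScenario], tree: ReferenceTree
) -> LateralNetwork:
    """Assemble the lateral network from one scheme's flagged scenarios.

    Only borrowing-candidate characters contribute edges; characters flagged
    as parallel evolution, and single-gain characters, do not.  The sum of
    all lateral edge weights equals the total number of inferred transfer
    events, sum over borrowing candidates of (gains - 1).
    """
    if not scenarios:
        raise ValueError("no scenarios given")
    schemes = {s.scheme for s in scenarios}
    if len(schemes) > 1:
        raise ValueError(f"scenarios span multiple cost schemes: {schemes}")
    scheme = next(iter(schemes))

    for s in scenarios:
        for node in s.gains:
            if node not in tree:
                raise ValueError(f"gain node {node!r} not in reference tree")

    acc: dict[tuple[str, str], list[tuple[str, float]]] = {}
    origins: dict[str, tuple[str, ...]] = {}
    n_parallel = 0
    for s in scenarios:
        if s.flag != BORROWING_CANDIDATE:
            n_parallel += 1
            continue
        origins[s.char_id] = s.gains
        k = s.n_gains
        if k < 2:
            continue
        pairs = list(itertools.combinations(sorted(s.gains), 2))
        w = (k - 1) / len(pairs)
        for pair in pairs:
            acc.setdefault(pair, []).append((s.char_id, w))

    edges = [
        LateralEdge(
            nodes=pair,
            weight=sum(w for _, w in contribs),
            characters=tuple(c for c, _ in contribs),
            per_character_weight=tuple(w for _, w in contribs),
        )
        for pair, contribs in sorted(acc.items())
    ]

    # node size = characters inferred present at the node under this scheme
    node_sizes = {n.label: 0 for n in tree.preorder()}
    for s in scenarios:
        for label, state in s.states.items():
            if state == 1:
                node_sizes[label] += 1
    return LateralNetwork(
        tree,
        scheme,
        edges,
        node_sizes,
        origins,
        n_parallel_flagged=n_parallel,
    )


def _to_dot(net: LateralNetwork) -> str:
    buf = io.StringIO()
    buf.write("graph mln {\n")
    for node in net.tree.preorder():
        shape = "box" if node.is_leaf else "ellipse"
        size = net.node_sizes.get(node.label, 0)
        buf.write(f'  "{node.label}" [shape={shape}, size={size}];\n')
    for node in net.tree.preorder():
        if node.parent is not None:
            buf.write(f'  "{node.parent.label}" -- "{node.label}" [kind=vertical];\n')
    for e in net.lateral_edges:
        buf.write(
            f'  "{e.nodes[0]}" -- "{e.nodes[1]}" '
            f'[kind=lateral, weight={e.weight:g}, style=dashed];\n'
        )
    buf.write("}\n")
    return buf.getvalue()


def _to_edge_list(net: LateralNetwork) -> str:
    lines = ["NODE_A\tNODE_B\tWEIGHT\tN_CHARACTERS\tCHARACTERS"]
    for e in net.lateral_edges:
        lines.append(
            "\t".join(
                (
                    e.nodes[0],
                    e.nodes[1],
                    repr(e.weight),
                    str(len(e.characters)),
                    ",".join(e.characters),
                )
            )
        )
    return "\n".join(lines) + "\n"


def read_edge_list(text: str) -> list[LateralEdge]:
    """Parse the 5-column lateral edge list back (weights round-trip exactly)."""
    df = pd.read_csv(io.StringIO(text), sep="\t", dtype=str)
    out = []
    for row in df.itertuples(index=False):
        chars = tuple(row.CHARACTERS.split(",")) if isinstance(row.CHARACTERS, str) else ()
        out.append(
            LateralEdge(
                nodes=(row.NODE_A, row.NODE_B),
                weight=float(row.WEIGHT),
                characters=chars,
                per_character_weight=(),
            )
        )
    return out


def export_network(
    net: LateralNetwork, format: Literal["gml", "edge-list", "dot"] = "edge-list"
) -> str:
    """Serialize the network; vertical and lateral edges are distinguished by
    the ``kind`` edge attribute, and every node carries its ``size``."""
    if format == "gml":
        return "\n".join(nx.generate_gml(net.to_multigraph())) + "\n"
    if format in ("edge-list", "edgelist"):
        return _to_edge_list(net)
    if format == "dot":
        return _to_dot(net)
    raise ValueError(
        f"unknown export format {format!r}; expected gml, edge-list or dot"
    )


@dataclass(frozen=True)
class NetworkSummary:
    n_characters: int
    n_multi_origin: int
    proportion_multi_origin: float
    total_lateral_weight: float
    n_lateral_edges: int
    n_parallel_flagged: int
    per_taxon_partners: dict[str, list[tuple[str, float]]]

    def to_json(self) -> dict:
        return {
            "n_characters": self.n_characters,
            "n_multi_origin": self.n_multi_origin,
            "proportion_multi_origin": self.proportion_multi_origin,
            "total_lateral_weight": self.total_lateral_weight,
            "n_lateral_edges": self.n_lateral_edges,
            "n_parallel_flagged": self.n_parallel_flagged,
            "per_taxon_partners": {
                t: [[p, w] for p, w in partners]
                for t, partners in self.per_taxon_partners.items()
            },
        }


def summarize(net: LateralNetwork, matrix: CharacterMatrix) -> NetworkSummary:
    """Headline numbers: how many characters conflict with the tree, and who
    exchanges most with whom.

    The multi-origin proportion is borrowing-candidate characters with >= 2
    origins over all characters.  Per-taxon partners rank, for each leaf that
    is an endpoint of lateral edges, its partner nodes by summed incident
    lateral weight.
    """
    partners: dict[str, dict[str, float]] = {}
    for e in net.lateral_edges:
        a, b = e.nodes
        for this, other in ((a, b), (b, a)):
            if this in net.tree and net.tree[this].is_leaf:
                partners.setdefault(this, {})
                partners[this][other] = partners[this].get(other, 0.0) + e.weight
    ranked = {
        t: sorted(d.items(), key=lambda kv: (-kv[1], kv[0]))
        for t, d in sorted(partners.items())
    }
    n_multi = len(net.multi_origin_characters)
    n_total = matrix.n_characters
    return NetworkSummary(
        n_characters=n_total,
        n_multi_origin=n_multi,
        proportion_multi_origin=(n_multi / n_total) if n_total else 0.0,
        total_lateral_weight=net.total_lateral_weight,
        n_lateral_edges=len(net.lateral_edges),
        n_parallel_flagged=net.n_parallel_flagged,
        per_taxon_partners=ranked,
    )
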