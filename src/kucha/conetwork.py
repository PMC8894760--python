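"""Drug-pair co-occurrence counting and core-material network analysis.

A *drug pair* is an unordered pair of materials appearing together inside
one formulation; its count is the number of formulations containing both.
Thresholding the pair counts (strictly greater than the threshold, default
4) yields the core network: nodes weighted by UV, edges by co-occurrence
count. Materials central in that network — here by weighted degree — are
the tradition's core ingredients.
"""

from __future__ import annotations

from itertools import combinations
from pathlib import Path

import networkx as nx

from .survey_data import CoreNetwork, SurveyDataset

__all__ = [
    "count_pairs",
    "build_core_network",
    "rank_core_materials",
    "export_network",
    "to_networkx",
]

Pair = tuple[str, str]


def count_pairs(dataset: SurveyDataset) -> dict[Pair, int]:
    """Count co-occurrences of every unordered material pair.

    Each formulation contributes one count to each of its C(|F|, 2)
    2-subsets. Pair keys are canonicalized (endpoints sorted), and pairs
    never co-occurring are absent rather than zero.
    """
    counts: dict[Pair, int] = {}
    for f in dataset.formulations:
        for a, b in combinations(sorted(f.materials), 2):
            counts[(a, b)] = counts.get((a, b), 0) + 1
    return counts


def build_core_network(pairs: dict[Pair, int], uv: dict[str, float],
                       threshold: int = 4) -> CoreNetwork:
    """Keep pairs with count strictly greater than ``threshold``.

    Nodes are the retained edges' endpoints, weighted by UV; isolated
    materials are excluded. A retained endpoint missing from the UV map is
    an error naming the material.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    edges = {pair: c for pair, c in pairs.items() if c > threshold}
    nodes: dict[str, float] = {}
    for a, b in edges:
        for end in (a, b):
            if end not in uv:
                raise KeyError(f"no UV value for network material {end!r}")
            nodes[end] = uv[end]
    return CoreNetwork(nodes=nodes, edges=edges, threshold=threshold)


def rank_core_materials(net: CoreNetwork,
                        score: str = "wdegree") -> list[tuple[str, float]]:
    """Rank network materials by centrality, most central first.

    Scores: ``wdegree`` (default) — sum of incident edge counts, the
    material's total frequent-partner co-occurrence; ``degree`` — number of
    frequent partners; ``eigenvector`` — eigenvector centrality on the
    count-weighted graph. Ties break by node UV descending, then material
    id ascending. Returns the full ranking; an empty network gives [].
    """
    if not net.nodes:
        return []
    if score == "wdegree":
        s: dict[str, float] = {m: 0.0 for m in net.nodes}
        for (a, b), c in net.edges.items():
            s[a] += c
            s[b] += c
    elif score == "degree":
        s = {m: 0.0 for m in net.nodes}
        for a, b in net.edges:
            s[a] += 1
            s[b] += 1
    elif score == "eigenvector":
        g = to_networkx(net)
        s = nx.eigenvector_centrality(g, weight="count", max_iter=1000)
    else:
        raise ValueError(f"unknown score {score!r}")
    order = sorted(net.nodes, key=lambda m: (-s[m], -net.nodes[m], m))
    return [(m, s[m]) for m in order]


def to_networkx(net: CoreNetwork) -> nx.Graph:
    """CoreNetwork as an undirected networkx graph (node attr ``uv``, edge
    attr ``count``), with deterministically ordered insertion."""
    g = nx.Graph(threshold=net.threshold)
    for mid, uv in sorted(net.nodes.items()):
        g.add_node(mid, uv=float(uv))
    for (a, b), c in sorted(net.edges.items()):
        g.add_edge(a, b, count=int(c))
    return g


def export_network(net: CoreNetwork, path: str | Path,
                   format: str = "graphml") -> None:
    """Write the network as ``graphml``, ``edgelist-tsv`` or ``json``.

    Output is deterministic (sorted keys) so repeated exports of the same
    network are byte-identical.
    """
    path = Path(path)
    if format == "graphml":
        g = to_networkx(net)
        nx.write_graphml(g, path)
    elif format == "edgelist-tsv":
        lines = ["material_a\tmaterial_b\tcount"]
        for (a, b), c in sorted(net.edges.items()):
            lines.append(f"{a}\t{b}\t{c}")
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    elif format == "json":
        from .survey_data import write_report

        write_report(net, path)
    else:
        raise ValueError(f"unknown format {format!r}")
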