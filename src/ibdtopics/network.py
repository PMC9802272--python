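"""Topic co-occurrence network, centrality ranking, and sociogram export.

Nodes are the 8 topics; an edge's weight counts the posts mentioning both
endpoint topics.  Only multi-topic posts (>=2 topics) contribute: a post
with k topics increments each of its C(k, 2) unordered pairs once,
regardless of how many term matches support each topic.

The published sociograms size nodes by "in-degree centrality"; on an
undirected co-occurrence graph that is read as weighted degree (node
strength, the sum of incident edge weights), with plain degree available
behind a flag.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .lexicons import CANONICAL_TOPICS
from .topics import TopicAssignment


@dataclass
class TopicNetwork:
    """Weighted undirected co-occurrence graph over the topic set."""

    graph: nx.Graph
    topics: tuple[str, ...]
    n_multitopic_posts: int = 0

    @property
    def node_strength(self) -> dict[str, int]:
        return {
            t: int(sum(d["weight"] for _, _, d in self.graph.edges(t, data=True)))
            for t in self.topics
        }

    @property
    def degree(self) -> dict[str, int]:
        return {t: self.graph.degree(t) for t in self.topics}

    def edge_weight(self, a: str, b: str) -> int:
        return self.graph.edges[a, b]["weight"] if self.graph.has_edge(a, b) else 0

    @property
    def total_weight(self) -> int:
        return int(sum(d["weight"] for _, _, d in self.graph.edges(data=True)))


def build_network(
    assignments: Iterable[TopicAssignment],
    topics: Sequence[str] = CANONICAL_TOPICS,
) -> TopicNetwork:
    """Accumulate post-level topic co-occurrences into a weighted graph."""
    g = nx.Graph()
    g.add_nodes_from(topics)
    n_multi = 0
    for a in assignments:
        if a.n_topics < 2:
            continue
        n_multi += 1
        for u, v in combinations(sorted(a.topics), 2):
            if g.has_edge(u, v):
                g.edges[u, v]["weight"] += 1
            else:
                g.add_edge(u, v, weight=1)
    net = TopicNetwork(graph=g, topics=tuple(topics), n_multitopic_posts=n_multi)
    for t, s in net.node_strength.items():
        g.nodes[t]["strength"] = s
    return net


def rank_centrality(
    network: TopicNetwork, weighted: bool = True
) -> list[tuple[str, int]]:
    """Topics by descending centrality; ties broken lexicographically.

    ``weighted=True`` ranks by node strength (the default reading of the
    sociogram's node sizing); ``weighted=False`` by plain degree.
    """
    scores = network.node_strength if weighted else network.degree
    return sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))


def cooccurrence_matrix(network: TopicNetwork):
    """Symmetric topic x topic co-occurrence count matrix (zero diagonal)."""
    import pandas as pd

    t = list(network.topics)
    data = [[network.edge_weight(a, b) if a != b else 0 for b in t] for a in t]
    return pd.DataFrame(data, index=t, columns=t)


def export_sociogram(
    network: TopicNetwork, path: str | Path, format: str = "graphml"
) -> Path:
    """Write the network with `strength` node and `weight` edge attributes.

    Formats: ``graphml``, ``edgelist_csv`` (columns topic_a, topic_b,
    weight, sorted descending by weight), or ``dot`` (node size scaled by
    strength — a minimal sociogram rendering input, not a styled figure).
    """
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(network.graph, path)
    elif format == "edgelist_csv":
        rows = sorted(
            ((u, v, d["weight"]) for u, v, d in network.graph.edges(data=True)),
            key=lambda r: (-r[2], r[0], r[1]),
        )
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["topic_a", "topic_b", "weight"])
            writer.writerows(rows)
    elif format == "dot":
        _write_dot(network, path)
    else:
        raise ValueError(f"unknown sociogram format {format!r}")
    return path


def _write_dot(network: TopicNetwork, path: Path) -> None:
    strength = network.node_strength
    max_s = max(strength.values()) or 1
    lines = ["graph topics {", "  layout=circo;"]
    for t in network.topics:
        size = 0.5 + 1.5 * strength[t] / max_s
        lines.append(
            f'  "{t}" [width={size:.2f}, height={size:.2f}, fixedsize=true, '
            f'label="{t}\\n{strength[t]}"];'
        )
    max_w = max((d["weight"] for _, _, d in network.graph.edges(data=True)), default=1)
    for u, v, d in network.graph.edges(data=True):
        pen = 0.5 + 4.5 * d["weight"] / max_w
        lines.append(f'  "{u}" -- "{v}" [weight={d["weight"]}, penwidth={pen:.2f}];')
    lines.append("}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_sociogram(path: str | Path, topics: Sequence[str] = CANONICAL_TOPICS) -> TopicNetwork:
    """Re-import a GraphML export (round-trip counterpart of export_sociogram)."""
    g = nx.read_graphml(Path(path))
    clean = nx.Graph()
    clean.add_nodes_from(topics)
    for u, v, d in g.edges(data=True):
        clean.add_edge(u, v, weight=int(d["weight"]))
    net = TopicNetwork(graph=clean, topics=tuple(topics))
    for t, s in net.node_strength.items():
        clean.nodes[t]["strength"] = s
    return net
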