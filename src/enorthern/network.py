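"""Summarization of gene interaction networks from weighted edge lists.

Networks are undirected graphs over gene symbols whose edges carry a
``combined_score`` in [0, 1] plus optional per-evidence-channel scores
(coexpression, experiments, database, text mining, genomic neighborhood,
gene fusion, co-occurrence), the dialect of a STRING tab-separated export.
Operations cover the usual summaries of such networks: restriction to a
gene panel, hub ranking by degree, isolated-node detection, connected
components, and filtering by a single evidence channel.

Graphs are held in a :class:`networkx.Graph` behind the
:class:`InteractionGraph` wrapper; duplicate A–B / B–A rows are merged
keeping the maximum of each score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

from .errors import ParseError, ValidationError

__all__ = [
    "CHANNELS",
    "InteractionGraph",
    "read_edge_list",
    "purge_to_gene_set",
    "isolated_nodes",
    "degree_ranking",
    "channel_subgraph",
    "connected_components",
]

logger = logging.getLogger(__name__)

#: Evidence channels recognized on edges, after the STRING schema.
CHANNELS = (
    "coexpression",
    "experiments",
    "database",
    "textmining",
    "neighborhood",
    "fusion",
    "cooccurrence",
)

#: Historical medium-confidence cutoff on the combined score; an
#: assumption, since source exports do not embed their cutoff.
DEFAULT_MIN_SCORE = 0.4


@dataclass
class InteractionGraph:
    """Undirected weighted gene interaction network.

    ``unmatched`` records genes that were requested in a purge but absent
    from the source network (they are kept as isolated nodes).
    """

    graph: nx.Graph
    unmatched: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for u, v, data in self.graph.edges(data=True):
            if u == v:
                raise ValidationError(f"self-loop on {u!r}")
            for key, val in data.items():
                if key == "combined_score" or key in CHANNELS:
                    if not 0.0 <= val <= 1.0:
                        raise ValidationError(
                            f"edge {u}-{v}: {key}={val} outside [0, 1]"
                        )
            if "combined_score" not in data:
                raise ValidationError(f"edge {u}-{v} lacks combined_score")

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset((u, v)) for u, v in self.graph.edges}

    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_score(self, u: str, v: str, channel: str = "combined_score") -> float:
        return self.graph.edges[u, v].get(channel, 0.0)

    def to_frame(self) -> pd.DataFrame:
        """Edge list as a DataFrame (protein1, protein2, channels, combined_score)."""
        rows = []
        for u, v, data in self.graph.edges(data=True):
            a, b = sorted((u, v))
            row = {"protein1": a, "protein2": b}
            for ch in CHANNELS:
                if ch in data:
                    row[ch] = data[ch]
            row["combined_score"] = data["combined_score"]
            rows.append(row)
        frame = pd.DataFrame(rows)
        if not frame.empty:
            frame = frame.sort_values(["protein1", "protein2"]).reset_index(drop=True)
        return frame


def read_edge_list(
    path: str | Path, nodes: Iterable[str] | None = None
) -> InteractionGraph:
    """Read a STRING-style tab-separated edge list.

    The first two columns name the interacting genes; a ``combined_score``
    column is required and evidence-channel columns are optional, all in
    [0, 1].  Reversed duplicate pairs are merged keeping per-score maxima.
    ``nodes`` adds genes that must exist even if edge-free.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t")
    if frame.shape[1] < 3 or "combined_score" not in frame.columns:
        raise ParseError(
            f"{path.name}: need two node columns and a combined_score column", 1
        )
    col_u, col_v = frame.columns[:2]
    score_cols = [c for c in frame.columns if c == "combined_score" or c in CHANNELS]

    g = nx.Graph()
    if nodes is not None:
        g.add_nodes_from(nodes)
    for i, row in frame.iterrows():
        u, v = str(row[col_u]), str(row[col_v])
        if u == v:
            raise ValidationError(f"row {i + 2}: self-loop on {u!r}")
        attrs = {}
        for c in score_cols:
            val = float(row[c])
            if not 0.0 <= val <= 1.0:
                raise ValidationError(f"row {i + 2}: {c}={val} outside [0, 1]")
            attrs[c] = val
        if g.has_edge(u, v):
            old = g.edges[u, v]
            for c, val in attrs.items():
                old[c] = max(old.get(c, 0.0), val)
        else:
            g.add_edge(u, v, **attrs)
    return InteractionGraph(g)


def purge_to_gene_set(
    graph: InteractionGraph, genes: Iterable[str]
) -> InteractionGraph:
    """Induced subgraph on a gene panel.

    Genes absent from the network are retained as isolated nodes and
    reported via ``unmatched`` (and a log warning), so a panel restriction
    never silently drops genes.
    """
    genes = set(genes)
    if not genes:
        raise ValidationError("empty gene set")
    present = genes & set(graph.graph.nodes)
    missing = genes - present
    if missing:
        logger.warning(
            "%d gene(s) absent from the network, kept isolated: %s",
            len(missing),
            ", ".join(sorted(missing)),
        )
    sub = graph.graph.subgraph(present).copy()
    sub.add_nodes_from(missing)
    return InteractionGraph(sub, unmatched=frozenset(missing))


def isolated_nodes(graph: InteractionGraph) -> set[str]:
    """Nodes with degree zero."""
    return set(nx.isolates(graph.graph))


def degree_ranking(
    graph: InteractionGraph, min_score: float = DEFAULT_MIN_SCORE
) -> list[tuple[str, int]]:
    """Genes ranked by degree after dropping weak edges.

    Edges with ``combined_score < min_score`` are ignored.  Descending
    degree, ties broken alphabetically.
    """
    g = graph.graph
    degree = {n: 0 for n in g.nodes}
    for u, v, data in g.edges(data=True):
        if data["combined_score"] >= min_score:
            degree[u] += 1
            degree[v] += 1
    return sorted(degree.items(), key=lambda item: (-item[1], item[0]))


def channel_subgraph(
    graph: InteractionGraph, channel: str, min_score: float
) -> InteractionGraph:
    """Keep edges whose named evidence channel scores at least ``min_score``.

    Nodes are preserved; edges lacking the channel count as score 0.
    """
    if channel not in CHANNELS:
        raise ValidationError(
            f"unknown channel {channel!r}; expected one of {CHANNELS}"
        )
    g = nx.Graph()
    g.add_nodes_from(graph.graph.nodes)
    for u, v, data in graph.graph.edges(data=True):
        if data.get(channel, 0.0) >= min_score:
            g.add_edge(u, v, **data)
    return InteractionGraph(g)


def connected_components(graph: InteractionGraph) -> list[set[str]]:
    """Maximal connected node sets, largest first (ties by smallest member)."""
    comps = [set(c) for c in nx.connected_components(graph.graph)]
    return sorted(comps, key=lambda c: (-len(c), min(c)))
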