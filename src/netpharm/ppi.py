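"""Scored interaction edges: confidence filtering, induced subnetwork, hubs."""

from __future__ import annotations

from collections.abc import Iterable
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .core import GeneSet, NetpharmError, RowError, normalize_symbol

#: declared score scales -> (lower bound, upper bound, divisor to unit scale)
SCALES = {"unit": (0.0, 1.0, 1.0), "thousand": (0.0, 1000.0, 1000.0)}


@dataclass
class ScoredEdgeSet:
    """Undirected scored edges; (a, b) == (b, a), best score kept."""

    edges: dict[tuple[str, str], float] = field(default_factory=dict)
    scale: str = "unit"

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; use {sorted(SCALES)}")

    def __len__(self) -> int:
        return len(self.edges)

    def add(self, a: str, b: str, score: float) -> None:
        a, b = normalize_symbol(a), normalize_symbol(b)
        if a == b:
            return  # self-interactions are dropped during cleaning
        lo, hi, _ = SCALES[self.scale]
        if not lo <= score <= hi:
            raise ValueError(
                f"score {score} outside declared {self.scale} scale [{lo}, {hi}]"
            )
        key = (a, b) if a < b else (b, a)
        if key not in self.edges or score > self.edges[key]:
            self.edges[key] = score

    def unit_scores(self) -> dict[tuple[str, str], float]:
        _, _, div = SCALES[self.scale]
        return {k: v / div for k, v in self.edges.items()}

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[str, str, float]], scale: str = "unit"
    ) -> "ScoredEdgeSet":
        es = cls(scale=scale)
        for a, b, s in pairs:
            es.add(a, b, float(s))
        return es

    @classmethod
    def from_tsv(cls, path, scale: str = "thousand", dialect=None) -> "ScoredEdgeSet":
        """Read a node1/node2/combined_score export."""
        from .core import _resolve_columns

        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        cols = _resolve_columns(df, ("node1", "node2", "combined_score"), dialect)
        es = cls(scale=scale)
        for idx, row in df.iterrows():
            line = int(idx) + 2
            try:
                score = float(row[cols["combined_score"]])
            except ValueError:
                raise RowError(
                    f"unparseable score {row[cols['combined_score']]!r}",
                    line=line,
                ) from None
            try:
                es.add(row[cols["node1"]], row[cols["node2"]], score)
            except ValueError as exc:
                raise RowError(str(exc), line=line) from None
        return es

    def to_tsv(self, path) -> None:
        rows = [
            {"node1": a, "node2": b, "combined_score": s}
            for (a, b), s in sorted(self.edges.items())
        ]
        pd.DataFrame(rows, columns=["node1", "node2", "combined_score"]).to_csv(
            path, sep="\t", index=False
        )


@dataclass
class PPINetwork:
    """Induced interaction subnetwork plus the query genes it excluded."""

    graph: nx.Graph
    dropped: list[str] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class HubStats:
    mean_degree: float  # exact 2E/N
    hubs: list[str]  # degree strictly above mean, ranked
    top: list[str]  # top-k by degree, label tie-break

    @property
    def mean_degree_rounded(self) -> float:
        return round(self.mean_degree, 3)


def filter_edges(
    edges: ScoredEdgeSet, min_score: float = 0.9, strict: bool = True
) -> ScoredEdgeSet:
    """Keep edges whose unit-scale score passes the threshold.

    The threshold is always given on the 0-1 scale (0.9 means 900 on a
    0-1000 export).  Default comparison is strict ``>``; set
    ``strict=False`` for ``>=``.
    """
    out = ScoredEdgeSet(scale=edges.scale)
    _, _, div = SCALES[edges.scale]
    for (a, b), score in edges.edges.items():
        unit = score / div
        if (unit > min_score) if strict else (unit >= min_score):
            out.edges[(a, b)] = score
    return out


def induce_subnetwork(
    edges: ScoredEdgeSet, genes: GeneSet, drop_isolated: bool = True
) -> PPINetwork:
    """Restrict the edge set to the query genes.

    With ``drop_isolated`` (default), query genes with no surviving edge
    are excluded from the node set and reported in ``dropped``.
    """
    if len(genes) == 0:
        raise NetpharmError("gene set for subnetwork induction is empty")
    g = nx.Graph()
    members = genes.genes
    for (a, b), score in edges.edges.items():
        if a in members and b in members:
            g.add_edge(a, b, score=score)
    connected = set(g.nodes)
    dropped = sorted(members - connected)
    if not drop_isolated:
        for gene in dropped:
            g.add_node(gene)
        dropped = []
    return PPINetwork(graph=g, dropped=dropped)


def hub_stats(net: PPINetwork, top_k: int = 4) -> HubStats:
    """Mean degree (2E/N), strict above-mean hubs, and the top-k list."""
    if net.n_nodes == 0:
        raise NetpharmError("hub statistics need a non-empty network")
    degrees = {n: int(d) for n, d in net.graph.degree}
    mean = 2.0 * net.n_edges / net.n_nodes
    ranked = sorted(degrees, key=lambda n: (-degrees[n], n))
    hubs = [n for n in ranked if degrees[n] > mean]
    return HubStats(mean_degree=mean, hubs=hubs, top=ranked[:top_k])
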