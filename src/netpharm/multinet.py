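"""Herbs-compounds-genes tripartite network, degrees and key-node selection.

Edges are restricted to herb-compound (one per herb membership) and
compound-gene (one per mapped target surviving the gene restriction).
Node importance is plain degree; key compounds are those whose degree
strictly exceeds the whole-network mean.
"""

from __future__ import annotations

from collections.abc import Iterable
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .core import GeneSet, NetpharmError, TargetMap
from .screen import UniqueCompound

PARTITIONS = ("herb", "compound", "gene")


@dataclass
class DegreeReport:
    """Per-node degrees plus partition and network means."""

    degrees: dict[str, int]
    partitions: dict[str, str]
    partition_means: dict[str, float]
    network_mean: float

    def above_network_mean(self) -> dict[str, bool]:
        return {n: d > self.network_mean for n, d in self.degrees.items()}


def build_multinetwork(
    records: Iterable[UniqueCompound],
    target_map: TargetMap,
    genes: GeneSet,
    herbs: Iterable[str] | None = None,
) -> nx.Graph:
    """Build the tripartite graph from deduplicated compound records.

    ``target_map`` is restricted to ``genes`` before any edge is created.
    Compounds left with zero surviving targets stay in the graph, flagged
    with the node attribute ``isolated_from_genes``.  If ``herbs`` is
    given, a compound listing a herb outside it is an error.
    """
    records = list(records)
    known_herbs = set(herbs) if herbs is not None else None
    restricted = target_map.restrict(genes)

    g = nx.Graph()
    for rec in records:
        if not rec.herbs:
            raise NetpharmError(f"compound {rec.mol_id} has no herb membership")
        if known_herbs is not None:
            bad = set(rec.herbs) - known_herbs
            if bad:
                raise NetpharmError(
                    f"compound {rec.mol_id} references unknown herb(s): "
                    f"{sorted(bad)}"
                )
        targets = restricted.get(rec.mol_id, frozenset())
        g.add_node(
            rec.mol_id,
            partition="compound",
            name=rec.name,
            isolated_from_genes=not targets,
        )
        for herb in rec.herbs:
            g.add_node(herb, partition="herb")
            g.add_edge(herb, rec.mol_id)
        for gene in targets:
            g.add_node(gene, partition="gene")
            g.add_edge(rec.mol_id, gene)
    _assert_partition_purity(g)
    return g


def _assert_partition_purity(g: nx.Graph) -> None:
    """No within-partition or herb-gene edges; no self loops."""
    for u, v in g.edges:
        if u == v:
            raise NetpharmError(f"self loop on {u!r}")
        pu, pv = g.nodes[u]["partition"], g.nodes[v]["partition"]
        if {pu, pv} not in ({"herb", "compound"}, {"compound", "gene"}):
            raise NetpharmError(
                f"edge {u!r}-{v!r} violates partition constraint ({pu}-{pv})"
            )


def degree_report(g: nx.Graph) -> DegreeReport:
    """Exact integer degrees; network mean is 2E/N over all nodes."""
    if g.number_of_nodes() == 0:
        raise NetpharmError("cannot report degrees of an empty network")
    degrees = {n: int(d) for n, d in g.degree}
    partitions = {n: g.nodes[n]["partition"] for n in g.nodes}
    part_means: dict[str, float] = {}
    for part in PARTITIONS:
        members = [n for n in g.nodes if partitions[n] == part]
        if members:
            part_means[part] = sum(degrees[n] for n in members) / len(members)
    network_mean = 2.0 * g.number_of_edges() / g.number_of_nodes()
    return DegreeReport(
        degrees=degrees,
        partitions=partitions,
        partition_means=part_means,
        network_mean=network_mean,
    )


def select_key_nodes(
    report: DegreeReport,
    partition: str,
    rule: str = "above-mean",
    k: int | None = None,
) -> list[str]:
    """Select important nodes of one partition.

    ``above-mean`` keeps nodes with degree strictly greater than the
    whole-network mean.  ``top-k`` ranks by degree descending with ties
    broken by node label ascending; asking for more nodes than the
    partition holds returns them all.
    """
    members = [n for n, p in report.partitions.items() if p == partition]
    ranked = sorted(members, key=lambda n: (-report.degrees[n], n))
    if rule == "above-mean":
        return [n for n in ranked if report.degrees[n] > report.network_mean]
    if rule == "top-k":
        if k is None or k < 0:
            raise ValueError("top-k selection needs a non-negative k")
        if k > len(ranked):
            import warnings

            warnings.warn(
                f"k={k} exceeds partition size {len(ranked)}; returning all",
                stacklevel=2,
            )
        return ranked[:k]
    raise ValueError(f"unknown selection rule {rule!r}")


def degrees_to_frame(report: DegreeReport) -> pd.DataFrame:
    rows = [
        {
            "node": n,
            "partition": report.partitions[n],
            "degree": report.degrees[n],
            "above_network_mean": report.degrees[n] > report.network_mean,
        }
        for n in sorted(
            report.degrees, key=lambda n: (-report.degrees[n], n)
        )
    ]
    return pd.DataFrame(
        rows, columns=["node", "partition", "degree", "above_network_mean"]
    )


def write_degree_report(report: DegreeReport, path) -> None:
    degrees_to_frame(report).to_csv(path, sep="\t", index=False)


def write_graphml(g: nx.Graph, path) -> None:
    nx.write_graphml(g, path)


def write_sif(g: nx.Graph, path) -> None:
    """Simple interaction format; relation named after the partition pair."""
    with open(path, "w") as fh:
        for u, v in sorted(g.edges):
            pu, pv = g.nodes[u]["partition"], g.nodes[v]["partition"]
            rel = "".join(sorted(p[0] for p in (pu, pv)))
            fh.write(f"{u}\t{rel}\t{v}\n")
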