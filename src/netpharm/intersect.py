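"""Disease-gene union, drug-target intersection and Venn region counts."""

from __future__ import annotations

import itertools
import json
import warnings
from collections.abc import Iterable
from dataclasses import dataclass, field

from .core import GeneSet

MAX_VENN_SOURCES = 6


@dataclass
class GeneUnion:
    """Union of several gene sources with per-gene provenance."""

    genes: GeneSet
    provenance: dict[str, frozenset[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class VennSummary:
    """Disjoint region counts over up to six sources.

    ``regions`` maps a membership pattern (frozenset of source labels) to
    the number of genes belonging to exactly those sources.
    """

    source_sizes: dict[str, int]
    regions: dict[frozenset[str], int]
    union_size: int
    intersection_with_targets: int | None = None

    def overlap(self, *labels: str) -> int:
        """Genes in all of ``labels`` (any pattern containing them)."""
        want = frozenset(labels)
        return sum(
            n for pattern, n in self.regions.items() if want <= pattern
        )

    def to_json(self, path=None) -> str:
        payload = {
            "source_sizes": self.source_sizes,
            "union_size": self.union_size,
            "intersection_with_targets": self.intersection_with_targets,
            "regions": {
                "&".join(sorted(pattern)): n
                for pattern, n in sorted(
                    self.regions.items(), key=lambda kv: sorted(kv[0])
                )
            },
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def union_gene_sources(sources: list[GeneSet]) -> GeneUnion:
    """Case-normalized union keeping per-gene source provenance."""
    if not sources:
        raise ValueError("at least one gene source is required")
    provenance: dict[str, set[str]] = {}
    for src in sources:
        for gene in src.genes:
            provenance.setdefault(gene, set()).add(src.label)
    union = GeneSet(
        label="union",
        genes=frozenset(provenance),
        source="+".join(s.label for s in sources),
    )
    return GeneUnion(
        genes=union,
        provenance={g: frozenset(v) for g, v in provenance.items()},
    )


def intersect_with_targets(disease: GeneSet, drug_targets: GeneSet) -> GeneSet:
    """Exact intersection after normalization; warns (not fails) when empty."""
    common = disease.genes & drug_targets.genes
    if not common:
        warnings.warn(
            "no overlap between disease genes and drug targets", stacklevel=2
        )
    return GeneSet(label="common", genes=frozenset(common))


def venn_summary(
    sources: list[GeneSet], drug_targets: GeneSet | None = None
) -> VennSummary:
    """Disjoint Venn region counts for the sources via membership tabulation."""
    if len(sources) > MAX_VENN_SOURCES:
        raise ValueError(
            f"venn_summary supports at most {MAX_VENN_SOURCES} sources, "
            f"got {len(sources)}"
        )
    labels = [s.label for s in sources]
    if len(set(labels)) != len(labels):
        raise ValueError("source labels must be unique")
    universe: set[str] = set()
    for s in sources:
        universe |= s.genes
    regions: dict[frozenset[str], int] = {
        frozenset(combo): 0
        for r in range(1, len(sources) + 1)
        for combo in itertools.combinations(labels, r)
    }
    for gene in universe:
        pattern = frozenset(s.label for s in sources if gene in s.genes)
        regions[pattern] += 1
    inter = None
    if drug_targets is not None:
        inter = len(universe & drug_targets.genes)
    return VennSummary(
        source_sizes={s.label: len(s.genes) for s in sources},
        regions=regions,
        union_size=len(universe),
        intersection_with_targets=inter,
    )


def union_size_inclusion_exclusion(sources: Iterable[GeneSet]) -> int:
    """Union size by inclusion-exclusion (cross-check for venn_summary)."""
    sources = list(sources)
    total = 0
    for r in range(1, len(sources) + 1):
        sign = 1 if r % 2 == 1 else -1
        for combo in itertools.combinations(sources, r):
            inter = set(combo[0].genes)
            for s in combo[1:]:
                inter &= s.genes
            total += sign * len(inter)
    return total
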