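"""Bundled nine-herb example dataset.

Ships two small tab-separated fixtures: a per-herb summary table and a
bioactive compound table with per-compound mapped-target counts.  Target
gene identities are not part of the published tables, so
:func:`example_target_map` assigns deterministic placeholder symbols
consistent with each compound's mapped-target count.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .core import CompoundRecord, GeneSet, HerbSummary, TargetMap, read_compound_table


def _data_path(name: str):
    return resources.files("netpharm.data").joinpath(name)


def load_herb_summary() -> list[HerbSummary]:
    """The nine-herb summary table (compound / bioactive / target counts)."""
    with resources.as_file(_data_path("herb_summary.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    return [
        HerbSummary(
            herb=row["herb"],
            n_compounds=int(row["n_compounds"]),
            n_bioactive=int(row["n_bioactive"]),
            n_targets=int(row["n_targets"]),
        )
        for _, row in df.iterrows()
    ]


def load_compound_table() -> list[CompoundRecord]:
    """The 50-compound bioactive table, herb-expanded to one row per herb."""
    with resources.as_file(_data_path("compound_table.tsv")) as p:
        return read_compound_table(p)


def example_gene_universe(n_genes: int = 48) -> GeneSet:
    """Placeholder common-gene set GENE01..GENEnn."""
    width = max(2, len(str(n_genes)))
    genes = frozenset(f"GENE{i:0{width}d}" for i in range(1, n_genes + 1))
    return GeneSet(label="common", genes=genes, source="example")


def example_target_map(n_genes: int = 48) -> TargetMap:
    """Deterministic target assignment matching each compound's count.

    Genes are dealt cyclically from the placeholder universe in compound
    table order, so every compound receives exactly its ``n_targets``
    distinct genes and the union covers the whole universe whenever the
    total count reaches ``n_genes``.
    """
    universe = sorted(example_gene_universe(n_genes).genes)
    records = load_compound_table()
    seen: dict[str, int] = {}
    for r in records:  # one entry per compound, first herb occurrence
        if r.mol_id not in seen:
            if r.n_targets is None:
                raise ValueError(f"compound {r.mol_id} lacks a target count")
            if r.n_targets > n_genes:
                raise ValueError(
                    f"compound {r.mol_id} needs {r.n_targets} targets, "
                    f"universe has only {n_genes}"
                )
            seen[r.mol_id] = r.n_targets
    mapping: dict[str, list[str]] = {}
    offset = 0
    for mol_id, count in seen.items():
        mapping[mol_id] = [
            universe[(offset + j) % n_genes] for j in range(count)
        ]
        offset += count
    return TargetMap(mapping)
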