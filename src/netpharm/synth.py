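"""Synthetic fixture generators with planted, machine-readable ground truth.

Every generator is a deterministic function of :class:`SimConfig.seed`.
A single integer seed is split into independent per-stage streams with
``numpy.random.SeedSequence.spawn`` in a fixed order (compounds, targets,
disease, interactions, pathways), so adding draws to one stage never
perturbs another.  Each stage records what it planted (hub compounds,
disease overlap, interaction hubs, the enriched pathway) in a truth log
that downstream recovery tests score against.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .core import CompoundRecord, GeneSet, TargetMap
from .screen import ScreenConfig, dedupe_compounds, screen_compounds
from .ppi import ScoredEdgeSet

OB_MIN, DL_MIN = 30.0, 0.18  # screen thresholds the generators target


@dataclass
class SimConfig:
    seed: int = 0
    # compound table
    n_herbs: int = 9
    n_compounds_per_herb: int = 30
    duplicate_rate: float = 0.10
    bioactive_fraction: float = 0.30
    # target map
    n_targets_universe: int = 120
    target_mean: float = 3.0
    target_max: int = 12
    hub_target_counts: tuple[int, ...] = (45, 40, 36, 32, 28)
    # disease genes
    n_disease_genes: int = 200
    overlap_fraction: float = 0.50
    # scored interactions
    ppi_density: float = 0.15
    ppi_pass_fraction: float = 0.50
    n_ppi_hubs: int = 4
    # pathway collection
    n_pathways: int = 30
    pathway_size_range: tuple[int, int] = (30, 45)
    planted_pathway_index: int = 0
    enrichment_boost: int = 12

    def __post_init__(self) -> None:
        for name in ("duplicate_rate", "bioactive_fraction", "overlap_fraction",
                     "ppi_density", "ppi_pass_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if min(self.n_herbs, self.n_compounds_per_herb) < 1:
            raise ValueError("need at least one herb and one compound per herb")
        if self.target_max < 1 or self.target_mean < 1:
            raise ValueError("target counts must be positive")
        if max(self.hub_target_counts, default=0) > self.n_targets_universe:
            raise ValueError("hub target counts exceed the gene universe")
        if not 0 <= self.planted_pathway_index < self.n_pathways:
            raise ValueError("planted pathway index out of range")
        lo, hi = self.pathway_size_range
        if not 1 <= lo <= hi:
            raise ValueError("bad pathway size range")

    def rngs(self) -> dict[str, np.random.Generator]:
        streams = np.random.SeedSequence(self.seed).spawn(6)
        names = ("compounds", "targets", "disease", "ppi", "gmt", "sources")
        return {n: np.random.default_rng(s) for n, s in zip(names, streams)}


def _draw_attrs(rng: np.random.Generator, bioactive: bool) -> tuple[float, float]:
    """(ob, dl) pair landing on the requested side of the screen."""
    if bioactive:
        return float(rng.uniform(OB_MIN, 100.0)), float(rng.uniform(DL_MIN, 1.0))
    mode = int(rng.integers(3))  # fail ob, fail dl, or fail both
    ob = float(rng.uniform(0.0, OB_MIN)) if mode != 1 else float(rng.uniform(OB_MIN, 100.0))
    dl = float(rng.uniform(0.0, DL_MIN)) if mode != 0 else float(rng.uniform(DL_MIN, 1.0))
    return ob, dl


def gen_compound_table(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> list[CompoundRecord]:
    """Herb-expanded compound listings with planted cross-herb duplicates.

    Each new compound is bioactive (both attributes above the screen
    thresholds) with probability ``bioactive_fraction``; with probability
    ``duplicate_rate`` a slot instead re-lists an existing compound under
    the current herb, preserving its attributes.
    """
    rng = rng if rng is not None else cfg.rngs()["compounds"]
    herbs = [f"HERB{i:02d}" for i in range(1, cfg.n_herbs + 1)]
    records: list[CompoundRecord] = []
    pool: list[CompoundRecord] = []  # first listing of each compound
    membership: dict[str, set[str]] = {}
    serial = 0
    for herb in herbs:
        for _ in range(cfg.n_compounds_per_herb):
            candidates = [
                c for c in pool if herb not in membership[c.mol_id]
            ]
            if candidates and rng.random() < cfg.duplicate_rate:
                src = candidates[int(rng.integers(len(candidates)))]
                rec = CompoundRecord(
                    mol_id=src.mol_id, name=src.name, ob=src.ob,
                    dl=src.dl, herb=herb,
                )
                membership[src.mol_id].add(herb)
            else:
                serial += 1
                mol_id = f"MOLS{serial:05d}"
                ob, dl = _draw_attrs(rng, bool(rng.random() < cfg.bioactive_fraction))
                rec = CompoundRecord(
                    mol_id=mol_id, name=f"compound-{serial}", ob=ob, dl=dl,
                    herb=herb,
                )
                pool.append(rec)
                membership[mol_id] = {herb}
            records.append(rec)
    return records


def gen_target_map(
    cfg: SimConfig,
    records: list[CompoundRecord],
    rng: np.random.Generator | None = None,
) -> tuple[TargetMap, dict]:
    """Per-compound target sets with heavy-tailed counts and planted hubs.

    Background counts are truncated-geometric; the planted hub compounds
    (chosen among screen survivors so the pipeline keeps them) receive
    ``hub_target_counts``, all larger than the background cap.
    """
    rng = rng if rng is not None else cfg.rngs()["targets"]
    universe = [f"T{i:04d}" for i in range(1, cfg.n_targets_universe + 1)]
    unique_all, _ = dedupe_compounds(records)
    screened, _ = dedupe_compounds(screen_compounds(records, ScreenConfig()))
    n_hubs = len(cfg.hub_target_counts)
    if len(screened) < n_hubs:
        raise ValueError("not enough screen survivors to plant hub compounds")
    hub_idx = rng.choice(len(screened), size=n_hubs, replace=False)
    hub_counts = {
        screened[int(i)].mol_id: int(c)
        for i, c in zip(hub_idx, cfg.hub_target_counts)
    }
    mapping: dict[str, list[str]] = {}
    for comp in unique_all:
        if comp.mol_id in hub_counts:
            count = hub_counts[comp.mol_id]
        else:
            count = min(cfg.target_max, int(rng.geometric(1.0 / cfg.target_mean)))
        picks = rng.choice(len(universe), size=count, replace=False)
        mapping[comp.mol_id] = [universe[int(i)] for i in picks]
    truth = {
        "hub_compounds": {m: c for m, c in sorted(hub_counts.items())},
        "n_gene_universe": cfg.n_targets_universe,
    }
    return TargetMap(mapping), truth


def gen_disease_genes(
    cfg: SimConfig,
    target_map: TargetMap,
    rng: np.random.Generator | None = None,
) -> tuple[GeneSet, dict]:
    """Disease gene set with an exactly constructed drug-target overlap.

    Exactly ``round(overlap_fraction * n_disease_genes)`` members are
    drawn from the drug-target union; the remainder are novel symbols
    disjoint from it.  The overlap count is constructed, not sampled.
    """
    rng = rng if rng is not None else cfg.rngs()["disease"]
    union = sorted(target_map.all_genes())
    n_overlap = round(cfg.overlap_fraction * cfg.n_disease_genes)
    if n_overlap > len(union):
        raise ValueError(
            f"requested overlap {n_overlap} exceeds drug-target union "
            f"size {len(union)}"
        )
    picks = rng.choice(len(union), size=n_overlap, replace=False)
    shared = {union[int(i)] for i in picks}
    novel = {
        f"D{i:04d}" for i in range(1, cfg.n_disease_genes - n_overlap + 1)
    }
    genes = GeneSet(label="disease", genes=frozenset(shared | novel))
    truth = {
        "n_disease_genes": cfg.n_disease_genes,
        "n_overlap": n_overlap,
        "overlap_genes": sorted(shared),
    }
    return genes, truth


def split_sources(
    genes: GeneSet, n_sources: int = 3, rng: np.random.Generator | None = None
) -> list[GeneSet]:
    """Split a gene set into overlapping per-database lists whose union is it."""
    rng = rng if rng is not None else np.random.default_rng(0)
    buckets: list[set[str]] = [set() for _ in range(n_sources)]
    for gene in sorted(genes.genes):
        home = int(rng.integers(n_sources))
        buckets[home].add(gene)
        for j in range(n_sources):  # extra memberships create overlap regions
            if j != home and rng.random() < 0.3:
                buckets[j].add(gene)
    return [
        GeneSet(label=f"source{i + 1}", genes=frozenset(b), source="synthetic")
        for i, b in enumerate(buckets)
    ]


def gen_ppi(
    cfg: SimConfig, genes: GeneSet, rng: np.random.Generator | None = None
) -> tuple[ScoredEdgeSet, dict]:
    """Scored edges over ``genes`` with planted always-passing hub nodes.

    Background pairs appear at ``ppi_density``; a passing score (above
    0.9 on the unit scale) is drawn with ``ppi_pass_fraction``.  Each of
    the ``n_ppi_hubs`` planted nodes is wired to every other node with a
    passing score, so after filtering its degree is the maximum possible.
    """
    rng = rng if rng is not None else cfg.rngs()["ppi"]
    nodes = sorted(genes.genes)
    if len(nodes) < cfg.n_ppi_hubs + 2:
        raise ValueError("gene set too small for the requested hub count")
    hub_idx = rng.choice(len(nodes), size=cfg.n_ppi_hubs, replace=False)
    hubs = sorted(nodes[int(i)] for i in hub_idx)
    edges = ScoredEdgeSet(scale="unit")
    n_pass = 0
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            a, b = nodes[i], nodes[j]
            is_hub_edge = a in hubs or b in hubs
            if not is_hub_edge and rng.random() >= cfg.ppi_density:
                continue
            passing = is_hub_edge or (rng.random() < cfg.ppi_pass_fraction)
            score = (
                float(rng.uniform(0.901, 0.999))
                if passing
                else float(rng.uniform(0.15, 0.899))
            )
            edges.add(a, b, score)
            if passing:
                n_pass += 1
    truth = {
        "ppi_hubs": hubs,
        "n_edges_total": len(edges),
        "n_edges_pass": n_pass,
    }
    return edges, truth


def gen_gmt(
    cfg: SimConfig,
    universe: GeneSet,
    query: GeneSet,
    rng: np.random.Generator | None = None,
) -> tuple[list[GeneSet], dict]:
    """Pathway collection with one planted enriched pathway.

    Null pathways are uniform draws from the universe.  The planted
    pathway overlaps the query by exactly ``round(n*K/N) + boost`` genes,
    i.e. the integer null expectation plus the configured boost.
    """
    rng = rng if rng is not None else cfg.rngs()["gmt"]
    uni = sorted(universe.genes)
    qry = sorted(query.genes & universe.genes)
    non_query = sorted(universe.genes - query.genes)
    N, n = len(uni), len(qry)
    lo, hi = cfg.pathway_size_range
    sets: list[GeneSet] = []
    truth: dict = {}
    for i in range(cfg.n_pathways):
        label = f"PW{i + 1:03d}"
        K = int(rng.integers(lo, hi + 1))
        if i == cfg.planted_pathway_index:
            expected = n * K / N
            k = int(round(expected)) + cfg.enrichment_boost
            if k > min(n, K) or K - k > len(non_query):
                raise ValueError(
                    f"planted enrichment infeasible: k={k}, K={K}, n={n}, N={N}"
                )
            inside = rng.choice(len(qry), size=k, replace=False)
            outside = rng.choice(len(non_query), size=K - k, replace=False)
            members = {qry[int(x)] for x in inside} | {
                non_query[int(x)] for x in outside
            }
            truth = {
                "planted_pathway": label,
                "planted_k": k,
                "null_expectation": expected,
            }
        else:
            picks = rng.choice(N, size=K, replace=False)
            members = {uni[int(x)] for x in picks}
        sets.append(GeneSet(label=label, genes=frozenset(members), source="synthetic"))
    return sets, truth


@dataclass
class SimOutput:
    """Everything one seed generates, plus the combined truth log."""

    config: SimConfig
    records: list[CompoundRecord]
    target_map: TargetMap
    disease: GeneSet
    disease_sources: list[GeneSet]
    common: GeneSet
    ppi_edges: ScoredEdgeSet
    pathways: list[GeneSet]
    truth: dict = field(default_factory=dict)


def simulate_all(cfg: SimConfig) -> SimOutput:
    """Run every generator in order under the documented seed split."""
    rngs = cfg.rngs()
    records = gen_compound_table(cfg, rngs["compounds"])
    target_map, t_truth = gen_target_map(cfg, records, rngs["targets"])
    disease, d_truth = gen_disease_genes(cfg, target_map, rngs["disease"])
    sources = split_sources(disease, 3, rngs["sources"])
    # the pipeline intersects against targets of *screened* compounds only,
    # so the truth log does the same
    screened, _ = dedupe_compounds(screen_compounds(records, ScreenConfig()))
    drug_union = frozenset().union(
        *(target_map.get(u.mol_id, frozenset()) for u in screened)
    )
    common = GeneSet(label="common", genes=disease.genes & drug_union)
    ppi_edges, p_truth = gen_ppi(cfg, common, rngs["ppi"])
    universe = GeneSet(
        label="universe", genes=target_map.all_genes() | disease.genes
    )
    pathways, g_truth = gen_gmt(cfg, universe, common, rngs["gmt"])
    truth = {
        "seed": cfg.seed,
        **t_truth,
        **d_truth,
        **p_truth,
        **g_truth,
        "n_common_genes": len(common),
    }
    return SimOutput(
        config=cfg,
        records=records,
        target_map=target_map,
        disease=disease,
        disease_sources=sources,
        common=common,
        ppi_edges=ppi_edges,
        pathways=pathways,
        truth=truth,
    )


def write_fixtures(cfg: SimConfig, outdir) -> dict:
    """Emit every file format the pipeline reads, plus ``truth.json``."""
    import os

    from .core import (
        write_compound_table,
        write_gene_list,
        write_gmt,
        write_target_map,
    )

    os.makedirs(outdir, exist_ok=True)
    out = simulate_all(cfg)
    write_compound_table(out.records, os.path.join(outdir, "compounds.tsv"))
    write_target_map(out.target_map, os.path.join(outdir, "target_map.tsv"))
    for i, src in enumerate(out.disease_sources, start=1):
        write_gene_list(src, os.path.join(outdir, f"disease_genes_{i}.txt"))
    out.ppi_edges.to_tsv(os.path.join(outdir, "ppi_edges.tsv"))
    write_gmt(out.pathways, os.path.join(outdir, "pathways.gmt"))
    payload = {"config": asdict(cfg), "truth": out.truth}
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return payload
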