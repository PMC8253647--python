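"""End-to-end orchestration: screen -> intersect -> network -> interactions
-> enrichment -> docking ranking, with a deterministic run manifest.

The manifest records the package version, seed, parameters, a sha256 of
every input, and the headline count at each filtering step, so the whole
chain of counts is auditable from one JSON file.  It contains no
timestamps: re-running with identical inputs and config yields an
identical manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import platform
from dataclasses import asdict, dataclass, field

import yaml

from . import __version__
from .core import (
    ConfigError,
    GeneSet,
    NetpharmError,
    read_compound_table,
    read_gene_list,
    read_gmt,
    read_target_map,
    write_gene_list,
)
from .docking import rank_pairs, read_docking_scores, spontaneity_check
from .enrichment import bubble_export, enrich
from .intersect import intersect_with_targets, union_gene_sources, venn_summary
from .multinet import (
    build_multinetwork,
    degree_report,
    select_key_nodes,
    write_degree_report,
    write_graphml,
    write_sif,
)
from .ppi import ScoredEdgeSet, filter_edges, hub_stats, induce_subnetwork
from .screen import ScreenConfig, dedupe_compounds, screen_compounds, summarize_by_herb

logger = logging.getLogger(__name__)


class PipelineError(NetpharmError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")


@dataclass
class PipelineConfig:
    compounds: str
    targets: str
    disease_lists: list[str]
    outdir: str
    ppi_edges: str | None = None
    gmt: str | None = None
    docking: str | None = None
    ob_min: float = 30.0
    dl_min: float = 0.18
    inclusive: bool = True
    ppi_min_score: float = 0.9
    ppi_scale: str = "thousand"
    ppi_strict: bool = True
    p_max: float = 0.05
    top_n_pathways: int = 30
    adjust: str = "none"
    top_k_compounds: int = 5
    top_k_targets: int = 4
    seed: int = 0
    _extra: dict = field(default_factory=dict, repr=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        try:
            with open(path) as fh:
                raw = yaml.safe_load(fh) or {}
        except OSError as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from None
        if not isinstance(raw, dict):
            raise ConfigError("pipeline config must be a YAML mapping")
        known = {f for f in cls.__dataclass_fields__ if not f.startswith("_")}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        missing = {"compounds", "targets", "disease_lists", "outdir"} - set(raw)
        if missing:
            raise ConfigError(f"missing required config keys: {sorted(missing)}")
        return cls(**raw)

    def validate(self) -> None:
        for label, p in self.input_paths().items():
            if p is not None and not os.path.exists(p):
                raise ConfigError(f"input {label!r} does not exist: {p}")
        ScreenConfig(self.ob_min, self.dl_min, self.inclusive)  # bounds check

    def input_paths(self) -> dict[str, str | None]:
        paths: dict[str, str | None] = {
            "compounds": self.compounds,
            "targets": self.targets,
            "ppi_edges": self.ppi_edges,
            "gmt": self.gmt,
            "docking": self.docking,
        }
        for i, p in enumerate(self.disease_lists, start=1):
            paths[f"disease_list_{i}"] = p
        return paths


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage in order and return the run manifest.

    A stage failure aborts the run with the stage name; artifacts written
    by earlier stages are preserved in the output directory.
    """
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    out = lambda name: os.path.join(config.outdir, name)  # noqa: E731

    manifest: dict = {
        "tool": {"name": "netpharm", "version": __version__,
                 "python": platform.python_version()},
        "seed": config.seed,
        "parameters": {
            k: v for k, v in asdict(config).items() if not k.startswith("_")
        },
        "inputs": {
            label: {"path": p, "sha256": _sha256(p)}
            for label, p in config.input_paths().items()
            if p is not None
        },
        "counts": {},
        "stages_completed": [],
    }
    counts = manifest["counts"]

    def stage(name):
        def deco(fn):
            try:
                fn()
            except NetpharmError as exc:
                raise PipelineError(name, str(exc)) from exc
            except Exception as exc:  # pragma: no cover - defensive
                raise PipelineError(name, f"{type(exc).__name__}: {exc}") from exc
            manifest["stages_completed"].append(name)
            logger.info("stage %s done: %s", name, counts)
        return deco

    state: dict = {}

    @stage("screen")
    def _screen():
        records = read_compound_table(config.compounds)
        screen_cfg = ScreenConfig(config.ob_min, config.dl_min, config.inclusive)
        screened = screen_compounds(records, screen_cfg)
        unique, n_removed = dedupe_compounds(screened)
        tmap = read_target_map(config.targets)
        from .core import write_compound_table

        write_compound_table(screened, out("screened.tsv"))
        summaries = summarize_by_herb(records, screened, tmap)
        with open(out("herb_summary.tsv"), "w") as fh:
            fh.write("herb\tn_compounds\tn_bioactive\tn_targets\n")
            for s in summaries:
                fh.write(f"{s.herb}\t{s.n_compounds}\t{s.n_bioactive}\t{s.n_targets}\n")
        counts["n_listings"] = len(records)
        counts["n_bioactive_listings"] = len(screened)
        counts["n_duplicates_removed"] = n_removed
        counts["n_unique_compounds"] = len(unique)
        counts["n_herbs"] = len({u for r in screened for u in (r.herb,)})
        state.update(records=records, unique=unique, tmap=tmap)

    @stage("intersect")
    def _intersect():
        sources = [
            read_gene_list(p, label=f"source{i}")
            for i, p in enumerate(config.disease_lists, start=1)
        ]
        union = union_gene_sources(sources)
        drug_targets = GeneSet(
            label="drug_targets",
            genes=frozenset().union(
                *(state["tmap"].get(u.mol_id, frozenset()) for u in state["unique"])
            ),
        )
        common = intersect_with_targets(union.genes, drug_targets)
        venn = venn_summary(sources, drug_targets)
        venn.to_json(out("venn.json"))
        write_gene_list(common, out("common_genes.txt"))
        counts["n_disease_union"] = len(union)
        counts["n_drug_targets"] = len(drug_targets.genes)
        counts["n_common_genes"] = len(common)
        state.update(common=common)

    @stage("multinetwork")
    def _network():
        net = build_multinetwork(state["unique"], state["tmap"], state["common"])
        report = degree_report(net)
        write_graphml(net, out("multinet.graphml"))
        write_sif(net, out("multinet.sif"))
        write_degree_report(report, out("degrees.tsv"))
        key = select_key_nodes(report, "compound", "above-mean")
        top = select_key_nodes(
            report, "compound", "top-k", k=config.top_k_compounds
        )
        parts = {"herb": 0, "compound": 0, "gene": 0}
        for p in report.partitions.values():
            parts[p] += 1
        counts["network_nodes"] = dict(parts)
        counts["network_edges"] = net.number_of_edges()
        counts["network_mean_degree"] = round(report.network_mean, 3)
        counts["n_key_compounds"] = len(key)
        manifest["top_compounds"] = top

    @stage("ppi")
    def _ppi():
        if config.ppi_edges is None:
            logger.info("no interaction edges supplied; skipping")
            return
        edges = ScoredEdgeSet.from_tsv(config.ppi_edges, scale=config.ppi_scale)
        kept = filter_edges(edges, config.ppi_min_score, strict=config.ppi_strict)
        net = induce_subnetwork(kept, state["common"], drop_isolated=True)
        stats = hub_stats(net, top_k=config.top_k_targets)
        kept.to_tsv(out("ppi_filtered.tsv"))
        import networkx as nx

        nx.write_graphml(net.graph, out("ppi.graphml"))
        counts["ppi_edges_in"] = len(edges)
        counts["ppi_edges_kept"] = len(kept)
        counts["ppi_nodes"] = net.n_nodes
        counts["ppi_edges"] = net.n_edges
        counts["ppi_dropped_genes"] = len(net.dropped)
        counts["ppi_mean_degree"] = stats.mean_degree_rounded
        counts["n_ppi_hubs"] = len(stats.hubs)
        manifest["top_targets"] = stats.top

    @stage("enrich")
    def _enrich():
        if config.gmt is None:
            logger.info("no pathway collection supplied; skipping")
            return
        collection = read_gmt(config.gmt)
        results = enrich(
            state["common"],
            collection,
            p_max=config.p_max,
            top_n=config.top_n_pathways,
            adjust=config.adjust,
        )
        bubble_export(results, out("enrichment.tsv"))
        counts["n_pathways_tested"] = len(collection)
        counts["n_significant_pathways"] = len(results)
        manifest["top_pathway"] = results[0].pathway if results else None

    @stage("docking")
    def _docking():
        if config.docking is None:
            logger.info("no docking scores supplied; skipping")
            return
        matrix = read_docking_scores(config.docking)
        ranked = rank_pairs(matrix, per="target")
        spont = spontaneity_check(matrix)
        with open(out("docking_best_per_target.tsv"), "w") as fh:
            fh.write("target\tcompound\tenergy\n")
            for c, t, e in ranked:
                fh.write(f"{t}\t{c}\t{e}\n")
        counts["docking_pairs_flagged_nonspontaneous"] = spont.n_flagged
        manifest["docking_best_per_target"] = {t: c for c, t, _ in ranked}

    with open(out("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
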