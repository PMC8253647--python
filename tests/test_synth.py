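import json
import math

import numpy as np
import pytest

from netpharm.core import GeneSet
from netpharm.ppi import filter_edges
from netpharm.screen import dedupe_compounds, screen_compounds
from netpharm.synth import (
    SimConfig,
    gen_compound_table,
    gen_disease_genes,
    gen_gmt,
    gen_ppi,
    gen_target_map,
    simulate_all,
    split_sources,
    write_fixtures,
)


class TestSimConfig:
    def test_defaults_valid(self):
        SimConfig()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"duplicate_rate": 1.5},
            {"bioactive_fraction": -0.1},
            {"hub_target_counts": (500,)},
            {"planted_pathway_index": 99},
            {"pathway_size_range": (10, 5)},
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)


class TestCompoundTable:
    def test_no_duplicates_when_rate_zero(self):
        cfg = SimConfig(seed=1, duplicate_rate=0.0)
        records = gen_compound_table(cfg)
        _, n_removed = dedupe_compounds(records)
        assert n_removed == 0

    def test_all_bioactive_when_fraction_one(self):
        cfg = SimConfig(seed=1, bioactive_fraction=1.0, duplicate_rate=0.0)
        records = gen_compound_table(cfg)
        assert len(screen_compounds(records)) == len(records)

    def test_pass_fraction_within_three_se(self):
        cfg = SimConfig(
            seed=4,
            n_herbs=10,
            n_compounds_per_herb=100,
            duplicate_rate=0.0,
            bioactive_fraction=0.15,
        )
        records = gen_compound_table(cfg)
        assert len(records) == 1000
        frac = len(screen_compounds(records)) / len(records)
        se = math.sqrt(0.15 * 0.85 / 1000)
        assert abs(frac - 0.15) <= 3 * se

    def test_seed_determinism(self):
        a = gen_compound_table(SimConfig(seed=12))
        b = gen_compound_table(SimConfig(seed=12))
        assert a == b


class TestTargetMap:
    def test_planted_hubs_in_truth_log(self):
        cfg = SimConfig(seed=2, hub_target_counts=(30, 19, 15))
        records = gen_compound_table(cfg)
        tmap, truth = gen_target_map(cfg, records)
        assert sorted(truth["hub_compounds"].values(), reverse=True) == [30, 19, 15]
        for mol, count in truth["hub_compounds"].items():
            assert len(tmap[mol]) == count

    def test_no_negative_counts(self):
        cfg = SimConfig(seed=3)
        records = gen_compound_table(cfg)
        tmap, _ = gen_target_map(cfg, records)
        assert all(len(ts) >= 1 for ts in tmap.values())

    def test_background_mean_within_three_se(self):
        # truncated-geometric background: compare against its own
        # simulated expectation rather than the untruncated 1/p mean
        cfg = SimConfig(seed=5, n_herbs=12, n_compounds_per_herb=60,
                        duplicate_rate=0.0)
        records = gen_compound_table(cfg)
        tmap, truth = gen_target_map(cfg, records)
        background = [
            len(ts)
            for mol, ts in tmap.items()
            if mol not in truth["hub_compounds"]
        ]
        rng = np.random.default_rng(123)
        ref = np.minimum(
            cfg.target_max, rng.geometric(1.0 / cfg.target_mean, size=200_000)
        )
        se = np.std(background, ddof=1) / math.sqrt(len(background))
        assert abs(np.mean(background) - ref.mean()) <= 3 * se


class TestDiseaseGenes:
    def _map(self, cfg):
        records = gen_compound_table(cfg)
        return gen_target_map(cfg, records)[0]

    def test_zero_overlap_disjoint(self):
        cfg = SimConfig(seed=6, overlap_fraction=0.0)
        tmap = self._map(cfg)
        genes, truth = gen_disease_genes(cfg, tmap)
        assert truth["n_overlap"] == 0
        assert not (genes.genes & tmap.all_genes())

    def test_full_overlap_subset(self):
        cfg = SimConfig(seed=6, overlap_fraction=1.0, n_disease_genes=50)
        tmap = self._map(cfg)
        genes, _ = gen_disease_genes(cfg, tmap)
        assert genes.genes <= tmap.all_genes()

    def test_constructed_overlap_exact(self):
        cfg = SimConfig(seed=6, overlap_fraction=0.2, n_disease_genes=240)
        tmap = self._map(cfg)
        genes, truth = gen_disease_genes(cfg, tmap)
        assert truth["n_overlap"] == 48
        assert len(genes.genes & tmap.all_genes()) == 48
        assert len(genes) == 240

    def test_split_sources_union_is_whole(self):
        cfg = SimConfig(seed=6)
        tmap = self._map(cfg)
        genes, _ = gen_disease_genes(cfg, tmap)
        sources = split_sources(genes, 3, np.random.default_rng(0))
        assert frozenset().union(*(s.genes for s in sources)) == genes.genes


class TestPpi:
    def _genes(self, n=40):
        return GeneSet("g", frozenset(f"T{i:04d}" for i in range(1, n + 1)))

    def test_zero_density_only_hub_edges(self):
        cfg = SimConfig(seed=7, ppi_density=0.0, n_ppi_hubs=2)
        edges, truth = gen_ppi(cfg, self._genes())
        endpoints = {n for e in edges.edges for n in e}
        hubs = set(truth["ppi_hubs"])
        assert all(e[0] in hubs or e[1] in hubs for e in edges.edges)
        assert hubs <= endpoints

    def test_hub_has_max_degree(self):
        cfg = SimConfig(seed=7, n_ppi_hubs=1)
        edges, truth = gen_ppi(cfg, self._genes())
        hub = truth["ppi_hubs"][0]
        degree = {}
        for a, b in edges.edges:
            degree[a] = degree.get(a, 0) + 1
            degree[b] = degree.get(b, 0) + 1
        assert degree[hub] == max(degree.values())

    def test_kept_count_matches_truth(self):
        cfg = SimConfig(seed=8)
        edges, truth = gen_ppi(cfg, self._genes(60))
        kept = filter_edges(edges, 0.9, strict=True)
        assert len(kept) == truth["n_edges_pass"]


class TestGmt:
    def _setting(self, cfg):
        universe = GeneSet("u", frozenset(f"G{i}" for i in range(220)))
        query = GeneSet("q", frozenset(f"G{i}" for i in range(100)))
        return gen_gmt(cfg, universe, query)

    def test_planted_k_is_expectation_plus_boost(self):
        cfg = SimConfig(seed=9)
        sets, truth = self._setting(cfg)
        planted = next(s for s in sets if s.label == truth["planted_pathway"])
        k = len(planted.genes & {f"G{i}" for i in range(100)})
        assert k == truth["planted_k"]
        assert k == round(truth["null_expectation"]) + cfg.enrichment_boost

    def test_sizes_within_range(self):
        cfg = SimConfig(seed=9)
        sets, _ = self._setting(cfg)
        lo, hi = cfg.pathway_size_range
        assert all(lo <= len(s.genes) <= hi for s in sets)

    def test_boost_zero_means_no_signal(self):
        cfg = SimConfig(seed=9, enrichment_boost=0)
        sets, truth = self._setting(cfg)
        planted = next(s for s in sets if s.label == truth["planted_pathway"])
        k = len(planted.genes & {f"G{i}" for i in range(100)})
        assert k == round(truth["null_expectation"])


class TestEndToEnd:
    def test_same_seed_byte_identical_fixtures(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_fixtures(SimConfig(seed=21), d1)
        write_fixtures(SimConfig(seed=21), d2)
        for name in sorted(p.name for p in d1.iterdir()):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes(), name

    def test_truth_json_is_machine_readable(self, tmp_path):
        write_fixtures(SimConfig(seed=22), tmp_path)
        payload = json.loads((tmp_path / "truth.json").read_text())
        assert {"hub_compounds", "ppi_hubs", "planted_pathway", "n_overlap"} <= set(
            payload["truth"]
        )

    def test_default_config_recovery_across_seeds(self):
        # >= 4 of 5 planted hub compounds in the top-5 and planted pathway
        # ranked first, in >= 90% of 50 seeds
        from netpharm.enrichment import enrich
        from netpharm.multinet import build_multinetwork, degree_report, select_key_nodes

        n_seeds, ok = 50, 0
        for seed in range(n_seeds):
            out = simulate_all(SimConfig(seed=seed))
            unique, _ = dedupe_compounds(screen_compounds(out.records))
            net = build_multinetwork(unique, out.target_map, out.common)
            top5 = select_key_nodes(
                degree_report(net), "compound", "top-k", k=5
            )
            hubs_ok = len(set(top5) & set(out.truth["hub_compounds"])) >= 4
            results = enrich(out.common, out.pathways, p_max=1.1, top_n=None)
            pathway_ok = results[0].pathway == out.truth["planted_pathway"]
            ok += hubs_ok and pathway_ok
        assert ok >= 0.9 * n_seeds
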