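# netpharm

A network-pharmacology analysis pipeline for multi-herb formulas. Given a
compound table with oral-bioavailability (OB) and drug-likeness (DL)
attributes, compound→target maps, disease-gene lists, scored
protein-interaction edges, pathway gene sets (GMT) and docking
binding-energy matrices, it:

1. **screens** compounds at OB ≥ 30% and DL ≥ 0.18 (inclusive, configurable)
   and deduplicates cross-herb listings;
2. **intersects** the union of disease-gene sources with the screened
   compounds' targets, with full Venn region counts;
3. builds the **herbs–compounds–genes tripartite network**, computes node
   degrees and selects key compounds above the whole-network mean degree;
4. filters **scored interaction edges** at confidence > 0.9 (strict),
   induces the target subnetwork, and ranks hub genes;
5. runs **hypergeometric (one-sided Fisher) pathway enrichment** with raw
   p < 0.05 filtering, top-30 truncation and optional Benjamini–Hochberg
   adjustment;
6. ingests and ranks **docking binding energies** (most negative = best),
   flagging non-spontaneous (≥ 0) pairs.

A synthetic-data module generates every input format with planted ground
truth (hub compounds, disease-gene overlap, interaction hubs, one enriched
pathway) so the whole pipeline is testable offline. A small nine-herb
example dataset (per-herb summary + 50-compound table) ships inside the
package.

## CLI

```bash
# generate synthetic fixtures with ground truth
netpharm simulate --outdir fixtures/ --seed 1

# individual stages
netpharm screen --in compounds.tsv --out screened.tsv --ob-min 30 --dl-min 0.18
netpharm intersect --disease d1.txt --disease d2.txt --targets target_map.tsv \
    --out common_genes.txt --venn venn.json
netpharm network --screened screened.tsv --targets target_map.tsv \
    --genes common_genes.txt --out net.graphml --degrees degrees.tsv
netpharm ppi --edges string_export.tsv --genes common_genes.txt \
    --min-score 0.9 --scale 1000
netpharm enrich --genes common_genes.txt --gmt pathways.gmt --p-max 0.05 --top 30
netpharm docking --in docking_scores.tsv --per target

# full pipeline from a YAML config; writes a deterministic run manifest
netpharm run-all --config pipeline.yaml
```

Exit codes: 0 success, 2 configuration error, 3 stage failure.

A minimal `pipeline.yaml`:

```yaml
compounds: fixtures/compounds.tsv
targets: fixtures/target_map.tsv
disease_lists: [fixtures/disease_genes_1.txt, fixtures/disease_genes_2.txt]
ppi_edges: fixtures/ppi_edges.tsv   # optional
ppi_scale: unit                     # or "thousand" for 0-1000 scores
gmt: fixtures/pathways.gmt          # optional
docking: fixtures/docking.tsv       # optional
outdir: out/
```

## Layout

- `src/netpharm/core.py` — domain types, TSV/GMT/gene-list readers & writers
- `src/netpharm/screen.py` — OB/DL screen, dedup, per-herb summary
- `src/netpharm/intersect.py` — gene-source union, intersection, Venn counts
- `src/netpharm/multinet.py` — tripartite network, degrees, key-node selection
- `src/netpharm/ppi.py` — scored edges, confidence filter, hub statistics
- `src/netpharm/enrichment.py` — hypergeometric test, BH, bubble-plot export
- `src/netpharm/docking.py` — binding-energy matrices, ranking, spontaneity
- `src/netpharm/synth.py` — seeded generators with planted truth logs
- `src/netpharm/pipeline.py`, `cli.py` — orchestration, manifest, CLI
- `src/netpharm/data/` — bundled nine-herb example tables
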