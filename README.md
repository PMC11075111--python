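# ovaspot

Spatial-transcriptomics analysis of **aging hotspots in ovary tissue**, as a
tested, reusable Python pipeline.

Ovarian aging is driven not only by follicle loss but by the somatic
microenvironment: senescence-associated programs (inflammation, SASP,
fibrosis) concentrate in discrete tissue neighbourhoods and appear to spread
outward. Given Visium-style spot-resolved counts from young and old ovary
samples, `ovaspot` locates those neighbourhoods and quantifies how aging
signal decays around them. It is aimed at computational biologists analysing
spot-level spatial data with an age (or other two-group) contrast.

## Method

Starting from a genes × spots count matrix with spot coordinates and
per-spot sample/age metadata, the pipeline runs:

1. **QC and normalization** — genes kept when detected (count ≥ 1) in ≥ 50
   spots; `x_gs = log2(1 + 6000 · c_gs / total_s)`.
2. **Clustering and annotation** — PCA (25 PCs on the top variable genes) →
   kNN graph (k = 15) → Leiden communities; each cluster is labelled with
   the marker gene set of highest mean module score, and types map onto the
   follicle (OO, GC, TC, PPF) / non-follicle (OSE, SC, SMC, IM, MT2high)
   regions.
3. **Module scoring** — for a gene set *S*,
   `score_s = mean_{g∈S} x_gs − mean_{g∈ctrl} x_gs`, with 100 control genes
   per set gene drawn from 24 equal-size average-expression bins.
4. **Aging differential expression** — per spot type, Wilcoxon rank-sum old
   vs young with BH FDR within type; DEGs at |log2FC| > 0.5 and FDR < 0.05.
5. **OSAG and aging score** — aging DEGs intersected with a curated aging
   gene list give the ovary-specific aging genes split by direction;
   `aging_score = score(OSAG_up) − score(OSAG_down)` per spot.
6. **PCOA selection** — candidate pathway scores with Pearson *r* > 0.5
   (p < 0.05) against the OSAG-up score are the primary contributors to
   ovarian aging.
7. **Hotspot calling** — the intersection of the top-5% spot sets of the
   aging score and every PCOA score; hotspots are characterized by spot-type
   composition and by ring-binned distance decay of scores
   (Pearson *r* of ring mean vs ring distance).
8. **Spot–spot communication** — CellPhoneDB-style permutation test of
   ligand–receptor pairs between spot types, run per age group;
   pairs significant only in the old group are "gained with age".

A first-class synthetic-data module (`ovaspot.synth`) generates
Visium-like multi-sample ovary studies — hex-lattice geometry, nine planted
spot types, negative-binomial counts, age-dependent expression programs and
senescence foci with outward-decaying signal — together with the ground
truth needed to test every stage.

## Worked example

```python
import ovaspot as ov

config = ov.SimConfig(seed=7)          # 8 samples, ~3,200 spots, 2,000 genes
ds, truth = ov.simulate_dataset(config)

result = ov.run_pipeline(ds, truth.marker_sets, truth.pathway_sets,
                         truth.aging_gene_list, seed=7)

print(f"clusters: {result.clusters.max() + 1}")
print(f"OSAG: {len(result.osag.up)} up / {len(result.osag.down)} down")
print("PCOA pathways:", ", ".join(result.pcoa.index[result.pcoa.selected]))
print(f"hotspots: {len(result.hotspots.hotspot_spot_ids)} spots")
print(f"distance decay: r = {result.decay.r:.3f}, p = {result.decay.p:.2e}")
```

prints

```
clusters: 9
OSAG: 50 up / 45 down
PCOA pathways: SASP, fibrosis, senescence, inflammatory_response
hotspots: 104 spots
distance decay: r = -0.907, p = 1.85e-05
```

The nine Leiden clusters match the nine planted spot types; the OSAG lists
recover the planted aging programs (50 up-, 50 down-regulated genes, of
which 45 down survive the per-type DEG cuts); exactly the four planted
focus programs are selected as PCOA; the 104 called hotspot spots are all
MT2high and coincide with the planted senescence foci; and the aging score
falls off sharply with distance from them.

Every stage is also exposed as a shell subcommand
(`ovaspot simulate | preprocess | score | annotate | deg | hotspot | comm`)
reading and writing plain-text Matrix Market / TSV / CSV / GMT files.

## Layout

```
src/ovaspot/
  synth.py          synthetic ovary generator + ground truth
  io_preprocess.py  dataset I/O, QC, normalization, HVG, clustering
  scoring.py        GMT handling, module scores, age comparisons
  annotation.py     spot-type assignment, regions, composition
  differential.py   Wilcoxon DE, markers, shared DEGs, BH, ORA
  hotspot.py        OSAG, aging score, PCOA, hotspot calling, decay
  communication.py  ligand-receptor permutation testing
  workflow.py       end-to-end orchestration
  cli.py            shell subcommands
docs/methods.md     model, parameters, and design notes
```
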