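# cernet

Tools for building and comparing **co-expressed regulatory networks
(CERNs)** — directed TF→target networks whose gene pairs are also
co-expressed — in plants or any organism with a usable TF–target resource.

## The problem

Co-expression networks (e.g., from WGCNA) group genes into modules with
correlated expression, but their edges are undirected and say nothing about
causality. Inferred gene regulatory networks (GRNs, e.g., from
GRNBoost2/GENIE3) are directed TF→target graphs but are notoriously noisy.
`cernet` combines both lines of evidence for a pair of biological
conditions:

1. **Curated filtering.** Inferred GRN edges absent from a curated
   TF→target network (AtRegNet, DAP-seq cistrome, TF2Network, ...) are
   discarded (optional — without a curated network the GRN passes through).
2. **Edge duplication + directed intersection.** Each undirected
   co-expression pair {A, B} is duplicated into A→B and B→A; intersecting
   with the GRN keeps exactly the TF→target edges whose gene pair is
   co-expressed, preserving the regulatory direction. The result is the
   CERN, with each edge carrying both the GRN importance and the
   co-expression adjacency weight.
3. **Module comparison.** Between the two conditions' WGCNA module
   partitions, every module pair (A_i, B_j) is tested for gene overlap
   with the one-sided hypergeometric test

   p = P(X ≥ k),  X ~ Hypergeom(N, |A_i|, |B_j|),

   where N is the background universe (by default the union of both
   networks' node sets) and k the observed overlap — equivalent to
   Fisher's exact test (greater) on the 2×2 table. P-values are
   Benjamini–Hochberg adjusted across the whole module×module family and
   coded ``***``/``**``/``*`` (q < 0.001 / 0.01 / 0.05) in a dot plot
   ordered by the canonical WGCNA colour sequence, so the largest modules
   sit at the bottom-left corner.
4. **Node overlap.** Nodes of the two CERNs are classified as shared
   (yellow), unique to the first condition (green) or the second (gold),
   and the combined network is exported. Directed centralities
   (in/out-degree, betweenness, closeness, PageRank) annotate every node.

A seeded synthetic generator (block-correlated expression with planted
modules, controlled cross-condition module overlap, and a GRN with a known
truth set plus decoys) makes the whole pipeline runnable and testable
without any downloads.

## Worked example

Generate a synthetic two-condition study and run the full comparison:

```bash
cernet simulate --outdir fixtures --seed 1
cernet compare --config run.yaml
```

with `run.yaml`:

```yaml
conditions:
  - name: condA
    nodes: fixtures/Nodes_condA.txt
    edges: fixtures/Edges_condA.txt
    grn: fixtures/GRN_condA.tsv
  - name: condB
    nodes: fixtures/Nodes_condB.txt
    edges: fixtures/Edges_condB.txt
    grn: fixtures/GRN_condB.tsv
curated: fixtures/curated_tf_targets.tsv
tf_list: fixtures/tf_list.csv
output_dir: out
```

The run logs every stage:

```
INFO cernet: wrote out/condA.gmt: 6 modules, 400 genes
INFO cernet: curated filter: 885 of 1327 GRN edges retained (condA)
INFO cernet: CERN (condA): 843 of 885 GRN edges co-expressed; 298 nodes
...
INFO cernet: node overlap: 221 shared, 77 unique to condA, 77 unique to condB (combined: 375 nodes, 1233 edges)
```

Reading: of 1327 inferred regulatory edges, 885 had curated support, and
843 of those connect co-expressed gene pairs — the condA CERN. The two
CERNs share 221 genes; 375 = 221 + 77 + 77 nodes make up the combined
network. `out/enrichment.tsv` holds the module comparison:

```
module_a   module_b   k    size_a  size_b  N    p          adjusted_p  tier
turquoise  turquoise  45   60      60      400  1.877e-33  9.384e-33   ***
turquoise  blue       0    60      60      400  1.0        1.0         NE
```

The planted matched module pair (turquoise↔turquoise, 45 of 60 genes
shared) is recovered at q ≈ 1e-32; unrelated pairs are not enriched.
The bundle also contains the enrichment dot plot, per-condition GMT files,
centrality tables, and GraphML exports of each CERN and the combined
network (`out/manifest.json` records all counts and parameters).

The same stages are available as a library
(`cernet.module_enrichment`, `cernet.filter_grn`, `cernet.merge_reg_coexp`,
`cernet.network_overlap`, ...) and as individual subcommands
(`cernet enrich / integrate / overlap / gmt / simulate`).

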