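# Methods

## Pipeline model

`cernet` treats the two input networks as fixed upstream facts: an
undirected co-expression network with a module partition (WGCNA node/edge
tables exported at an adjacency threshold chosen upstream) and a directed
TF→target network with importance weights (GRNBoost2-style output). The
package performs no network inference of its own beyond the synthetic
stand-in; its contribution is the integration and comparison layer.

**CERN construction.** Every undirected co-expression pair {A, B} is
duplicated into the ordered pairs (A, B) and (B, A), both carrying the
pair's adjacency weight. The CERN edge set is the intersection of the
(optionally curated-filtered) GRN with this duplicated set, keyed on the
ordered (TF, target) identity after case normalisation. The direction of
every retained edge therefore comes from the GRN; co-expression only
gates existence. Each CERN edge keeps both the importance and the
adjacency weight rather than collapsing them into one score, since the
two weights answer different questions downstream (regulatory confidence
vs. co-expression strength).

**Assumptions.** Gene identifiers are comparable across all inputs after
upper-casing (AGI-style ids); cross-species analyses must map orthologs
to a common id space before loading. Self-loops are dropped everywhere:
neither a co-expression self-pair nor TF self-regulation has a defined
meaning in this edge-intersection semantics.

**Module overlap test.** For modules A_i (condition A) and B_j
(condition B) with k shared genes in a background universe of N genes,
the p-value is the one-sided upper tail P(X ≥ k) of
Hypergeometric(N, |A_i|, |B_j|), identical to Fisher's exact test with
alternative "greater" on the 2×2 table (k, |A_i|−k, |B_j|−k,
N−|A_i|−|B_j|+k). The upper tail is the right sidedness because the
question is over-representation of overlap. Module sizes are counted
after intersecting with the background, which is required for the 2×2
table to be well formed. The default background is the union of the two
networks' node sets; an explicit universe file can override it.
Benjamini–Hochberg adjustment is applied across all |modules_A|×|modules_B|
cells as a single family — a per-row family would make a cell's q-value
depend on which direction the comparison was run in.

**Significance tiers.** Strict thresholds on the adjusted p:
q < 0.001 → `***` (green), q < 0.01 → `**` (gold), q < 0.05 → `*`
(yellow), else `NE` drawn as `+`. The grey (unassigned) module is excluded
from the test by default because WGCNA's grey is a catch-all, not a
co-expression module; `--keep-grey` includes it.

**Dot-plot ordering.** Labels follow the canonical WGCNA colour sequence
(turquoise, blue, brown, ...), which is a size ranking by construction in
WGCNA, so the largest modules land at the bottom-left corner of the plot.
Non-canonical labels follow, ordered by descending module size then
lexicographically. Label matching strips non-alphanumerics, so
"green-yellow" and "greenyellow" are the same colour.

**Centralities.** The suite is in/out-degree, betweenness (directed,
normalized by (n−1)(n−2)), closeness (directed, incoming-distance
convention: how quickly a node is reached from the rest of the network),
and PageRank with damping 0.85. PageRank values sum to 1 over the nodes.

## Tunable parameters

| Parameter | Default | Meaning |
|---|---|---|
| `weight_floor` | none | Minimum co-expression adjacency at load time; WGCNA exports are usually already thresholded (0.9 in typical exports), so no second cut is applied by default. |
| `importance_floor` | none | Minimum GRN importance at load time; curated filtering is the preferred denoiser. |
| `filter` | on | Curated-edge GRN filtering; disabled automatically when no curated network is given. |
| `alpha_tiers` | 0.001, 0.01, 0.05 | Adjusted-p thresholds for the three significance tiers. |
| `keep_grey` | off | Include the unassigned module in the enrichment family. |

Duplicate rows in any edge list keep the maximum weight — a deterministic
rule that preserves the strongest evidence. Genes present in an edge table
but missing from the node table are kept with module "grey" and a warning,
so partial exports remain loadable.

## Synthetic generator

The generator emulates a two-condition design (default: 30 samples per
condition, mirroring a typical WGCNA-scale experiment) at desk scale:

* **Expression.** Genes of module m are x = √ρ·f_m + √(1−ρ)·ε with a
  shared standard-normal latent factor f_m per sample and independent
  noise, so any two same-module genes have population correlation exactly
  ρ (default 0.85). Unassigned genes are pure noise. This single-factor
  block model was chosen over a scale-free WGCNA-style simulation because
  the pairwise correlation is analytically known, which makes calibration
  checks exact.
* **Partitions.** Condition A tiles five 60-gene modules over a 400-gene
  universe; condition B keeps a fraction of each matched module and
  refills from genes unassigned in A so the matched-pair Jaccard hits the
  target (default 0.6; overlap = round(2js/(1+j)) for equal sizes s).
  Matched pairs are recorded as ground truth.
* **Co-expression inference.** Edges connect pairs with |Pearson r| ≥ 0.7
  (weight |r|) — a correlation-threshold stand-in for WGCNA at a scale
  where the factor model makes the outcome predictable. At ρ = 0.85 and
  30 samples, within-module pairs clear the threshold with high
  probability while the null |r| ≥ 0.7 is vanishingly rare.
* **GRN.** The first 3 genes of each module act as TFs; true edges are
  TF→same-module member with importance |r|. Decoys (0.5 × the true
  count) are random ordered pairs with low importance (uniform
  0.01–0.3), placed outside the *combined* curated set of both conditions
  so that curated filtering removes exactly the decoys; the curated
  network is exactly the union of true edges. CERN precision against the
  planted truth is therefore 1.0 by construction, and recall measures
  only co-expression-threshold losses.
* **Null partitions.** For calibration checks, `random_partition` cuts a
  shuffled 2,000-gene universe into modules of 100–400 genes (the
  relative scale of WGCNA modules in real runs: thousands of genes across
  ~13 modules), so each module is marginally a uniform random subset.

What the generator does **not** emulate: mean–variance relationships of
counts, scale-free topology, hub TFs spanning modules, microarray noise,
or the importance-score distribution of tree ensembles. Passing tests
demonstrate the correctness of the integration and testing machinery
under a clean factor model, not the end-to-end performance of WGCNA or
GRNBoost2 on real transcriptomes.

## Numerical and statistical choices

* The hypergeometric tail is computed as the survival function at k−1
  (exact at k = 0, giving p = 1).
* The exact overlap test is conservative: because p is discrete, the
  attained level at α = 0.05 is below 0.05 (≈ 0.04 at the null-partition
  sizes above). Calibration checks compare the observed rejection
  fraction against binomial bounds using the number of independent
  replicate tables — cells within one table share fixed row/column sums
  and are not independent trials.
* BH adjustment delegates to the standard step-up implementation and is
  verified in the tests against the direct formula
  q_(i) = min_{j≥i} m·p_(j)/j.
* Ties in duplicate edges, module display order and file output are
  broken deterministically (max weight; size-then-name; sorted rows), so
  a rerun with the same inputs is byte-identical.
* Degenerate inputs: empty edge tables load as edgeless networks;
  an empty CERN yields an empty centrality list and a valid GraphML;
  modules emptied by background restriction are tested with k = 0 and a
  warning rather than dropped, keeping the table rectangular.

## Design decisions on genuinely open points

* **is_tf** annotation reflects the CERN itself (out-degree ≥ 1 in the
  retained edge set), not the input TF list; the TF list, when given, is
  recorded separately per node. The CERN is the object of interest, and a
  TF whose every edge was filtered away is not acting as a regulator in it.
* The combined two-condition network keeps both sides' edge attributes
  under source-tagged keys rather than merging them — lossless, and lets
  downstream viewers distinguish condition-specific evidence.
* Problem sizes in tests and the acceptance script (400-gene universes,
  2,000-gene null calibrations, 20 replicates) were chosen so the full
  statistical battery completes in well under a minute each while leaving
  the planted signals unambiguous.

## Known limitations

* No interactive network visualisation; exports are GraphML plus static
  dot plots.
* No GO/pathway enrichment of the resulting gene sets; GMT exports are
  provided for external enrichment tools.
* The enrichment test conditions on the observed module sizes; it does
  not model uncertainty in the upstream module assignment itself.
* Single pair of conditions per run; multi-condition designs require
  pairwise runs.
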