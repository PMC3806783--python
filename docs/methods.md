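# Methods

## Scoring model

A phenotype *Ph* is a **candidate** for a query gene *G* when at least one
evidence path reaches it; candidates and their scores are computed per
gene, never globally.

**PPI path.** `S_ppi(G, Ph) = Σ s_ppi(G, P_i)` over the interaction
partners `P_i` of *G* that are known to be associated with *Ph*. The sum
(rather than max or mean) makes the score monotone in evidence: adding an
annotated interactor can only raise it. A gene's own annotation to *Ph*
is not a path.

**Orthology path.** `S_orth(G, Ph) = Σ s_orth(G, O_i) · s_phnet(O_i, Ph)`
over orthologs `O_i` of *G* in other species. `s_orth` is the cosine
similarity of the two proteins' domain-count vectors (0 when either
protein has no scanned domains), a proxy for functional conservation.
`s_phnet(O_i, Ph)` collapses the similarities between *Ph* and the
phenotypes known for `O_i` into one number; the default aggregation is
**max** (the single best-matching phenotype speaks for the ortholog), with
**sum** available — the max keeps the score insensitive to how finely an
ortholog's phenotype annotations happen to be subdivided. Only
similarity-table edges that survived the load-time filter (≥ 0.5)
contribute, and only direct ortholog→phenotype→similarity links are
followed; no transitive similarity chaining.

**Combination.** Within a gene's candidate set each raw component is
divided by its maximum (a component whose maximum is 0 normalizes to 0
everywhere — no 0/0), blended as `λ·S̄_ppi + (1−λ)·S̄_orth`, and divided
once more by the gene's maximum blend so the top candidate scores exactly
1. A sum-to-one final normalization is available
(`ScoringConfig(final_normalization="sum")`); the two are
ranking-equivalent, and max is the default because it keeps scores
interpretable as "fraction of the gene's best evidence". Ranking ties
break lexicographically on the phenotype identifier for determinism.
Scoring a phenotype (`score_phenotype`) reuses the per-gene scores
unchanged, so both entry points agree on every pair.

## Input filtering

* PPI combined score ≥ 0.5 at load; duplicate/reversed rows collapse to
  the maximum score *before* any combination, making loading
  order-independent.
* Experimentally validated pairs can be injected at a fixed score
  (default 0.9). A pair present in both sources is fused by plain
  noisy-OR `1 − (1−s_base)(1−s_inj)`, without any dataset-specific prior
  correction. An `experimental_ppi_only` switch restricts scoring to
  edges whose experimental-channel score itself clears the threshold.
* Cross-species phenotype similarity ≥ 0.5 at load; the table is
  undirected and queryable in either orientation.
* Protein-coding or identifier-namespace restrictions are the input
  preparer's responsibility; loaders validate structure, ranges, and
  species consistency (with line numbers on errors) but accept any
  identifier strings.

## Evaluation

Labels are **candidate-restricted**: only scored candidates enter a
gene's label vector (positives = candidates in the positive set,
negatives = the rest). Never-inferred phenotypes are not appended as
zero-score negatives, which would rescale the false-positive rate by the
arbitrary phenome size.

* **ROC/AUC** sweeps all distinct score thresholds with tied scores
  grouped (AUC then equals the Mann–Whitney statistic with ties at ½);
  built on scikit-learn's curve construction with trapezoidal
  integration. An instance without both label classes raises rather than
  returning a default.
* **λ tuning** evaluates the mean per-gene AUC on the panel of the most
  phenotype-annotated genes that have both PPI and orthology data (top
  100 by default), over the grid 0, 0.1, …, 1. Genes with undefined AUC
  are skipped and counted. Argmax ties break toward the **largest λ**:
  when the orthology channel carries no information every λ > 0 yields
  an identical ranking, and the convention attributes the weight to the
  informative single channel (λ = 1) instead of an arbitrary interior
  value; an uninformative PPI channel is strictly harmful at λ > 0, so
  its optimum lands at 0 under any tie rule.
* **Cutoff and MCC.** The operating point is where the ROC curve meets
  the descending diagonal (minimal |TPR − (1 − FPR)|, i.e. sensitivity ≈
  specificity), earliest threshold on ties. The Matthews correlation
  coefficient at that cutoff is compared against a null in which every
  gene's positive set is replaced by an equal-size uniform draw (without
  replacement) from its species' phenome — true positives are not
  excluded from the draw by default (a literal phenome draw; an
  exclusion variant is a flag) — repeated 100 times under a fixed seed.
* **Held-out recovery** labels candidates by the generator's held-out
  truth and drops the gene's visible (training) associations from the
  pooled list entirely: they are neither positives nor honest negatives.

## Synthetic worlds

`generate_world` plants phenotype **modules**: each phenotype owns a
random gene subset (mean size 6, overlapping freely, which emulates gene
multi-functionality), shared across species by gene index so that
orthology aligns with matched phenotypes. Defaults: 3 species, 60 genes
and 30 phenotypes per species, 40 Pfam-like domains with Zipf-skewed
popularity, Poisson(3) domains per gene.

* Co-module gene pairs are wired with probability `ppi_signal` (0.6) and
  carry high-biased scores (0.5 + 0.5·Beta(4, 1.5) plus Gaussian jitter,
  clipped to [0.5, 1]); background pairs with `ppi_noise` (0.02) and
  uniform scores on [0.5, 1]. When `ppi_signal == ppi_noise` the score
  bias is switched off too, so an uninformative network is uninformative
  through both wiring *and* weights. Scores are rounded to 6 decimals so
  worlds are exactly representable in their TSV files.
* Orthologs exist per gene index and species pair with probability
  `ortholog_fraction` (0.5); each species keeps each base domain with
  probability `ortholog_domain_retention` (0.8), which sets the scale of
  the ortholog cosines. Matched phenotypes across species connect with
  probability `phenet_signal` (0.7) at a similarity uniform on [0.5, 1].
* 30 % of the planted truth is held out per association. A held-out pair
  with no surviving path (given the post-split visible table) is
  returned to the visible set in one repair pass — re-adding
  associations can only create paths for the remaining held-out pairs,
  so a single pass suffices. Generation fails loudly if nothing can be
  held out.
* Written worlds include deliberate sub-threshold decoy rows (PPI scores
  and similarities below 0.5) so a load exercises the filters; decoys
  never exist in memory.

Presets: `default` as above; `ppi-only` (no orthology data); `orth-only`
(uniform PPI wiring, strengthened orthology: ortholog fraction and
similarity probability 0.8); `null`. The null preset keeps uniform wiring
at probability 0.165 — the default world's **expected edge density** —
rather than at the background noise rate: a density-matched null is the
standard network null model (remove the alignment, keep the density), and
at very low degree the pooled evaluation of per-gene max-normalized
scores acquires a small structural upward bias because near-empty
candidate lists pool at score 1.0 while every panel gene contributes at
least one positive. At matched density the measured null AUC is
0.53 ± 0.03 over 20 seeds; the residual +0.03 is that same finite-degree
pooling artifact, not planted signal (per-gene null AUC is 0.494).

### What the generator does and does not emulate

It reproduces the dependence structure the method relies on — module
co-annotation, score reliability, domain conservation, phenotype
matching — but not realistic PPI degree distributions (no hubs), ontology
DAG structure (similarities are flat pairwise numbers), annotation
incompleteness bias, or identifier noise. Passing tests therefore
demonstrate correctness and calibration of the machinery, not performance
on any real database snapshot; real-data AUCs and λ optima depend
entirely on the snapshot used.

## Enrichment

Upper-tail hypergeometric test of the truncated ranked gene list against
each set of a GMT collection. The query is cut at the collection's
rounded mean set size (so query and sets are comparable; an explicit
`override_n` mirrors conventions like fixed 90-gene GO or 69-gene pathway
queries). The background universe defaults to the union of the
collection's members; raw p-values are reported, Benjamini–Hochberg
q-values behind a flag.

## Numerical choices and problem sizes

* All float comparisons in ranking use exact ordering with lexicographic
  identifier tie-breaks; no epsilon fudging.
* `mcc` returns 0 whenever a marginal is empty.
* Test and acceptance runs use desk-scale worlds (≤ 3 species × 60
  genes; brute-force cross-checks on 2 × 10-gene worlds), 100
  randomization rounds, 20-seed null calibrations, and exhaustive
  hypergeometric enumeration up to a 12-gene universe; the whole suite
  runs in well under a minute on one CPU.

## Known limitations

* One-hop evidence only: no network propagation/diffusion, no paralogy,
  no transitive phenotype-similarity chaining.
* Exact term-ID matching in evaluation; no ontology-aware credit for
  ancestor/descendant hits.
* The per-species suggested λ values shipped with the CLI
  ({fly: 0.9, human: 0.8, mouse: 0.9, worm: 0.8, yeast: 0.9,
  zebrafish: 0.8}) are conventional defaults for real-data use;
  synthetic worlds tune their own λ, and the default synthetic world's
  optimum is low (orthology-heavy) because its cross-species channel is
  deliberately strong.
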