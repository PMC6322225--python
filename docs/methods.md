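# Methods

## Model

A pathway here is purely a gene set; its internal interaction topology is
out of scope. A *crosstalk region* is the intersection of two pathway gene
sets, treated as a single set per pair — when the shared genes happen to be
scattered across a pathway's molecular graph we still test them jointly,
because membership, not wiring, defines the region in this model. The
pathway crosstalk network (PXN) over a collection links every overlapping
pair; the pathway crosstalk *perturbation* network (PXPN) for a
two-condition contrast is the subgraph of enrichment-significant pathways
with edges only where the region itself is enrichment-significant.

The construction is deliberately agnostic to the abundance type and the
enrichment function. The default enrichment is fully specified here so
results are reproducible end-to-end:

1. per-gene score `u_g = |t_g|`, the absolute Welch two-sample t of group B
   vs group A (undirected perturbation — a pathway pushed down counts like
   one pushed up);
2. per-set statistic: Welch t of member vs non-member scores, upper-tail
   Student-t p with Welch–Satterthwaite degrees of freedom;
3. Benjamini–Hochberg adjustment across all sets tested in one call;
   significance at q < alpha.

Pathways (step 1) and crosstalk regions (step 3) form **separate BH
families**: each is one enrichment run over its own universe of sets. A
sampled permutation alternative (random equal-size gene sets, add-one
corrected: p = (1 + #{mean ≥ observed}) / (1 + n_perm)) and an exhaustive
enumeration variant are provided; the set-statistic argument of
`enrich`/`PxpnConfig` accepts any callable with the same signature, so a
different gene-set test can be swapped in without touching the pipeline.

## Parameters and conventions

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.05 | q-value threshold for pathways and regions (dimensionless) |
| `min_pathway_size` | 2 | scored member genes required to test a pathway |
| `min_region_test_size` | 1 | scored genes required to test a region; single-gene crosstalk is meaningful and the two-sample form stays defined |
| `min_region_size` | 1 | smallest intersection that counts as crosstalk at all |
| `u_cap` | 50 | score assigned to zero-variance genes with unequal means (and a hard cap on all scores) — keeps infinities out while preserving extreme rank |
| `trials` (Infomap) | 10 | best-of-n restarts by codelength |

Numerical conventions:

- **Singleton sets.** A one-gene group contributes zero variance to the
  Welch statistic; its degrees-of-freedom term drops out, leaving the
  non-member df. This keeps single-gene crosstalk regions testable with the
  same formula.
- **p floor.** Tail probabilities are floored at 1e-300 so p stays in
  (0, 1] even when a zero-variance set yields an infinite statistic.
- **Clustering coefficient.** Mean of local clustering over *all* nodes,
  degree-<2 nodes contributing 0. This is one of the two common
  conventions; `count_zero=False` switches to excluding such nodes. Both
  appear in the literature and differ materially on sparse graphs, so
  clustering values are only comparable within one convention.
- **Average shortest path.** Mean over reachable pairs within connected
  components; unreachable pairs are excluded. PXPNs are typically highly
  disconnected, and this convention keeps the metric finite and
  interpretable there.
- **Gene identifiers.** Exact string match by default; an optional
  case-folding mode exists for collections whose capitalization differs
  from the expression rows (e.g. murine symbols vs vendor exports).
  Case-folding is opt-in because it can silently merge distinct symbols.
- **Structure classes.** Shuffle-null networks are classified with fixed
  precedence empty → single_edge → clique → star → other, computed on the
  edge-bearing core (isolated nodes ignored): a triangle is a clique, not a
  star; a lone edge is its own class; a star needs ≥3 edges through one
  common node.

## Null models

**Rewiring.** Rewiring with probability proportional to pairwise overlap is
ambiguous between a swap-acceptance chain and resampling; it is realized
here as weighted sampling *without replacement* of E edges from all
candidate pairs (node pairs with intersecting gene sets), with weight =
pairwise Jaccard index. This is
a well-defined distribution that conserves the node set and edge count
exactly and cannot produce self-loops or multi-edges; a degree-preserving
swap chain is a different null and deliberately not implemented. Replicate
RNG streams are spawned from the master seed by index
(`numpy.random.SeedSequence`), so ensembles are reproducible and
parallelizable. Metrics whose ensemble standard deviation is zero (nodes,
edges by construction) report an undefined Z rather than a division by
zero; Z-tests use the sample sd (n−1) and a two-sided normal tail.

**Label shuffle.** Row labels of the expression matrix are permuted
uniformly; values are untouched, so every sample's value multiset is
conserved. Each replicate reruns the entire pipeline and the resulting
graph is classified. With intact biology destroyed, the pipeline should
find (mostly) nothing — the ensemble census quantifies that.

**Infomap.** python-igraph's Infomap draws from Python's global `random`
module; `detect_communities` seeds it locally (saving and restoring the
interpreter's RNG state) so partitions are deterministic given
(graph, seed, trials). Isolated nodes become singleton communities;
community ids are relabeled contiguous from 0 in node order.

## Synthetic data

The generator emulates the pipeline's input: a pathway collection with
*controlled* pairwise overlaps (each planned pair shares exactly
`overlap_size` genes, distinct per pair so no triple overlaps; unplanned
pairs are disjoint) and a two-group Gaussian abundance matrix. Defaults —
10 pathways × 20 genes, 4-gene overlaps, 200 background genes, 6 samples
per group, baseline 10, noise sd 1, effect size 3 — represent a small
two-condition profiling experiment with biological replicates and a
moderate, clearly detectable effect. In the target group, *affected* genes
are shifted by `effect_size · noise_sd`; affected genes are the exclusive
genes of planted perturbed pathways plus the shared genes of planted
perturbed regions. Shared genes of an *unplanted* region stay unshifted
even when both parents are perturbed — this keeps edge-level ground truth
unambiguous and gives every scenario a built-in true-negative edge.

What the generator does **not** emulate: count noise (negative-binomial
overdispersion), library-size and batch effects, correlated genes within a
pathway, and hierarchically nested gene sets. Gaussian abundances satisfy
the default statistic's assumptions by construction, which makes the
recovery tests sharp: they verify the pipeline's logic (set construction,
families, thresholds, graph assembly), not its robustness to real RNA-seq
noise. Passing them says the machinery is correct, not that the default
statistic is optimal for counts — for count data users may prefer to plug
in a count-aware set statistic.

Recovery scoring: node sensitivity/specificity over planted vs non-planted
pathways; edge sensitivity/specificity over planted region pairs vs all
overlapping pairs among the planted pathways. Undefined ratios (empty
denominators) are reported as None, never silently as 0 or 1.

## Problem sizes

Tests and the acceptance script run the stock scenario (10 pathways, ~380
genes, 12 samples): recovery over 50–100 simulation seeds, the
delta-0 null over 100–200 runs, shuffle ensembles of 200 replicates, and
rewiring ensembles of 1000–5000 replicates on small fixtures. These sizes
give binomial/ensemble standard errors comfortably inside the asserted
tolerances while keeping a full run in seconds; production analyses
(hundreds of pathways, 5000-replicate ensembles) use the same code paths
with the defaults in `rewire_ensemble`/`shuffle_ensemble`.

## Known limitations

- Region testing is restricted to pairs of step-1-enriched pathways by
  design; a region between one enriched and one non-enriched pathway is
  never tested.
- Edge sets are not monotone in alpha: the region BH family depends on the
  step-1 node set, so raising alpha can re-rank region q-values. Node sets
  are monotone (within one pathway enrichment run).
- BH control assumes independence or positive regression dependence across
  set statistics; overlapping gene sets violate independence, which is the
  standard caveat for all set-enrichment FDR pipelines.
- The Welch-vs-rest default ignores inter-gene correlation, like most
  competitive gene-set tests; permutation mode permutes gene labels, not
  samples, and inherits the same caveat.
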