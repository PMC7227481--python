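# Methods

## The screening model

The pipeline treats a multi-compound preparation as a set system: each
compound contributes a predicted target set; the union (the "non-repetitive"
targets) characterises the preparation; the intersection with a curated
disease target list gives the disease-relevant targets. Core-target
identification then runs on an undirected simple protein–protein interaction
(PPI) graph:

1. **Seed expansion.** For each seed set (compound targets, disease targets)
   the PPI subnetwork is the subgraph induced on the seeds plus their direct
   interactors (1 hop; configurable to 0). Induced means interactor–
   interactor edges are kept. Seeds absent from the PPI are counted and
   reported, not an error (unless none is present).
2. **Edge-wise intersection.** The compound and disease subnetworks are
   intersected: edge set E_A ∩ E_B; by default only endpoints of surviving
   edges remain (keeping common-but-isolated nodes is available via
   `keep_isolated`, since the convention cannot be inferred from headline
   node/edge counts alone).
3. **Stage 1 — degree filter.** A node survives if its degree strictly
   exceeds `degree_multiplier` (default 2.0) times the median degree of all
   nodes in the intersected network. The subgraph induced on survivors moves
   forward.
4. **Stage 2 — six-measure median filter.** On the survivor network the six
   measures DC/BC/CC/EC/NC/LAC are recomputed from scratch, each measure's
   median is taken over the survivor nodes, and a node is a core target if
   it strictly exceeds the median in every measure. Strictness mirrors
   stage 1's "more than"; a non-strict (≥) variant exists because on highly
   tied graphs (e.g. vertex-transitive ones) the strict screen is empty by
   symmetry. Fixed external cutoffs can replace the recomputed medians
   (`select_by_thresholds`), which is how a published feature table with
   published cutoff values is replayed.

Medians are recomputed on the stage-2 input network rather than inherited
from the full network: a hub network's medians are far above the global
ones, and the screen is defined relative to the population it filters.

## Centrality conventions

All six measures are implemented from first principles over adjacency sets;
the test suite checks them against independent routes (path-count identity
for BC, BFS sums for CC, dense eigendecomposition for EC, triangle counts
for NC/LAC) on random graphs and closed forms (K_n, stars).

- **DC** — plain degree, an integer.
- **BC** — unnormalized shortest-path betweenness (Brandes accumulation).
  Each unordered pair {s,t} counts once; the ordered-pair convention is
  exactly 2× on an undirected graph and is exposed as a flag, since tools
  differ and the choice rescales medians without reordering nodes.
- **CC** — component-wise closeness (|C|−1)/Σd within the node's component,
  in [0,1]; singleton components score 0. Computed per BFS; identical to
  whole-graph computation because cross-component pairs contribute nothing.
- **EC** — non-negative principal eigenvector of the adjacency matrix,
  rescaled to maximum entry 1 (a unit-Euclidean option exists). Max-entry
  normalisation is the default because it keeps values on a scale where a
  dominant clique scores exactly 1 and medians are interpretable for
  networks of any size (under unit-Euclidean norm every entry of a 564-node
  vector is ≤ 1/√564 ≈ 0.042, which makes typical reported medians like 0.3
  impossible). Computed by power iteration on A + I: the identity shift
  leaves eigenvectors unchanged while making the principal eigenvalue
  strictly dominant — bipartite graphs (stars, single edges) have spectra
  symmetric about 0 and plain iteration on A oscillates. Uniform positive
  start, tol 1e−10 on the max-norm change, max 1000 iterations,
  convergence failure is an error, not a silent result. On disconnected
  graphs the iteration runs whole-graph, so mass concentrates on the
  component with the largest spectral radius and other components decay to
  ~0; this is the documented behaviour (screen inputs are effectively
  connected around the seeds).
- **ECC / NC** — ECC(u,v) = |N(u)∩N(v)| / min(deg u−1, deg v−1), defined as
  0 when an endpoint has degree 1 (vanishing denominator); NC(v) sums ECC
  over v's incident edges. Note the degenerate consequence: on a single
  edge (K_2) both endpoints have degree 1 and NC is 0, so the K_n closed
  form (NC = n−1) holds only for n ≥ 3.
- **LAC** — mean degree of v's neighbours within the subgraph they induce,
  equal to 2·triangles(v)/deg(v); 0 for isolated nodes.
- **Medians** — per-column sample median; an even row count averages the two
  middle order statistics. Recomputed from rows on access, never cached.

## Enrichment

One-sided hypergeometric over-representation: p = P(X ≥ k) with
X ~ Hypergeometric(N, K, n), evaluated through the survival function with
log-space term accumulation (scipy), exact to the deep tail; the test suite
sweeps the full lattice N ≤ 12 against a counting oracle. The background
universe defaults to the union of all term members (annotation-based
background, the convention of desktop enrichment tools); a user-supplied
background overrides it, with terms either trimmed to it or the universe
extended by union so the subset invariant always holds. Significance is
called on raw p < α (α = 0.05 default) — matching the convention of the
tools this replaces — with Benjamini–Hochberg adjusted values always
reported in the same table so the multiple-testing question stays visible.
(BH is *not* idempotent; the tests assert its real invariants: elementwise
≥ raw p, rank-monotone, capped at 1.) Fold enrichment is (k/n)/(K/N).

## Synthetic data: what it emulates, and what it does not

Every generator is a pure function of (spec, master seed); per-generator
streams are derived as `default_rng([seed, stream_index])` with fixed
indices, so inputs regenerate independently and byte-identically.

- **Compound targets.** Exactly `planted_kway` genes appear in all
  compounds; every other gene is placed in at most n−1 compounds, so the
  k-way intersection is exact, not merely at-least. When `n_unique_targets`
  is set, non-shared genes get multiplicities (1..n−1) summing to the
  remaining interaction count and are assigned most-constrained-first
  against per-compound capacities, making the union size exact as well.
  Defaults (156/129/226/141 targets, k-way 16, union 438) are the study
  conditions the pipeline was built around.
- **Disease targets.** Exact planted overlap (default 47 of 321) against
  the compound union.
- **PPI (planted-clique model).** A complete q-clique (default q = 16 in a
  2,000-node network; the recovery benchmark uses q = 12 in 300 nodes) sits
  in a sparse Erdős–Rényi periphery (mean degree 3); each member also gets
  `clique_periphery_degree` (default 4) random periphery attachments so the
  stage-1 degree filter is non-trivial. The construction must guarantee the
  module dominates all six measures *within the stage-1 survivor network*,
  which is delicate for betweenness (a complete clique has internal BC 0)
  and for the medians (survivors are few, so the median can land inside the
  module's own value range). Both are solved by **decoy hubs**:
  q + ⌈0.1·n⌉ nodes adjacent to every clique member and to nothing else.
  Decoys (degree q) pass stage 1; they hand every clique member strictly
  positive betweenness (all decoy↔network shortest paths run through
  members); their own betweenness is exactly 0 (their neighbourhoods are
  mutually adjacent); and they are numerous enough that, together with the
  sparse degree-tail survivors, they hold the majority in the survivor
  network, pinning each stage-2 median at or below the constant decoy level
  — strictly below every member's value in all six measures. Coverage
  wiring (one edge from any seed-distant node to a random seed) is applied
  in the end-to-end pipeline so 1-hop expansions span the network and the
  screen sees the full planted structure. Erdős–Rényi and
  preferential-attachment models are available as structureless controls.
- **Annotations.** Planted terms draw `round(size·fold·|query|/N)` members
  from the query, the rest from outside; background terms draw uniformly.
  The annotation background is its own smaller universe (default 1,000
  genes plus the query) — annotated genomes are far smaller than symbol
  space, and a size-20 term cannot reach a 10-fold overlap against a
  5,000-gene background with a 47-gene query.
- **Cell types.** Exact per-cell-type association counts (defaults
  31/14/13/11 for neuron/astrocyte/endothelial/microglia).
- **Feature table.** A synthetic stand-in for a published supplementary
  six-measure table (which is not redistributable here): 564 rows whose
  per-column median equals the published cutoff vector exactly
  (95 / 240.7 / 0.53 / 0.3 / 19.74 / 17.77) and in which exactly 189 rows
  strictly exceed all six cutoffs; every other row carries a designated
  failing measure, so the planted core is exact. Per column the order
  statistics are arranged as 281 below / 2 at / 281 above the cutoff, which
  fixes the even-count median at the cutoff itself.

What the synthetic family does **not** emulate: realistic PPI degree
distributions (BioGRID-like heavy tails), database disagreement and symbol
aliasing, correlated annotation terms (GO DAG structure), or graded
cell-type association scores. Passing tests therefore demonstrate that the
algorithms recover what the statistics of the inputs put there — not that
any particular biological conclusion transfers to live databases.

## Numerical and degenerate-input choices

- Gene symbols are whitespace-stripped and uppercased at ingest
  (configurable off); no alias/HGNC resolution — merged databases are
  reconciled by symbol only, as any resolution step would change counts
  unpredictably.
- Graphs are simple and undirected: self-loop lines are dropped (and
  tallied), duplicate and reversed edges collapse.
- Duplicate (compound, target) rows collapse to one record with provenance
  strings concatenated.
- Empty screens raise errors naming the stage (`EmptyStageError`) rather
  than returning silently empty sets; the pipeline writes a `FAILED` marker
  file before propagating.
- Ties: stage-1 and default stage-2 comparisons are strict, so an all-tied
  network legitimately screens to empty (K_n under strict medians).
- Written artifacts sort nodes/edges/terms, so identical runs are
  byte-identical.

## Problem sizes

The shipped defaults — 2,000-node PPI end-to-end, 300-node instances for
the 20-seed recovery benchmark, n ≤ 60 for the brute-force oracle suite —
were chosen so the full test suite and the reproduction script each run in
well under a minute on a laptop-class single core while still exercising
every code path at non-toy scale.

## Known limitations

- The two-stage screen's strict-median semantics make the returned set
  sensitive to ties on small or highly symmetric networks; use the
  non-strict variant or external cutoffs there.
- Eigenvector centrality on a disconnected network reflects only the
  dominant component; a per-component analysis requires screening the
  components separately.
- Betweenness is exact (no sampling), O(V·E); networks beyond ~10⁵ edges
  will be slow, and approximation is out of scope.
- Enrichment treats terms as independent gene sets; no DAG-aware (elim /
  weight) correction.
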