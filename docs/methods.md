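# Methods

## Model and procedure

The screen treats the interactome as an unweighted, undirected simple graph
of opaque protein identifiers; the metric is the shortest-path hop count.
All proximity computation is restricted to the largest connected component
so every distance is finite; disease proteins and compound targets falling
outside it are dropped and counted in the per-compound bookkeeping. Ties
between equal-size components are broken by the component containing the
lexicographically smallest node, so repeated runs see the same graph.

For a disease set S and target set T, the closest distance d_c(S, T) is the
mean over targets of the hop distance to the nearest disease protein,
realized as a single multi-source BFS from S (the inner minimum over
sources falls out of the sweep). Targets inside S contribute zero — the
measure deliberately rewards direct targeting of disease proteins; the
per-compound direct-interaction count |T ∩ S| is reported alongside so that
this contribution is visible.

### Degree-matched null

Raw closest distances are confounded by degree: high-degree proteins are
close to everything. The null redraws both S and T independently in each of
`n_iterations` iterations, replacing every protein with a random protein of
comparable degree, and recomputes d_c. Degree comparability is implemented
with contiguous degree bins: distinct degree values are pooled in ascending
order until a bin holds at least `min_bin_size` nodes (default 100,
following the convention of the proximity framework this screen adopts); a
trailing undersized bin is merged into its predecessor. Sampling is without
replacement within one drawn set; an exhausted bin is temporarily widened
to its neighbours (logged). Reference proteins are themselves legal draws —
excluding them would bias the null away from the observed configuration.

Z_dc = (d_c − μ)/σ uses the population (denominator-n) standard deviation
of the null ensemble: the drawn ensemble is the null population being
described, not a sample from a larger one. When σ falls below the
`sigma_tolerance` (1e-12) the z-score is undefined and reported as a null
sentinel rather than ±∞, keeping sorting and serialization well-defined;
such compounds rank after all z-scored compounds, ordered by d_c. The
ranking order is z ascending, then d_c, then compound identifier.

`n_iterations` defaults to 1000. Each compound consumes an independent
child random stream spawned from the run seed, so results are bit-
reproducible and insensitive to screen order.

## Compound–target assembly

Two provenance classes are merged into one row per (compound, target) pair:
validated (curated databases; no score required) and predicted (score in
[0, 1] mandatory). The prediction-score filter keeps predicted rows with
score strictly greater than 0.82 — the operating point at which the
upstream target predictor showed a 1% false-discovery rate; validated rows
always survive. The drug-likeness filter keeps compounds with QED at or
above 0.35 (inclusive), the average QED of approved drugs. When a pair
occurs in both sources the merged row is recorded as validated; a validated
directional label (activatory/inhibitory) beats a predicted one, but a
validated "other" is refined by a directional prediction — the experiment
certifies the interaction exists, the prediction supplies its direction.
Conflicting duplicate rows within one source are an input error, reported
with the offending pairs; unknown action labels are rejected at parse time.

## Recovery statistics

Whether predicted pairs re-find a validated gold standard is tested two
ways against the universe of all predictable pairs: exactly, with the
hypergeometric upper tail P(X ≥ k) (the conventional over-representation
tail), and empirically, by redrawing the predicted set uniformly without
replacement and counting gold overlaps, with the add-one estimator
(1 + hits)/(1 + permutations) so the permutation p is never exactly zero.
The two routes cross-check each other in the test suite.

## Mechanism outputs

A compound's mechanism subnetwork admits its targets plus every disease
protein directly adjacent to a target; interactome edges within the node
set and compound→target edges are emitted with node labels recording
target/disease/bridge status and process group. Direct adjacency is the
default because mechanism diagrams in this field show first-neighbour
interactions; one-hop bridge proteins (adjacent to both a target and a
disease protein) are opt-in, and admitting a bridge also admits the disease
proteins it reaches — otherwise the bridge would dangle. Targets that are
themselves disease proteins carry both labels.

Overrepresentation uses one-sided Fisher exact tests (equal to the
hypergeometric tail) with Benjamini-Hochberg correction across all tested
terms (delegated to statsmodels behind the package's own validated
surface); fold enrichment is (k/n)/(K/N). The annotation universe is a
caller decision and is carried in every result row, because fold baselines
are meaningless without it. Process-group assignment resolves
multi-membership by a fixed priority order (lipid metabolism →
inflammation → oxidative stress → other), mirroring how disease-protein
panels are conventionally grouped.

## Synthetic scenarios

The generator emulates the statistical structure of the real inputs, not
their scale:

* **Interactome** — preferential attachment (via networkx's growth model,
  star-seed convention, hence exactly `attachment · (n − attachment)`
  edges): connected by construction with heavy-tailed degrees, the two
  properties the null model must be exercised against. A configuration
  model would need extra repair steps for both.
* **Disease module** — BFS growth from a random node with randomized
  frontier ties: connected, as disease modules are by hypothesis.
* **Compound cohorts** — proximal compounds draw targets within
  `proximity_radius` hops of the module (radius 0 ⇒ targets inside the
  module ⇒ d_c = 0 exactly); distal compounds draw strictly farther.
  Prediction scores straddle the 0.82 threshold by design (proximal
  ~ U(0.82, 1.0), distal ~ U(0.5, 0.95)) so score filtering is exercised
  on both sides of the cut. Generated action labels follow a
  ~9/87/4% activatory/inhibitory/other mix, the typical dominance of
  inhibitory calls in predicted compound–target tables.
* **Annotations** — random term sets plus one planted term whose members
  are drawn from a chosen protein set at `enrichment_fold` (default 5)
  times the baseline rate |set|/N, realized as a binomial count of
  in-set members followed by uniform picks; with the set equal to the
  universe the term degenerates to uniform, carrying no signal.

The reference scenario (500 nodes, attachment 3, module 30, 20 proximal
radius-1 + 20 distal compounds with 10–30 targets each, 1000 null
iterations) is the default parameterization everywhere — chosen as the
smallest configuration with a stable degree-binned null (five ≥100-node
bins) and realistic target-set sizes (mean ≈ 20 targets per compound).
What passing tests on it show: the screen separates known-proximal from
known-distal target sets and the null is calibrated on a scale-free
topology. What they do not show: performance on real interactomes' edge
densities, identifier noise, or literature-biased degree distributions —
the generator plants clean ground truth and samples targets independently
of each other, which real pharmacology does not.

## Numerical and design notes

* Distances are integer hop counts; d_c is an exact rational mean, so
  oracle comparisons in the tests use exact equality.
* Seeds: one run seed fans out to per-stage (and per-compound) child
  streams via seed-sequence spawning; identical inputs + seed reproduce
  outputs byte-for-byte.
* The degree-bin sampler first rejection-samples inside the home bin (20
  tries) before falling back to an explicit candidate list; both paths
  consume the same stream, preserving determinism.
* Degenerate inputs: empty sets after network restriction raise analysis
  errors naming the set; an empty graph is legal for loading but not for
  binning; a null ensemble with a single attainable distance yields σ = 0
  and an undefined z.
* The interactome loader silently drops self-loops and duplicate edges
  (logged), strips identifier whitespace, accepts comment lines and an
  optional header, and can apply a two-column identifier mapping at load
  time; it never translates identifiers on its own.

## Known limitations

* Only the closest proximity measure is implemented; shortest, centre,
  kernel, and separation variants are out of scope.
* The null matches degree marginals but not community structure; z-scores
  on strongly modular graphs can be conservative.
* Recovery-test universes must be supplied by the caller; the package does
  not reconstruct a predictor's predictable-pair space.
* QED values and prediction scores are consumed as given — computing them
  belongs to cheminformatics tooling upstream of this package.
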