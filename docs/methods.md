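# Methods

This note records the model assumptions, parameter choices, numerical
conventions and known limitations behind `pertnet`.  It documents decisions;
every empirical claim here is one the test suite or `scripts/acceptance.py`
computes itself.

## Data model

A *perturbation experiment* silences or over-expresses one gene and measures
standardized (z-scored) expression over a fixed gene universe.  Replication
is two-level: `m_j` biological replicates (distinct samples, usually 2–4),
each the average of `q_k` technical replicates (repeated measurements of the
same sample, usually 4–6).  `ReplicateTensor` stores the raw
genes × biological × technical values with ragged technical counts, since the
technical count is indexed per biological replicate.  Values are taken as
already standardized; technical averaging happens on that scale.  Missing
values are a load-time error — there is no principled imputation rule at this
stage, and silently propagating NaN through PCA and thresholding would be
worse than failing.

Knockdown vs over-expression and the time point are carried as metadata only.
Repeated assays of the same perturbation (e.g. two time points) are treated
as independent perturbation records and merged by edge union downstream; no
longitudinal model is attempted.

## Consensus replicate selection

Per perturbation, gene rows are centered on their replicate mean and scaled
by the *sample* standard deviation (`m_j − 1` denominator — the conventional
estimator at replicate counts of 2–4).  PCA is taken over the
replicate-by-replicate covariance (genes as observations, replicates as
variables), and the biological replicate with maximal Pearson correlation to
the PC1 score vector is selected as the representative.

Numerical conventions:

* PC1's sign is arbitrary, so the score vector is anchored to correlate
  non-negatively with the perturbation's grand-mean profile.  The anchor must
  use the pre-normalization (grand mean) profile: after per-gene centering
  the replicate-mean of the normalized matrix is identically zero.  If the
  anchor correlation is itself degenerate, the largest-magnitude score is
  made positive.  Selection is invariant to this convention (argmax of
  correlations is unaffected by a global sign flip).
* Correlation ties break to the lowest replicate index — deterministic and
  order-stable.
* Zero-variance gene rows are zeroed and flagged; a perturbation whose rows
  are all degenerate has no variance direction and raises an error.
* Single-replicate perturbations cannot be normalized or selected against;
  they pass through flagged, selecting replicate 0 with correlation 1.

The within-perturbation z-scores exist *only* to choose the representative.
They rescale every gene row to unit sd, destroying response magnitude, so a
fixed differential threshold would be meaningless on them.  Edge calling
therefore uses the selected replicate's values on the technical-replicate-mean
(standardized differential) scale.  Both scales are kept in
`ConsensusMatrix`, and `build_consensus_matrix(scale=...)` makes the choice
explicit and reversible.

## Edge calling and network assembly

A regulation `perturbed_gene → g` is called when `|v| ≥ θ` for some
qualifying biological-replicate value `v`.  The default rule examines *all*
biological replicates ("at least one biological replicate"); a
`selected_replicate_only` rule restricts to the consensus replicate — both
behaviors sit behind `ReconstructionParams.rule` because the two readings are
genuinely in tension and the package does not pretend to resolve it.

`θ = 4` by default, applied to the standardized differential value.  On
z-scored data there is no control baseline from which to form a literal
expression ratio, so "4-fold" is operationalized as 4 standardized units —
the same scale the synthetic generator plants effects on.  Calls with
opposite-sign passing replicates resolve to the larger magnitude and are
flagged as conflicts rather than dropped.  Self-edges are excluded by
default: the perturbed gene's own shift is the intervention, not a
regulation.  Duplicate (source, target) records merge keeping the larger
magnitude; node set is every incident gene plus every perturbed gene.

### Transitive simplification

`simplify_network` removes an edge `(u, w, s)` when a directed path
`u ⇝ w` of length ≥ 2 with edge-sign product `s` still exists without it.
Edges are processed in sorted order and each check runs against the
currently remaining graph, so removal never breaks signed reachability,
the operation is idempotent, and an edge on a cycle whose only explanation
is itself is kept.  On acyclic networks this equals the classic transitive
reduction refined by sign, independent of processing order (substituting any
removed edge by its explaining path preserves sign products, and a DAG
admits no self-referential substitution).  It is **off by default** so that
the raw reconstruction matches the verbatim calling rule; the underlying
published simplification procedure is not specified in detail anywhere we
can reproduce, and sign-aware transitive reduction is this package's
documented interpretation.

## Topology metrics

The metric names are standard but tool conventions vary, so the definitions
are fixed here: characteristic path length averages directed shortest-path
lengths over ordered *reachable* pairs (unreachable pairs are excluded, not
infinite); diameter/radius are max/min directed eccentricity over nodes that
reach at least one other node (0 for edgeless graphs); clustering,
neighborhood connectivity, topological coefficient and shared-neighbor
counts use the undirected projection; closeness is harmonic
(mean of `1/d` over the out-reachable set, hence in [0, 1], 0 for sinks);
betweenness and stress count directed shortest paths with endpoints
excluded, unnormalized.  Components are counted as weakly connected.  Hub
extraction returns nodes at or above an out-degree cutoff (presets 10 and
100), sorted by out-degree then node id.

All-pairs distances and path counts are computed by per-source BFS with
path-count accumulation and the centralities derived from the resulting
matrices; every metric is validated against exhaustive Floyd–Warshall /
path-enumeration oracles on small digraphs, and betweenness additionally
against networkx.

## Hotspot modules

Gene activity is the maximum absolute consensus differential across
perturbations, mapped through a rank-inverse-normal transform
(`Φ⁻¹((r − ½)/N)`, average ranks for ties) so scores are standard-normal
scale and invariant to monotone transforms of the raw statistic.  A module's
score is `z_A = Σ z_i / √|A|`.  Search grows modules greedily from the
top-scoring seed nodes (undirected neighbors, strict score improvement, size
cap 50); `search="local"` adds a pruning pass that drops nodes whose removal
keeps the module connected and raises the score.  Equal-gain additions break
ties by an optional node attribute (e.g. betweenness or neighborhood
connectivity) and then node id, keeping the search deterministic; the seed
only matters when random restarts are requested.  Up to `n_modules` (preset
5) candidates are accepted in score order, discarding any with Jaccard
overlap above `overlap_threshold` (preset 0.8) against an accepted module.
Greedy search is a heuristic: the test suite measures it at ≥ 0.9 of the
exhaustive optimum on 12-node graphs across 50 trials rather than assuming
it.  A Monte-Carlo background calibration for `z_A` (mean/sd over random
size-k sets) is available but not applied by default.

## Enrichment and cross-talk

Over-representation uses the upper-tail hypergeometric test against a
user-supplied background universe (default: the study's gene matrix, not the
genome) with Benjamini–Hochberg adjustment across the collection and the
conventional FDR ≤ 0.05 cutoff.  Gene sets are read from GMT.  Cross-talk
between sets S and T is the count of network edges `u → v` with `u ∈ S`,
`v ∈ T`, split by sign; genes in `S ∩ T` are reported separately (shared-gene
count and edges originating from shared genes) instead of being silently
double-counted.

## Synthetic studies

The generator plants a signed network — each perturbed gene regulates every
other gene independently with probability `edge_density`, with a random sign
and fixed effect size — then simulates, per biological replicate, background
`N(0, noise_sd²)` plus `sign × effect_size` for true targets, and per
technical replicate adds `N(0, (noise_sd/2)²)` re-measurement noise
(technical variation below biological, configurable).  The background
distribution of standardized values is taken as Gaussian; replicate counts
are drawn uniformly from the configured ranges.

Defaults are the package's benchmark study: **591 perturbations** with 2–4
biological × 4–6 technical replicates, `effect_size = 8`, `noise_sd = 0.5`,
`θ = 4`.  The source screens cover a ~22k-gene transcriptome, which is not a
desk-scale test condition; the default universe is scaled once to
`n_genes = 1000` with `edge_density = 0.02`, chosen so the expected planted
edge count (591 × 999 × 0.02 ≈ 11.8k) matches the order of magnitude of the
real networks this pipeline is aimed at, and not revisited.  Perturbed genes
are sampled without replacement, so each perturbation names a distinct gene;
`effect_size = 0` plants no edges (an effect-0 regulation is
indistinguishable from background).

What the simulator does **not** emulate: transcriptome covariance structure
(genes are independent given the planted effects), the landmark/imputed gene
distinction, chemical-compound perturbations, batch effects, or
heavy-tailed/outlier noise.  Consequently, passing recovery tests show the
pipeline's selection, thresholding and graph machinery are correct under the
stated noise model — not that the threshold `θ = 4` has any particular
operating characteristic on real screens, where effect sizes are continuous
and noise is structured.

At the benchmark conditions the per-replicate biological value of a true
target is `N(±8, 0.5² + 0.25²/q)`, so a miss at `θ = 4` is a ≥ 7.8-sd event
and recovery is essentially exact; the test suite asserts precision and
recall ≥ 0.95 across seeds, and the Gaussian-tail arithmetic itself is
verified against simulation at a noisier setting where the tails are
non-trivial.

## Problem sizes and determinism

Default test and acceptance runs use the 591 × 1000 benchmark study for the
end-to-end path and 5–6-node graphs for exhaustive-oracle comparisons (500
signed DAGs for the reduction, 200 digraphs for topology); these sizes keep
exhaustive enumeration exact while exercising every code path, and the full
pipeline at benchmark scale completes in well under a minute.  All
randomness flows through `numpy.random.default_rng` seeded from the
configuration (child streams for truth vs profiles), so identical
configurations reproduce byte-identical studies; profile TSVs are written
with `%.17g` and parsed with round-trip float precision so disk round-trips
are exact.

## Known limitations

* Edges carry no statistical significance — the calling rule is a fixed
  threshold by design, so downstream counts inherit its arbitrariness.
* The greedy module search has no optimality guarantee (measured bound
  above) and no simulated-annealing alternative.
* The enrichment universe default (study genes) is the right null for
  network-derived queries but not for externally derived gene lists.
* GCT support is a minimal read-only adapter for GCT 1.3 text matrices;
  HDF5-backed GCTX at repository scale is out of scope.
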