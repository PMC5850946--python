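# pertnet

Signed, directed gene-regulatory-network reconstruction from replicated
gene-perturbation expression screens, with downstream directed-topology
analysis, expression-activated ("hotspot") module search, and pathway
enrichment / cross-talk quantification.

## The problem

Large perturbation screens (systematic knockdown or over-expression of
hundreds of genes, transcriptome readout per experiment, in the style of the
LINCS L1000 resource) measure each perturbation as `m_j` biological
replicates, each averaged from `q_k` technical replicates, on a standardized
(z-scored) expression scale.  The question is which genes each perturbation
regulates, with what sign, and what the resulting directed network looks
like.  `pertnet` implements the full reconstruction pipeline plus a
synthetic-study generator with a planted ground-truth network, so every stage
is testable at desk scale without any external download.

## Method

For perturbation `j` with raw values `P[j,k,l]` (gene × biological replicate
`k` × technical replicate `l`):

1. **Technical averaging** — `P̄[j,k] = Σ_l P[j,k,l] / q_k`.
2. **Per-gene center/scale across replicates** —
   `Z[j,k] = (P̄[j,k] − P̿[j]) / σ_j` with `P̿[j]` the replicate mean and
   `σ_j` the sample standard deviation (zero-variance genes are zeroed and
   flagged).
3. **Representative selection** — the first principal component of the
   replicate-by-replicate covariance of `Z_j` is computed (genes as
   observations); the biological replicate with maximal Pearson correlation
   to PC1 becomes the perturbation's representative `Ẑ_j`, and
   `A = [Ẑ_1 … Ẑ_n]` is the consensus matrix.
4. **Edge calling** — gene `g` is regulated by perturbation `j` when its
   standardized differential value reaches `|v| ≥ θ` (default `θ = 4`) in at
   least one biological replicate; the edge `perturbed_gene → g` takes the
   sign of the largest-magnitude supporting value.
5. **Optional simplification** — sign-aware transitive reduction: an edge is
   removed when an indirect directed path with the same edge-sign product
   already explains it (signed reachability is preserved exactly).

Downstream: directed topology metrics (characteristic path length, diameter,
radius, clustering, betweenness, harmonic closeness, stress, neighborhood
connectivity, topological coefficient, shared-neighbor counts, out-degree hub
extraction); greedy hotspot-module search scoring connected subnetworks by
`z_A = Σ z_i / √|A|` over rank-inverse-normal gene activity scores (module
count 5, overlap threshold 0.8 as presets); hypergeometric gene-set
over-representation with Benjamini–Hochberg FDR (cutoff 0.05) and signed
cross-talk edge counts between pathway gene sets supplied as GMT files.

## Worked example

```python
from pertnet import (SimulationConfig, simulate_study, consensus_stage,
                     reconstruct_network, summarize, node_activity_scores,
                     search_modules, HotspotParams)

cfg = SimulationConfig(n_genes=100, n_perturbations=25, edge_density=0.05,
                       effect_size=8.0, noise_sd=0.5, seed=7)
study = simulate_study(cfg)                       # planted truth + profiles
stage = consensus_stage(study.profiles)           # averaging + PC1 selection
net = reconstruct_network(stage)                  # threshold at theta = 4

truth, found = study.truth.signed_edges(), net.signed_edges()
tp = len(truth & found)
print(f"planted edges: {len(truth)}, reconstructed: {len(found)}, "
      f"precision {tp/len(found):.3f}, recall {tp/len(truth):.3f}")

s = summarize(net)
print(f"nodes {s.n_nodes}, edges {s.n_edges}, CPL {s.characteristic_path_length:.2f}, "
      f"avg neighbors {s.avg_neighbors:.2f}")

scores, _ = node_activity_scores(stage.consensus, nodes=list(net.graph.nodes))
top = search_modules(net, scores, HotspotParams(seed=7))[0]
print(f"top hotspot: {len(top.nodes)} genes, score {top.score:.2f}, seed {top.seed_node}")
```

Output:

```
planted edges: 117, reconstructed: 117, precision 1.000, recall 1.000
nodes 75, edges 117, CPL 2.54, avg neighbors 3.12
top hotspot: 13 genes, score 4.00, seed G0070
```

All 117 planted signed edges are recovered with no false positives at these
benchmark conditions (effect size 8 against noise sd 0.5, threshold 4); the
network summary describes the reconstructed digraph, and the top hotspot is
the highest-scoring connected subnetwork of strongly responding genes.

The same stages are exposed as a CLI:

```sh
pertnet simulate  --config cfg.yaml --out study/ --seed 1
pertnet consensus --in study/ --out consensus.tsv --report selection.tsv
pertnet network   --study study/ --theta 4 --out net.tsv --sif net.sif
pertnet topology  --net net.tsv --summary summary.json --nodes nodes.tsv
pertnet hotspots  --net net.tsv --study study/ --out modules.json --seed 1
pertnet enrich    --net net.tsv --gmt sets.gmt --out enrich.tsv
pertnet crosstalk --net net.tsv --gmt sets.gmt --pairs SetA,SetB --out xtalk.tsv
pertnet pipeline  --config cfg.yaml --out run/ --gmt sets.gmt   # all of the above
```

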