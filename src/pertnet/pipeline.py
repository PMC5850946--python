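"""End-to-end orchestration: study -> consensus -> network -> reports.

Thin programmatic layer over the stage modules, shared by the command-line
interface and by scripted analyses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .consensus import (
    ConsensusMatrix,
    NormalizedProfile,
    build_consensus_matrix,
    center_scale,
)
from .enrichment import GeneSetCollection, hypergeometric_enrichment
from .hotspots import HotspotParams, node_activity_scores, search_modules
from .profile_io import (
    BiologicalReplicateMatrix,
    ReplicateTensor,
    average_technical_replicates,
    load_study,
)
from .reconstruction import (
    ReconstructionParams,
    RegulatoryNetwork,
    build_network,
    call_regulations,
    simplify_network,
)
from .topology import node_metrics, summarize

__all__ = ["ConsensusStage", "consensus_stage", "reconstruct_network", "run_pipeline"]


@dataclass
class ConsensusStage:
    tensors: list[ReplicateTensor]
    matrices: list[BiologicalReplicateMatrix]
    profiles: list[NormalizedProfile]
    consensus: ConsensusMatrix


def consensus_stage(
    tensors: Sequence[ReplicateTensor], scale: str = "differential"
) -> ConsensusStage:
    """Average technical replicates, normalize, and select representatives."""
    matrices = [average_technical_replicates(t) for t in tensors]
    profiles = [center_scale(b) for b in matrices]
    consensus = build_consensus_matrix(profiles, matrices, scale=scale)
    return ConsensusStage(
        tensors=list(tensors), matrices=matrices, profiles=profiles, consensus=consensus
    )


def reconstruct_network(
    stage: ConsensusStage, params: ReconstructionParams = ReconstructionParams()
) -> RegulatoryNetwork:
    """Threshold differential values and assemble the signed directed network."""
    calls = []
    for j, b in enumerate(stage.matrices):
        k = (
            int(stage.consensus.selection_index[j])
            if params.rule == "selected_replicate_only"
            else None
        )
        calls.append(call_regulations(b, params, selected_index=k))
    net = build_network(
        calls, perturbed_genes=[b.perturbed_gene for b in stage.matrices], params=params
    )
    if params.simplify:
        net = simplify_network(net)
    return net


def run_pipeline(
    study_dir: str | Path,
    out_dir: str | Path,
    recon: ReconstructionParams = ReconstructionParams(),
    hotspot: HotspotParams = HotspotParams(),
    gmt: str | Path | None = None,
    fdr: float = 0.05,
) -> dict:
    """Run every analysis stage on a study directory, writing all outputs.

    Expects ``<study_dir>/profiles/`` and ``<study_dir>/manifest.tsv``.
    Writes consensus.tsv, selection.tsv, network.tsv, network.sif,
    topology_summary.json, node_metrics.tsv, modules.json and (when a GMT
    collection is given) enrichment.tsv under ``out_dir``.  Returns the main
    in-memory results keyed by stage.
    """
    study_dir = Path(study_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    tensors = load_study(study_dir / "profiles", study_dir / "manifest.tsv")
    stage = consensus_stage(tensors)
    stage.consensus.to_frame().to_csv(out / "consensus.tsv", sep="\t", float_format="%.6g")
    stage.consensus.selection_report().to_csv(out / "selection.tsv", sep="\t", index=False)

    net = reconstruct_network(stage, recon)
    net.write_tsv(out / "network.tsv")
    net.write_sif(out / "network.sif")

    summary = summarize(net)
    (out / "topology_summary.json").write_text(json.dumps(summary.to_dict(), indent=2))
    nodes = node_metrics(net)
    nodes.to_csv(out / "node_metrics.tsv", sep="\t", float_format="%.6g")

    scores, _missing = node_activity_scores(stage.consensus, nodes=list(net.graph.nodes))
    modules = search_modules(net, scores, hotspot)
    (out / "modules.json").write_text(
        json.dumps(
            [
                {"nodes": sorted(m.nodes), "score": m.score, "seed_node": m.seed_node}
                for m in modules
            ],
            indent=2,
        )
    )

    enrich_df = None
    if gmt is not None:
        collection = GeneSetCollection.from_gmt(gmt, universe=stage.consensus.gene_ids)
        enrich_df = hypergeometric_enrichment(list(net.graph.nodes), collection)
        enrich_df.to_csv(out / "enrichment.tsv", sep="\t", index=False)

    return {
        "stage": stage,
        "network": net,
        "summary": summary,
        "node_metrics": nodes,
        "modules": modules,
        "enrichment": enrich_df,
    }
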