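"""Synthetic perturbation study generator with a planted regulatory network.

Emulates the structure of a large replicated knockdown/over-expression screen:
``n_perturbations`` experiments over a shared gene universe, each measured as
2-4 biological replicates of 4-6 technical replicates, on a standardized
(z-scored) expression scale.  A planted signed network drives large expression
shifts in true targets over Gaussian background noise, so the full
reconstruction pipeline can be validated against known ground truth.

Default condition: 591 perturbations over a 1000-gene universe with
edge_density 0.02 (≈ 11.8k expected true edges), background noise sd 0.5 and
target effect size 8 on the standardized scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .profile_io import ReplicateTensor, write_study

__all__ = [
    "SimulationConfig",
    "TruthNetwork",
    "SimulatedStudy",
    "generate_truth_network",
    "simulate_perturbation_study",
    "simulate_study",
    "write_truth_network",
    "load_truth_network",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for the simulator.

    All expression quantities are on the standardized ("level 3" z-score)
    scale, the same scale the reconstruction threshold theta applies to.
    """

    n_genes: int = 1000
    n_perturbations: int = 591
    biological_replicates_range: tuple[int, int] = (2, 4)
    technical_replicates_range: tuple[int, int] = (4, 6)
    noise_sd: float = 0.5
    effect_size: float = 8.0
    edge_density: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_perturbations < 1:
            raise ValueError("n_genes and n_perturbations must be >= 1")
        if self.n_perturbations > self.n_genes:
            raise ValueError(
                "n_perturbations may not exceed n_genes: each perturbation "
                "must name a distinct perturbed gene"
            )
        for lo, hi in (self.biological_replicates_range, self.technical_replicates_range):
            if lo < 1 or hi < lo:
                raise ValueError("replicate ranges must be [lo, hi] with 1 <= lo <= hi")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be > 0")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0.0 <= self.edge_density <= 1.0:
            raise ValueError("edge_density must be in [0, 1]")


@dataclass(frozen=True)
class TruthNetwork:
    """Planted ground truth: signed weighted edges from perturbed genes."""

    genes: tuple[str, ...]
    perturbed_genes: tuple[str, ...]
    edges: frozenset  # of (source, target, sign, effect)

    def __post_init__(self) -> None:
        universe = set(self.genes)
        for s, t, sign, eff in self.edges:
            if s == t:
                raise ValueError(f"self-edge {s}->{t} not allowed")
            if s not in universe or t not in universe:
                raise ValueError(f"edge {s}->{t} outside gene universe")
            if sign not in (-1, 1):
                raise ValueError(f"edge {s}->{t}: sign must be +-1")
            if not eff > 0:
                raise ValueError(f"edge {s}->{t}: effect size must be > 0")

    def signed_edges(self) -> set[tuple[str, str, int]]:
        return {(s, t, sign) for s, t, sign, _ in self.edges}

    def targets_of(self, source: str) -> dict[str, tuple[int, float]]:
        return {t: (sign, eff) for s, t, sign, eff in self.edges if s == source}

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class SimulatedStudy:
    truth: TruthNetwork
    profiles: list[ReplicateTensor]
    manifest: pd.DataFrame

    def write(self, out_dir: str | Path) -> None:
        """Write profiles/, manifest.tsv and truth_edges.tsv under out_dir."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_study(self.profiles, out / "profiles", out / "manifest.tsv")
        write_truth_network(self.truth, out / "truth_edges.tsv")


def _gene_names(n: int) -> tuple[str, ...]:
    width = max(4, len(str(n - 1)))
    return tuple(f"G{i:0{width}d}" for i in range(n))


def generate_truth_network(config: SimulationConfig) -> TruthNetwork:
    """Draw the planted network: per perturbed gene, each other gene becomes a
    target independently with probability ``edge_density``, with a random sign
    and the configured effect size."""
    rng = np.random.default_rng([config.seed, 0])
    genes = _gene_names(config.n_genes)
    idx = rng.choice(config.n_genes, size=config.n_perturbations, replace=False)
    perturbed = tuple(genes[i] for i in idx)
    edges = set()
    if config.effect_size == 0:
        # an effect-0 regulation is indistinguishable from background noise;
        # plant nothing so truth edges always carry a positive effect
        return TruthNetwork(genes=genes, perturbed_genes=perturbed, edges=frozenset())
    for i, src in zip(idx, perturbed):
        hit = rng.random(config.n_genes) < config.edge_density
        hit[i] = False  # no self-regulation: the perturbation is the cause
        signs = rng.choice((-1, 1), size=config.n_genes)
        for g in np.flatnonzero(hit):
            edges.add((src, genes[g], int(signs[g]), float(config.effect_size)))
    return TruthNetwork(genes=genes, perturbed_genes=perturbed, edges=frozenset(edges))


def simulate_perturbation_study(
    truth: TruthNetwork, config: SimulationConfig
) -> SimulatedStudy:
    """Simulate replicated profiles for each perturbation in ``truth``.

    Each biological replicate draws, per gene, background Normal(0, noise_sd^2)
    plus sign*effect_size if the gene is a true target; each technical
    replicate re-measures its biological replicate with additional
    Normal(0, (noise_sd/2)^2) technical noise.
    """
    if tuple(truth.genes) != _gene_names(config.n_genes) or len(
        truth.perturbed_genes
    ) != config.n_perturbations:
        raise ValueError("truth network was generated from an incompatible config")
    rng = np.random.default_rng([config.seed, 1])
    n = config.n_genes
    gene_index = {g: i for i, g in enumerate(truth.genes)}
    blo, bhi = config.biological_replicates_range
    tlo, thi = config.technical_replicates_range
    tech_sd = config.noise_sd / 2.0

    tensors: list[ReplicateTensor] = []
    for j, src in enumerate(truth.perturbed_genes):
        shift = np.zeros(n)
        for tgt, (sign, eff) in truth.targets_of(src).items():
            shift[gene_index[tgt]] = sign * eff
        m = int(rng.integers(blo, bhi + 1))
        blocks = []
        for _ in range(m):
            bio = shift + rng.normal(0.0, config.noise_sd, size=n)
            q = int(rng.integers(tlo, thi + 1))
            blocks.append(bio[:, None] + rng.normal(0.0, tech_sd, size=(n, q)))
        ptype = str(rng.choice(("knockdown", "overexpression")))
        tpoint = str(rng.choice(("96H", "144H")))
        tensors.append(
            ReplicateTensor(
                perturbation_id=f"P{j:04d}",
                perturbed_gene=src,
                gene_ids=list(truth.genes),
                values=blocks,
                perturbation_type=ptype,
                time_point=tpoint,
            )
        )

    rows = []
    for t in tensors:
        for k, block in enumerate(t.values):
            for l in range(block.shape[1]):
                rows.append(
                    {
                        "perturbation_id": t.perturbation_id,
                        "perturbed_gene": t.perturbed_gene,
                        "bio_rep": k + 1,
                        "column": f"b{k + 1}t{l + 1}",
                        "perturbation_type": t.perturbation_type,
                        "time_point": t.time_point,
                    }
                )
    return SimulatedStudy(truth=truth, profiles=tensors, manifest=pd.DataFrame(rows))


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Convenience: planted network plus simulated profiles in one call."""
    truth = generate_truth_network(config)
    return simulate_perturbation_study(truth, config)


def write_truth_network(truth: TruthNetwork, path: str | Path) -> None:
    rows = sorted(truth.edges)
    pd.DataFrame(rows, columns=["source", "target", "sign", "effect"]).to_csv(
        path, sep="\t", index=False
    )


def load_truth_network(path: str | Path, genes: tuple[str, ...] | None = None) -> TruthNetwork:
    df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
    edges = frozenset(
        (r.source, r.target, int(r.sign), float(r.effect)) for r in df.itertuples()
    )
    if genes is None:
        genes = tuple(sorted(set(df["source"]) | set(df["target"])))
    perturbed = tuple(dict.fromkeys(df["source"]))
    return TruthNetwork(genes=tuple(genes), perturbed_genes=perturbed, edges=edges)
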