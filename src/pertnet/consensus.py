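"""Representative-replicate (consensus) selection per perturbation.

For each perturbation the biological-replicate means are centered and scaled
per gene, the first principal component over replicates is computed, and the
single biological replicate best correlated with that component is selected as
the perturbation's representative profile.  Columns of the consensus matrix A
are the selected replicates, one per perturbation.

The within-perturbation z-scores exist only to choose the representative:
they rescale every gene row to unit sd, which destroys response magnitude.
Thresholded edge calling therefore uses the selected replicate's values on the
technical-replicate-mean (standardized differential) scale; both scales are
retained in :class:`ConsensusMatrix` and the choice is configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .profile_io import BiologicalReplicateMatrix

__all__ = [
    "NormalizedProfile",
    "ConsensusMatrix",
    "center_scale",
    "first_principal_component",
    "select_representative",
    "build_consensus_matrix",
]


@dataclass
class NormalizedProfile:
    """Per-gene centered/scaled replicate profile of one perturbation.

    Rows with zero between-replicate sd are set to zero and flagged in
    ``degenerate``; single-replicate perturbations skip normalization
    entirely (``single_replicate``) and pass raw values through.
    """

    perturbation_id: str
    perturbed_gene: str
    gene_ids: list[str]
    Z: np.ndarray  # (n_genes, m_j)
    sigma: np.ndarray  # per-gene sample sd across biological replicates
    grand_mean: np.ndarray  # per-gene mean across biological replicates
    degenerate: np.ndarray  # boolean mask of sigma == 0 rows
    single_replicate: bool = False

    @property
    def n_biological(self) -> int:
        return self.Z.shape[1]


def center_scale(b: BiologicalReplicateMatrix) -> NormalizedProfile:
    """Center each gene row on its replicate mean and scale by its sample sd.

    Sample sd uses the m_j - 1 denominator.  A single-replicate matrix cannot
    be scaled and is passed through flagged; zero-sd rows are zeroed and
    flagged degenerate.
    """
    X = b.values
    m = X.shape[1]
    grand_mean = X.mean(axis=1)
    if m == 1:
        return NormalizedProfile(
            perturbation_id=b.perturbation_id,
            perturbed_gene=b.perturbed_gene,
            gene_ids=list(b.gene_ids),
            Z=X.copy(),
            sigma=np.zeros(X.shape[0]),
            grand_mean=grand_mean,
            degenerate=np.zeros(X.shape[0], dtype=bool),
            single_replicate=True,
        )
    sigma = X.std(axis=1, ddof=1)
    degenerate = sigma == 0.0
    safe = np.where(degenerate, 1.0, sigma)
    Z = (X - grand_mean[:, None]) / safe[:, None]
    Z[degenerate] = 0.0
    return NormalizedProfile(
        perturbation_id=b.perturbation_id,
        perturbed_gene=b.perturbed_gene,
        gene_ids=list(b.gene_ids),
        Z=Z,
        sigma=sigma,
        grand_mean=grand_mean,
        degenerate=degenerate,
    )


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    nx = np.linalg.norm(xc)
    ny = np.linalg.norm(yc)
    if nx == 0.0 or ny == 0.0:
        return np.nan
    return float(np.dot(xc, yc) / (nx * ny))


def first_principal_component(p: NormalizedProfile) -> np.ndarray:
    """PC1 score vector over genes.

    Treats genes as observations and replicates as variables; returns the
    projection of each gene's (centered) replicate profile onto the leading
    eigenvector of the replicate-by-replicate covariance.  The overall sign is
    fixed so the score vector correlates non-negatively with the perturbation's
    replicate-mean profile (on the pre-normalization scale, where that mean is
    not identically zero); if that correlation is degenerate, the largest-
    magnitude score is made positive.
    """
    if p.single_replicate or p.n_biological < 2:
        raise ValueError(
            f"{p.perturbation_id}: PCA requires at least 2 biological replicates"
        )
    if bool(p.degenerate.all()):
        raise ValueError(f"{p.perturbation_id}: no variance (all gene rows degenerate)")
    scores = PCA(n_components=1).fit_transform(p.Z)[:, 0]
    anchor = _pearson(scores, p.grand_mean)
    if np.isnan(anchor) or anchor == 0.0:
        if scores[np.argmax(np.abs(scores))] < 0:
            scores = -scores
    elif anchor < 0:
        scores = -scores
    return scores


def select_representative(p: NormalizedProfile) -> tuple[int, float]:
    """Index (0-based) and Pearson correlation of the replicate most correlated
    with PC1; ties broken toward the lowest index.  Single-replicate profiles
    trivially select replicate 0 with correlation 1."""
    if p.single_replicate or p.n_biological == 1:
        return 0, 1.0
    pc1 = first_principal_component(p)
    corrs = np.array([_pearson(p.Z[:, k], pc1) for k in range(p.n_biological)])
    usable = np.where(np.isnan(corrs), -np.inf, corrs)
    k_star = int(np.argmax(usable))  # argmax returns the first (lowest) maximizer
    return k_star, float(corrs[k_star])


@dataclass
class ConsensusMatrix:
    """Selected representative profiles, genes x perturbations.

    ``values`` holds the thresholding-scale matrix A (selected replicates on
    the technical-replicate-mean scale by default); ``values_z`` the same
    columns on the within-perturbation z-score scale used for selection.
    """

    gene_ids: list[str]
    perturbation_ids: list[str]
    perturbed_genes: list[str]
    values: np.ndarray  # (n_genes, n)
    values_z: np.ndarray  # (n_genes, n)
    selection_index: np.ndarray  # chosen biological replicate per perturbation
    selection_correlation: np.ndarray
    single_replicate: np.ndarray  # boolean flags
    scale: str = "differential"

    def to_frame(self, z_scale: bool = False) -> pd.DataFrame:
        return pd.DataFrame(
            self.values_z if z_scale else self.values,
            index=pd.Index(self.gene_ids, name="gene_id"),
            columns=self.perturbation_ids,
        )

    def selection_report(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "perturbation_id": self.perturbation_ids,
                "perturbed_gene": self.perturbed_genes,
                "selected_replicate": self.selection_index,
                "correlation": self.selection_correlation,
                "single_replicate": self.single_replicate,
            }
        )


def build_consensus_matrix(
    profiles: Sequence[NormalizedProfile],
    raw: Sequence[BiologicalReplicateMatrix],
    scale: str = "differential",
) -> ConsensusMatrix:
    """Assemble A = [Zhat_1, ..., Zhat_n] from per-perturbation selections.

    ``scale='differential'`` (default) puts the selected replicate's
    technical-replicate-mean values in ``values``; ``scale='zscore'`` puts the
    within-perturbation z-scores there instead.  All perturbations must share
    the gene universe.
    """
    if scale not in ("differential", "zscore"):
        raise ValueError(f"unknown scale {scale!r}")
    if len(profiles) != len(raw):
        raise ValueError("profiles and raw matrices must align one-to-one")
    if not profiles:
        raise ValueError("no perturbations given")
    genes = list(profiles[0].gene_ids)
    cols, cols_z, ks, rs, singles = [], [], [], [], []
    for p, b in zip(profiles, raw):
        if p.gene_ids != genes or b.gene_ids != genes:
            raise ValueError(
                f"{p.perturbation_id}: gene universe differs from first perturbation"
            )
        if p.perturbation_id != b.perturbation_id:
            raise ValueError(
                f"profile/raw mismatch: {p.perturbation_id} vs {b.perturbation_id}"
            )
        k, r = select_representative(p)
        cols.append(b.values[:, k])
        cols_z.append(p.Z[:, k])
        ks.append(k)
        rs.append(r)
        singles.append(p.single_replicate)
    diff = np.column_stack(cols)
    zmat = np.column_stack(cols_z)
    return ConsensusMatrix(
        gene_ids=genes,
        perturbation_ids=[p.perturbation_id for p in profiles],
        perturbed_genes=[p.perturbed_gene for p in profiles],
        values=diff if scale == "differential" else zmat,
        values_z=zmat,
        selection_index=np.array(ks, dtype=int),
        selection_correlation=np.array(rs, dtype=float),
        single_replicate=np.array(singles, dtype=bool),
        scale=scale,
    )
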