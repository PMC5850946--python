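"""Data model and I/O for replicated perturbation expression profiles.

A perturbation experiment (one gene knocked down or over-expressed, one time
point) is measured as ``m_j`` biological replicates, each of which is itself
measured as ``q_k`` technical replicates.  Values are standardized ("level
3"-style z-scored) expression over a fixed gene universe.  The raw tensor is
``P[j, k, l]`` with ``j`` indexing the perturbation, ``k = 1..m_j`` the
biological replicate and ``l = 1..q_k`` the technical replicate; technical
replicate counts may differ between biological replicates (ragged ``q_k``).

On-disk layout is plain TSV: one genes x technical-replicates matrix per
perturbation plus a manifest mapping columns to biological replicates.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ReplicateTensor",
    "BiologicalReplicateMatrix",
    "average_technical_replicates",
    "load_study",
    "write_study",
    "read_gct",
    "MANIFEST_COLUMNS",
]

#: Required manifest columns; extra metadata columns are preserved but ignored.
MANIFEST_COLUMNS = ("perturbation_id", "perturbed_gene", "bio_rep", "column")


@dataclass
class ReplicateTensor:
    """Raw values of one perturbation experiment: genes x biological x technical.

    ``values[k]`` is the (n_genes, q_k) block of technical replicates for
    biological replicate ``k``; blocks may have different widths.
    """

    perturbation_id: str
    perturbed_gene: str
    gene_ids: list[str]
    values: list[np.ndarray]
    perturbation_type: str | None = None
    time_point: str | None = None
    column_names: list[list[str]] | None = None

    def __post_init__(self) -> None:
        if len(self.values) < 1:
            raise ValueError(
                f"{self.perturbation_id}: need at least one biological replicate"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError(f"{self.perturbation_id}: duplicate gene ids")
        n = len(self.gene_ids)
        self.values = [np.asarray(v, dtype=float) for v in self.values]
        for k, block in enumerate(self.values):
            if block.ndim != 2 or block.shape[0] != n:
                raise ValueError(
                    f"{self.perturbation_id}: biological replicate {k} block has "
                    f"shape {block.shape}, expected ({n}, q_k)"
                )
            if block.shape[1] < 1:
                raise ValueError(
                    f"{self.perturbation_id}: biological replicate {k} has no "
                    "technical replicates"
                )
            if not np.isfinite(block).all():
                raise ValueError(
                    f"{self.perturbation_id}: non-finite value in biological "
                    f"replicate {k}"
                )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_biological(self) -> int:
        """m_j: number of biological replicates."""
        return len(self.values)

    @property
    def n_technical(self) -> list[int]:
        """q_k for each biological replicate."""
        return [block.shape[1] for block in self.values]


@dataclass
class BiologicalReplicateMatrix:
    """Technical-replicate means: one column per biological replicate."""

    perturbation_id: str
    perturbed_gene: str
    gene_ids: list[str]
    values: np.ndarray  # (n_genes, m_j)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.gene_ids):
            raise ValueError(
                f"{self.perturbation_id}: expected (n_genes, m_j) matrix, got "
                f"shape {self.values.shape}"
            )
        if not np.isfinite(self.values).all():
            raise ValueError(f"{self.perturbation_id}: non-finite value")

    @property
    def n_biological(self) -> int:
        return self.values.shape[1]


def average_technical_replicates(tensor: ReplicateTensor) -> BiologicalReplicateMatrix:
    """Average each biological replicate's technical replicates, per gene.

    The mean biological sample is the arithmetic mean over the q_k technical
    replicates; ragged q_k is supported.
    """
    means = np.column_stack([block.mean(axis=1) for block in tensor.values])
    return BiologicalReplicateMatrix(
        perturbation_id=tensor.perturbation_id,
        perturbed_gene=tensor.perturbed_gene,
        gene_ids=list(tensor.gene_ids),
        values=means,
    )


def _read_profile_matrix(path: Path) -> pd.DataFrame:
    if not path.is_file():
        raise FileNotFoundError(f"profile matrix not found: {path}")
    # round_trip parsing: loaded values must equal the written float64 exactly
    df = pd.read_csv(path, sep="\t", dtype={0: str}, float_precision="round_trip")
    if df.columns[0] != "gene_id":
        raise ValueError(f"{path}: first column must be 'gene_id', got {df.columns[0]!r}")
    df = df.set_index("gene_id")
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()[:5]
        raise ValueError(f"{path}: duplicate gene ids {dups}")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index
            raise ValueError(
                f"{path}: non-numeric cell in column {col!r} "
                f"(e.g. gene {bad[0]!r})" if len(bad) else f"{path}: column {col!r} not numeric"
            )
    if df.isna().any().any():
        gene = df.index[df.isna().any(axis=1)][0]
        raise ValueError(f"{path}: missing value at gene {gene!r}")
    return df


def load_study(profile_dir: str | os.PathLike, manifest: str | os.PathLike) -> list[ReplicateTensor]:
    """Load a replicated perturbation study from per-perturbation TSV matrices.

    The manifest must contain the columns ``perturbation_id``,
    ``perturbed_gene``, ``bio_rep`` and ``column``; each row assigns one
    technical-replicate column of ``<perturbation_id>.tsv`` to a biological
    replicate.  Gene order is harmonized to the first perturbation's order;
    differing gene universes are an error.
    """
    profile_dir = Path(profile_dir)
    man = pd.read_csv(manifest, sep="\t", dtype={"perturbation_id": str, "column": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in man.columns]
    if missing:
        raise ValueError(f"{manifest}: manifest missing columns {missing}")

    tensors: list[ReplicateTensor] = []
    gene_order: list[str] | None = None
    for pid, rows in man.groupby("perturbation_id", sort=False):
        path = profile_dir / f"{pid}.tsv"
        df = _read_profile_matrix(path)
        if gene_order is None:
            gene_order = df.index.tolist()
        elif set(df.index) != set(gene_order):
            raise ValueError(
                f"{path}: gene universe differs from first perturbation "
                f"({len(df.index)} vs {len(gene_order)} genes or different ids)"
            )
        df = df.reindex(gene_order)
        perturbed = rows["perturbed_gene"].unique()
        if len(perturbed) != 1:
            raise ValueError(f"{manifest}: perturbation {pid!r} has multiple perturbed genes {perturbed}")
        blocks: list[np.ndarray] = []
        colnames: list[list[str]] = []
        for bio_rep, sub in rows.groupby("bio_rep", sort=True):
            cols = sub["column"].tolist()
            absent = [c for c in cols if c not in df.columns]
            if absent:
                raise ValueError(
                    f"{manifest}: perturbation {pid!r} bio_rep {bio_rep} names "
                    f"column(s) {absent} absent from {path.name}"
                )
            blocks.append(df[cols].to_numpy(dtype=float))
            colnames.append(cols)
        extra = {}
        for opt in ("perturbation_type", "time_point"):
            if opt in man.columns:
                extra[opt] = rows[opt].iloc[0]
        tensors.append(
            ReplicateTensor(
                perturbation_id=str(pid),
                perturbed_gene=str(perturbed[0]),
                gene_ids=list(gene_order),
                values=blocks,
                column_names=colnames,
                **extra,
            )
        )
    return tensors


def write_study(
    tensors: Sequence[ReplicateTensor],
    profile_dir: str | os.PathLike,
    manifest: str | os.PathLike,
) -> None:
    """Write per-perturbation TSV matrices plus the replicate manifest."""
    profile_dir = Path(profile_dir)
    profile_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for t in tensors:
        cols: list[str] = []
        data: list[np.ndarray] = []
        for k, block in enumerate(t.values):
            for l in range(block.shape[1]):
                name = (
                    t.column_names[k][l]
                    if t.column_names is not None
                    else f"b{k + 1}t{l + 1}"
                )
                cols.append(name)
                data.append(block[:, l])
                row = {
                    "perturbation_id": t.perturbation_id,
                    "perturbed_gene": t.perturbed_gene,
                    "bio_rep": k + 1,
                    "column": name,
                }
                if t.perturbation_type is not None:
                    row["perturbation_type"] = t.perturbation_type
                if t.time_point is not None:
                    row["time_point"] = t.time_point
                rows.append(row)
        df = pd.DataFrame(np.column_stack(data), index=pd.Index(t.gene_ids, name="gene_id"), columns=cols)
        # %.17g round-trips float64 exactly
        df.to_csv(profile_dir / f"{t.perturbation_id}.tsv", sep="\t", float_format="%.17g")
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)


def read_gct(path: str | os.PathLike) -> pd.DataFrame:
    """Minimal read-only adapter for GCT 1.3 text matrices.

    Returns the data block as a genes x samples DataFrame indexed by the first
    (id) column; row/column metadata fields are dropped.
    """
    path = Path(path)
    with open(path) as fh:
        version = fh.readline().strip()
        if not version.startswith("#1.3"):
            raise ValueError(f"{path}: unsupported GCT version line {version!r}")
        dims = fh.readline().split()
        if len(dims) < 4:
            raise ValueError(f"{path}: malformed GCT dimension line")
        n_rows, n_cols, n_rmeta, n_cmeta = (int(x) for x in dims[:4])
        df = pd.read_csv(fh, sep="\t", index_col=0)
    # drop row-metadata columns and column-metadata rows
    df = df.iloc[n_cmeta:, n_rmeta:]
    if df.shape != (n_rows, n_cols):
        raise ValueError(
            f"{path}: data block {df.shape} disagrees with declared ({n_rows}, {n_cols})"
        )
    return df.astype(float)
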