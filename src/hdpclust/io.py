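"""Reading, preprocessing and writing of expression matrices and cluster
tables.

On disk a matrix is TSV/CSV with genes as rows: first column gene IDs,
header row experiment IDs.  Internally experiments index rows (see
:class:`~hdpclust.core.ExpressionMatrix`), so reading transposes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, Partition
from .sampler import ChainTrace, MembershipPosterior

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "PreprocessConfig",
    "preprocess",
    "write_clusters",
    "read_clusters",
    "write_trace",
    "write_truth",
]

_SEPS = {"tsv": "\t", "csv": ","}


def read_expression_matrix(path, dialect: str = "tsv") -> ExpressionMatrix:
    """Read a genes-as-rows matrix file; errors name the offending cell."""
    if dialect not in _SEPS:
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    df = pd.read_csv(path, sep=_SEPS[dialect], index_col=0, dtype=str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene IDs: {dups}")
    if df.isna().any().any():
        raise ValueError("ragged or missing cells in matrix file")
    values = np.empty(df.shape)
    for ci, col in enumerate(df.columns):
        for ri, raw in enumerate(df[col]):
            try:
                values[ri, ci] = float(raw)
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric cell at gene {df.index[ri]!r}, "
                    f"experiment {col!r}: {raw!r}") from None
    return ExpressionMatrix(values=values.T,
                            gene_ids=tuple(str(g) for g in df.index),
                            experiment_ids=tuple(str(c) for c in df.columns))


def write_expression_matrix(data: ExpressionMatrix, path,
                            dialect: str = "tsv") -> None:
    df = pd.DataFrame(data.values.T, index=list(data.gene_ids),
                      columns=list(data.experiment_ids))
    df.index.name = "gene_id"
    df.to_csv(path, sep=_SEPS[dialect])


@dataclass(frozen=True)
class PreprocessConfig:
    """Filtering switches: optional log2 transform, then drop genes whose
    mean or variance across experiments falls below a threshold."""

    log2: bool = False
    min_mean: float = 0.0
    min_variance: float = 0.0

    def __post_init__(self) -> None:
        if self.min_mean < 0 or self.min_variance < 0:
            raise ValueError("thresholds must be >= 0")


def preprocess(data: ExpressionMatrix, cfg: PreprocessConfig,
               ) -> tuple[ExpressionMatrix, list[tuple[str, str]]]:
    """Apply the configured transform and filters.

    Returns the retained matrix and a report: (gene_id, reason) for every
    dropped gene.  The log2 transform requires strictly positive values.
    """
    values = data.values.copy()
    if cfg.log2:
        if np.any(values <= 0):
            bad = np.argwhere(values <= 0)[0]
            raise ValueError(
                f"log2 transform of non-positive value at experiment "
                f"{data.experiment_ids[bad[0]]!r}, gene {data.gene_ids[bad[1]]!r}")
        values = np.log2(values)
    means = values.mean(axis=0)
    variances = values.var(axis=0)
    report: list[tuple[str, str]] = []
    keep = []
    for idx, gid in enumerate(data.gene_ids):
        # a zero threshold disables the corresponding filter
        if cfg.min_mean > 0 and means[idx] < cfg.min_mean:
            report.append((gid, f"mean {means[idx]:.4g} < {cfg.min_mean:g}"))
        elif cfg.min_variance > 0 and variances[idx] < cfg.min_variance:
            report.append((gid, f"variance {variances[idx]:.4g} < {cfg.min_variance:g}"))
        else:
            keep.append(idx)
    if not keep:
        raise ValueError("preprocessing removed every gene")
    out = ExpressionMatrix(values=values[:, keep],
                           gene_ids=tuple(data.gene_ids[idx] for idx in keep),
                           experiment_ids=data.experiment_ids)
    return out, report


def write_clusters(partition: Partition, posterior: MembershipPosterior | None,
                   path, long_path=None) -> None:
    """Write the gene -> cluster table (TSV: gene_id, cluster,
    max_posterior_probability) and optionally a long-format per-experiment
    membership table."""
    rows = []
    gene_index = {}
    if posterior is not None:
        gene_index = {g: idx for idx, g in enumerate(posterior.gene_ids)}
    for gid in partition.items:
        prob = ""
        if posterior is not None:
            scores = posterior.gene_scores[gene_index[gid]]
            prob = f"{scores.max() / scores.sum():.6f}"
        rows.append((gid, partition[gid], prob))
    df = pd.DataFrame(rows, columns=["gene_id", "cluster",
                                     "max_posterior_probability"])
    df.to_csv(path, sep="\t", index=False)
    if long_path is not None and posterior is not None:
        long_rows = []
        M, N, K = posterior.cell_probs.shape
        for j in range(M):
            for gid, idx in gene_index.items():
                for a in range(K):
                    p = posterior.cell_probs[j, idx, a]
                    if p > 0:
                        long_rows.append((gid, j, a + 1, f"{p:.6f}"))
        pd.DataFrame(long_rows, columns=["gene_id", "experiment_index",
                                         "cluster", "probability"]
                     ).to_csv(long_path, sep="\t", index=False)


def read_clusters(path) -> Partition:
    """Read a cluster table written by :func:`write_clusters` (or any TSV
    whose first two columns are gene_id and cluster)."""
    df = pd.read_csv(path, sep="\t")
    return Partition.from_sequence(df.iloc[:, 0].astype(str),
                                   df.iloc[:, 1].tolist())


def write_truth(partition: Partition, path) -> None:
    df = pd.DataFrame(sorted(partition.labels.items()),
                      columns=["gene_id", "cluster"])
    df.to_csv(path, sep="\t", index=False)


def write_trace(trace: ChainTrace, path) -> None:
    """Serialize a chain trace as JSON lines: one snapshot per line with
    canonical table and dish labels and the concentration values."""
    with open(path, "w") as fh:
        for idx, snap in enumerate(trace.snapshots):
            fh.write(json.dumps({
                "snapshot": idx,
                "tables": snap.tables.tolist(),
                "dishes": snap.z.tolist(),
                "alpha0": snap.alpha0,
                "alpha1": snap.alpha1,
            }) + "\n")
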