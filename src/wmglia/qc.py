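"""Per-cell quality-control filters for plate-based and droplet scRNA-seq.

Two filter chains are provided. The plate-based (Smart-seq2) chain keeps a
cell only if all nine per-cell sequencing metrics fall inside closed
intervals, matching QC conventions for full-length libraries where alignment
statistics and ERCC spike-in fractions are informative. The droplet chain
removes lowly detected genes first and then cells by detected-gene count,
mitochondrial fraction and (optionally) per-batch UMI/gene caps, the
convention for UMI-based platforms.

Smart-seq2 bounds are inclusive on both ends; droplet caps are strict
(`umi >= max_umi` removes), so the two chains deliberately use different
boundary semantics.
"""
from __future__ import annotations

import dataclasses
import json
import logging

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

#: the nine per-cell Smart-seq2 QC metrics, in reporting order
SMARTSEQ_METRICS: tuple[str, ...] = (
    "reads",
    "genes",
    "mean_read_length",
    "mismatch_rate",
    "pct_unique_mapped",
    "pct_multimapped",
    "pct_too_short",
    "frac_ercc",
    "frac_mito",
)

#: default genes flagged as ribosomal-RNA contamination in mouse droplet data
DEFAULT_CONTAMINANT_GENES: tuple[str, ...] = ("Gm42418", "AY036118")


@dataclasses.dataclass(frozen=True)
class QCThresholds:
    """Closed [lo, hi] interval per Smart-seq2 QC metric.

    A cell passes only if every metric satisfies ``lo <= value <= hi``.
    ``mismatch_rate`` carries an unusual lower bound of 0.15 and ``frac_ercc``
    an upper bound of 0.011 interpreted on the 0-1 fraction scale; both are
    applied exactly as configured (see the methods note for discussion) and
    are ordinary configurable intervals here.
    """

    reads: tuple[float, float] = (20_000.0, 4e6)
    genes: tuple[float, float] = (1_000.0, 6_500.0)
    mean_read_length: tuple[float, float] = (180.0, 200.0)
    mismatch_rate: tuple[float, float] = (0.15, 0.5)
    pct_unique_mapped: tuple[float, float] = (68.0, 100.0)
    pct_multimapped: tuple[float, float] = (2.3, 7.7)
    pct_too_short: tuple[float, float] = (0.0, 17.0)
    frac_ercc: tuple[float, float] = (0.0, 0.011)
    frac_mito: tuple[float, float] = (0.0, 0.006)

    def __post_init__(self) -> None:
        for metric, (lo, hi) in self.bounds().items():
            if not lo <= hi:
                raise ValueError(f"threshold for {metric!r} has lo > hi: ({lo}, {hi})")

    def bounds(self) -> dict[str, tuple[float, float]]:
        return {m: getattr(self, m) for m in SMARTSEQ_METRICS}

    def replace(self, **updates: tuple[float, float]) -> "QCThresholds":
        return dataclasses.replace(self, **updates)


@dataclasses.dataclass(frozen=True)
class DropletFilterParams:
    """Droplet-platform filter parameters.

    ``min_cells_per_gene`` is applied to genes first; the remaining bounds
    remove cells. ``max_umi`` and ``max_genes`` are strict upper caps
    (a cell at exactly the cap is removed) and may be ``None`` to disable,
    since they vary per sequencing batch.
    """

    min_cells_per_gene: int = 3
    min_genes_per_cell: int = 200
    max_frac_mito: float = 0.10
    max_umi: int | None = None
    max_genes: int | None = None
    mito_prefix: str = "mt-"

    def __post_init__(self) -> None:
        for name in ("min_cells_per_gene", "min_genes_per_cell", "max_frac_mito"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("max_umi", "max_genes"):
            value = getattr(self, name)
            if value is not None and value <= 0:
                raise ValueError(f"{name} must be positive when set")


@dataclasses.dataclass
class QCReport:
    """Outcome of a filter chain: partition sizes and per-metric failures."""

    n_input: int
    n_kept: int
    n_removed: int
    failure_counts: dict[str, int]
    removed: dict[str, list[str]]
    n_genes_input: int | None = None
    n_genes_kept: int | None = None

    def __post_init__(self) -> None:
        if self.n_kept + self.n_removed != self.n_input:
            raise ValueError("kept + removed must equal input")
        if any(not reasons for reasons in self.removed.values()):
            raise ValueError("every removed cell must fail at least one metric")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    def summary(self) -> str:
        lines = [
            f"cells in: {self.n_input}, kept: {self.n_kept}, removed: {self.n_removed}"
        ]
        if self.n_genes_input is not None:
            lines.append(f"genes in: {self.n_genes_input}, kept: {self.n_genes_kept}")
        for metric, count in self.failure_counts.items():
            lines.append(f"  failed {metric}: {count}")
        return "\n".join(lines)


def _metric_frame(table: pd.DataFrame) -> pd.DataFrame:
    """Validate and coerce the nine metric columns; index must be cell ids."""
    if "cell_id" in table.columns:
        table = table.set_index("cell_id")
    if not table.index.is_unique:
        raise ValueError("cell ids are not unique")
    missing = [m for m in SMARTSEQ_METRICS if m not in table.columns]
    if missing:
        raise KeyError(f"QC table is missing metric columns: {missing}")
    out = pd.DataFrame(index=table.index)
    for metric in SMARTSEQ_METRICS:
        col = pd.to_numeric(table[metric], errors="coerce")
        if col.isna().sum() > table[metric].isna().sum():
            raise ValueError(f"non-numeric values in metric column {metric!r}")
        out[metric] = col
    return out


def apply_smartseq_filters(
    table: pd.DataFrame, thresholds: QCThresholds | None = None
) -> tuple[list[str], QCReport]:
    """Keep cells whose nine QC metrics all lie inside their closed intervals.

    Parameters
    ----------
    table
        One row per cell with the nine metric columns; cell ids either as the
        index or in a ``cell_id`` column.
    thresholds
        Interval per metric; defaults to the plate-based thresholds above.

    Returns
    -------
    kept
        Cell ids passing every filter, in input order.
    report
        Per-metric failure counts and the failing metrics of each removed
        cell. Missing (NaN) metric values count as failures since the
        interval condition cannot be verified.
    """
    thresholds = thresholds or QCThresholds()
    metrics = _metric_frame(table)
    fail = pd.DataFrame(False, index=metrics.index, columns=list(SMARTSEQ_METRICS))
    for metric, (lo, hi) in thresholds.bounds().items():
        col = metrics[metric]
        fail[metric] = ~((col >= lo) & (col <= hi))  # NaN -> fail
    removed_mask = fail.any(axis=1)
    kept = [str(cid) for cid in metrics.index[~removed_mask]]
    removed = {
        str(cid): [m for m in SMARTSEQ_METRICS if fail.at[cid, m]]
        for cid in metrics.index[removed_mask]
    }
    report = QCReport(
        n_input=len(metrics),
        n_kept=len(kept),
        n_removed=int(removed_mask.sum()),
        failure_counts={m: int(fail[m].sum()) for m in SMARTSEQ_METRICS},
        removed=removed,
    )
    return kept, report


def _dense_counts(adata: ad.AnnData) -> np.ndarray:
    X = adata.X
    if sp.issparse(X):
        X = X.toarray()
    return np.asarray(X)


def apply_droplet_filters(
    adata: ad.AnnData, params: DropletFilterParams | None = None
) -> tuple[ad.AnnData, QCReport]:
    """Gene-then-cell filtering for droplet count matrices.

    Order is fixed: genes expressed in fewer than ``min_cells_per_gene``
    cells are dropped first (expression counted over the *input* cells), and
    detected-gene numbers for the subsequent cell filter are computed on the
    surviving genes. Cells are then removed when detected genes fall below
    ``min_genes_per_cell``, the mitochondrial count fraction exceeds
    ``max_frac_mito`` (strictly), or total UMIs / detected genes reach the
    optional strict caps.
    """
    params = params or DropletFilterParams()
    if adata.n_obs == 0 or adata.n_vars == 0:
        raise ValueError("empty matrix")
    X = _dense_counts(adata)
    if X.min() < 0:
        raise ValueError("counts must be non-negative")

    cells_per_gene = (X > 0).sum(axis=0)
    gene_keep = cells_per_gene >= params.min_cells_per_gene
    Xg = X[:, gene_keep]
    var_kept = adata.var_names[gene_keep]

    genes_detected = (Xg > 0).sum(axis=1)
    umis = Xg.sum(axis=1)
    mito = np.char.lower(var_kept.to_numpy().astype(str))
    mito_mask = np.char.startswith(mito, params.mito_prefix.lower())
    with np.errstate(invalid="ignore", divide="ignore"):
        frac_mito = np.where(umis > 0, Xg[:, mito_mask].sum(axis=1) / np.maximum(umis, 1), 0.0)

    reasons = {
        "genes": genes_detected < params.min_genes_per_cell,
        "frac_mito": frac_mito > params.max_frac_mito,
    }
    if params.max_umi is not None:
        reasons["umi"] = umis >= params.max_umi
    if params.max_genes is not None:
        reasons["max_genes"] = genes_detected >= params.max_genes
    fail = np.column_stack(list(reasons.values()))
    removed_mask = fail.any(axis=1)

    cell_ids = adata.obs_names.to_numpy().astype(str)
    removed = {
        cell_ids[i]: [name for j, name in enumerate(reasons) if fail[i, j]]
        for i in np.flatnonzero(removed_mask)
    }
    filtered = adata[~removed_mask, gene_keep].copy()
    report = QCReport(
        n_input=adata.n_obs,
        n_kept=int((~removed_mask).sum()),
        n_removed=int(removed_mask.sum()),
        failure_counts={name: int(fail[:, j].sum()) for j, name in enumerate(reasons)},
        removed=removed,
        n_genes_input=adata.n_vars,
        n_genes_kept=int(gene_keep.sum()),
    )
    return filtered, report


def remove_genes(
    adata: ad.AnnData, genes: tuple[str, ...] | list[str] = DEFAULT_CONTAMINANT_GENES
) -> ad.AnnData:
    """Drop named genes (e.g. rRNA-contamination indicators) from the matrix.

    Names absent from the matrix are ignored with a log note; cells are
    never touched.
    """
    present = [g for g in genes if g in adata.var_names]
    missing = sorted(set(genes) - set(present))
    if missing:
        logger.info("remove_genes: %d name(s) not in matrix: %s", len(missing), missing)
    if not present:
        return adata.copy()
    keep = ~adata.var_names.isin(present)
    return adata[:, keep].copy()
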