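"""Normalization, marker-signature scoring, cell-state calls and marker ranking.

The biology of the aging-white-matter states lives in small marker sets:
interferon-responsive oligodendrocytes (IRO: Stat1, Ifi27l2a and MHC class I
genes), age-related oligodendrocytes (ARO: Serpina3n, C4b),
interferon-responsive microglia (IRM: Stat1, Ifit3), the IFN program shared
between IRO and IRM, and T/NK cells (Cd3d, Trbc2). Cells are scored against
each signature as the mean across signature genes of the gene's across-cell
z-score, and labeled with the best-scoring signature above a threshold.

Marker ranking between two cell groups uses a two-sided Wilcoxon rank-sum
test per gene (exact enumeration for small groups, tie- and
continuity-corrected normal approximation otherwise), the Seurat-style
log2 fold change of mean de-logged expression, and Benjamini-Hochberg
adjustment.
"""
from __future__ import annotations

import dataclasses
import logging

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: pseudo-expression added to both group means in the fold-change ratio
FC_EPSILON = 1e-9
#: largest per-group size for which the exact rank-sum distribution is used
EXACT_MAX_GROUP = 10


@dataclasses.dataclass(frozen=True)
class SignatureSet:
    """A named marker gene set."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("signature gene list must be non-empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("signature genes must be unique")


def default_signatures() -> dict[str, SignatureSet]:
    """Marker sets for the aging white-matter glial states."""
    sets = {
        "IRO": ("Stat1", "Ifi27l2a", "B2m", "H2-K1", "H2-D1"),
        "ARO": ("Serpina3n", "C4b"),
        "IRM": ("Stat1", "Ifit3"),
        "IFN_shared": ("Stat1", "Ifit3", "Usp18", "Ifi27l2a"),
        "T_NK": ("Cd3d", "Trbc2"),
    }
    return {name: SignatureSet(name, genes) for name, genes in sets.items()}


def _matrix(adata: ad.AnnData) -> np.ndarray:
    X = adata.X
    if sp.issparse(X):
        X = X.toarray()
    return np.asarray(X, dtype=float)


def normalize_log(adata: ad.AnnData, scale_factor: float = 1e4) -> ad.AnnData:
    """Library-size normalize and log-transform counts.

    Each entry becomes ``log(1 + count / libsize * scale_factor)`` where
    ``libsize`` is the cell's total count. Raw counts are preserved in
    ``layers['counts']``. A zero-libsize cell signals that QC was skipped
    and raises.
    """
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    X = _matrix(adata)
    if X.min() < 0:
        raise ValueError("counts must be non-negative")
    libsize = X.sum(axis=1)
    if np.any(libsize == 0):
        raise ValueError("cell(s) with zero library size; run QC filtering first")
    norm = np.log1p(X / libsize[:, None] * scale_factor)
    out = ad.AnnData(
        X=norm, obs=adata.obs.copy(), var=adata.var.copy(), uns=dict(adata.uns)
    )
    out.layers["counts"] = X
    return out


def score_signature(norm: ad.AnnData, sig: SignatureSet) -> np.ndarray:
    """Per-cell signature score: mean across-cell z-score of signature genes.

    Genes with zero variance across cells contribute 0 (not NaN). Genes
    missing from the matrix are skipped with a log note; if none are
    present an error is raised.
    """
    present = [g for g in sig.genes if g in norm.var_names]
    if not present:
        raise ValueError(f"no gene of signature {sig.name!r} present in matrix")
    if len(present) < len(sig.genes):
        logger.info(
            "signature %s: %d/%d genes present",
            sig.name, len(present), len(sig.genes),
        )
    idx = norm.var_names.get_indexer(present)
    X = _matrix(norm)[:, idx]
    mu = X.mean(axis=0)
    sd = X.std(axis=0)  # population sd; degenerate genes handled below
    z = np.zeros_like(X)
    ok = sd > 0
    z[:, ok] = (X[:, ok] - mu[ok]) / sd[ok]
    return z.mean(axis=1)


def score_signatures(
    norm: ad.AnnData, sigs: dict[str, SignatureSet] | None = None
) -> pd.DataFrame:
    """Score every signature; returns cells x signatures."""
    sigs = sigs or default_signatures()
    return pd.DataFrame(
        {name: score_signature(norm, sig) for name, sig in sigs.items()},
        index=norm.obs_names,
    )


def assign_states(
    scores: pd.DataFrame,
    rules: list[tuple[str, float]],
    unassigned_label: str = "unassigned",
) -> pd.DataFrame:
    """Label each cell with the best-scoring signature above its threshold.

    ``rules`` is an ordered list of (signature name, threshold tau). A cell
    gets the highest-scoring signature whose score strictly exceeds its tau;
    exact ties go to the earlier rule. Cells clearing no threshold are
    labeled ``unassigned``.
    """
    if not rules:
        raise ValueError("rule list must be non-empty")
    names = [name for name, _ in rules]
    missing = [n for n in names if n not in scores.columns]
    if missing:
        raise KeyError(f"rules reference unscored signatures: {missing}")
    S = scores[names].to_numpy(dtype=float)
    if not np.all(np.isfinite(S)):
        raise ValueError("signature scores must be finite")
    taus = np.array([tau for _, tau in rules], dtype=float)
    masked = np.where(S > taus, S, -np.inf)
    best = masked.argmax(axis=1)  # argmax takes the first max -> earlier rule
    labels = np.where(
        np.isfinite(masked[np.arange(len(S)), best]),
        np.array(names, dtype=object)[best],
        unassigned_label,
    )
    out = scores.copy()
    out.insert(0, "state", labels)
    return out


def _exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact rank-sum p by dynamic programming over pooled ranks.

    Uses doubled mid-ranks so all sums are integers (ties allowed). The
    p-value is P(|W - E[W]| >= |w_obs - E[W]|) under the permutation
    distribution of the group-A rank sum W.
    """
    n1, n = len(x), len(x) + len(y)
    pooled = np.concatenate([x, y])
    ranks2 = np.rint(2 * stats.rankdata(pooled)).astype(np.int64)
    w_obs = int(ranks2[:n1].sum())
    mean2 = n1 * (n + 1)  # doubled expected rank sum
    total = ranks2.sum()
    # ways[k, s] = number of size-k subsets with doubled-rank sum s
    ways = np.zeros((n1 + 1, total + 1), dtype=np.float64)
    ways[0, 0] = 1.0
    for r in ranks2:
        for k in range(n1, 0, -1):
            ways[k, r:] += ways[k - 1, : total + 1 - r]
    dist = ways[n1]
    n_subsets = dist.sum()
    s = np.arange(total + 1)
    extreme = np.abs(s - mean2) >= abs(w_obs - mean2)
    return float(dist[extreme].sum() / n_subsets)


def _rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p; exact for small groups."""
    if np.ptp(np.concatenate([x, y])) == 0:
        return 1.0
    if max(len(x), len(y)) <= EXACT_MAX_GROUP:
        return _exact_rank_sum_p(x, y)
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.pvalue)


def rank_markers(
    norm: ad.AnnData,
    labels: pd.Series | np.ndarray,
    group_a: str,
    group_b: str,
    fc_threshold: float | None = None,
) -> pd.DataFrame:
    """Rank genes differentially expressed between two labeled cell groups.

    Per gene: ``avg_log2FC = log2((mean expm1 in A + eps)/(mean expm1 in B
    + eps))``, a two-sided Wilcoxon rank-sum p, and BH adjustment across all
    tested genes. When ``fc_threshold`` is set, genes with
    ``|avg_log2FC| <= fc_threshold`` are dropped *after* adjustment. Rows
    are sorted by p ascending then |avg_log2FC| descending.
    """
    labels = np.asarray(labels)
    if len(labels) != norm.n_obs:
        raise ValueError("labels length must match number of cells")
    mask_a = labels == group_a
    mask_b = labels == group_b
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValueError("each group needs at least 2 cells for the rank-sum test")
    X = _matrix(norm)
    Xa, Xb = X[mask_a], X[mask_b]
    mean_a = np.expm1(Xa).mean(axis=0)
    mean_b = np.expm1(Xb).mean(axis=0)
    log2fc = np.log2((mean_a + FC_EPSILON) / (mean_b + FC_EPSILON))
    if max(len(Xa), len(Xb)) <= EXACT_MAX_GROUP:
        pvals = np.array([_rank_sum_p(Xa[:, j], Xb[:, j]) for j in range(X.shape[1])])
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.mannwhitneyu(
                Xa, Xb, alternative="two-sided", method="asymptotic",
                use_continuity=True, axis=0,
            )
        pvals = np.asarray(res.pvalue, dtype=float)
        degenerate = np.ptp(X, axis=0) == 0
        pvals[degenerate | ~np.isfinite(pvals)] = 1.0
    p_adj = multipletests(pvals, method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "gene": norm.var_names.to_numpy(),
            "avg_log2FC": log2fc,
            "p": pvals,
            "p_adjusted": p_adj,
            "direction": np.where(log2fc > 0, "up", np.where(log2fc < 0, "down", "flat")),
        }
    )
    if fc_threshold is not None:
        table = table[np.abs(table["avg_log2FC"]) > fc_threshold]
    table = table.sort_values(
        ["p", "avg_log2FC"],
        key=lambda c: c if c.name == "p" else -c.abs(),
        kind="mergesort",
    ).reset_index(drop=True)
    return table


def top_k_overlap(
    markers_a: pd.DataFrame, markers_b: pd.DataFrame, k: int = 50
) -> set[str]:
    """Genes in the top-k rows of both (already sorted) marker tables.

    Tables shorter than ``k`` are used in full with a log note. The result
    is symmetric in its arguments.
    """
    tops = []
    for name, table in (("a", markers_a), ("b", markers_b)):
        if len(table) < k:
            logger.info("marker table %s has %d < k=%d rows; using all", name, len(table), k)
        tops.append(set(table["gene"].head(k)))
    return tops[0] & tops[1]
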