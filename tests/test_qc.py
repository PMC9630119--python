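"""QC filter chains: boundary semantics, oracle equivalence, invariants."""
import anndata as ad
import numpy as np
import pandas as pd
import pytest

from wmglia.qc import (
    SMARTSEQ_METRICS,
    DropletFilterParams,
    QCThresholds,
    apply_droplet_filters,
    apply_smartseq_filters,
    remove_genes,
)

from conftest import passing_qc_row, random_qc_table


def brute_force_smartseq(table: pd.DataFrame, thresholds: QCThresholds) -> list[str]:
    """Independent per-cell conjunction of the nine interval predicates."""
    bounds = thresholds.bounds()
    kept = []
    for cid, row in table.iterrows():
        if all(bounds[m][0] <= row[m] <= bounds[m][1] for m in SMARTSEQ_METRICS):
            kept.append(str(cid))
    return kept


@pytest.mark.parametrize("metric", SMARTSEQ_METRICS)
@pytest.mark.parametrize("side", ["lo", "hi"])
def test_interval_endpoints_inclusive(metric, side):
    """A cell exactly at either bound passes; just outside it fails there."""
    lo, hi = getattr(QCThresholds(), metric)
    span = hi - lo
    at_bound = passing_qc_row()
    at_bound[metric] = lo if side == "lo" else hi
    outside = passing_qc_row()
    outside[metric] = lo - 1e-4 * span if side == "lo" else hi + 1e-4 * span
    table = pd.DataFrame([at_bound, outside], index=["at_bound", "outside"])
    kept, report = apply_smartseq_filters(table)
    assert kept == ["at_bound"]
    assert report.removed["outside"] == [metric]


def test_reads_boundary_literal_counts():
    """reads = 20,000 is kept, 19,999 is removed and attributed to reads."""
    rows = [passing_qc_row(), passing_qc_row()]
    rows[0]["reads"] = 20_000
    rows[1]["reads"] = 19_999
    table = pd.DataFrame(rows, index=["ok", "low"])
    kept, report = apply_smartseq_filters(table)
    assert kept == ["ok"]
    assert report.removed["low"] == ["reads"]


def test_smartseq_matches_brute_force(rng):
    table = random_qc_table(rng, 2000)
    kept, report = apply_smartseq_filters(table)
    assert kept == brute_force_smartseq(table, QCThresholds())
    assert report.n_kept + report.n_removed == report.n_input == 2000
    assert set(kept).isdisjoint(report.removed)
    assert all(report.removed.values())  # every removed cell fails something


def test_smartseq_idempotent(rng):
    table = random_qc_table(rng, 500)
    kept, _ = apply_smartseq_filters(table)
    kept2, report2 = apply_smartseq_filters(table.loc[kept])
    assert kept2 == kept
    assert report2.n_removed == 0


def test_widening_interval_grows_kept_set(rng):
    table = random_qc_table(rng, 500)
    kept_default, _ = apply_smartseq_filters(table)
    for metric in SMARTSEQ_METRICS:
        lo, hi = getattr(QCThresholds(), metric)
        span = hi - lo
        wide = QCThresholds().replace(
            **{metric: (max(0.0, lo - span), hi + span)}
        )
        kept_wide, _ = apply_smartseq_filters(table, wide)
        assert set(kept_default) <= set(kept_wide)


def test_missing_metric_column_errors(rng):
    table = random_qc_table(rng, 5).drop(columns=["frac_mito"])
    with pytest.raises(KeyError, match="frac_mito"):
        apply_smartseq_filters(table)


def test_non_numeric_metric_errors(rng):
    table = random_qc_table(rng, 5).astype(object)
    table.iloc[0, 0] = "not a number"
    with pytest.raises(ValueError, match="non-numeric"):
        apply_smartseq_filters(table)


# ---------------------------------------------------------------------------
# droplet chain


def _adata(X: np.ndarray, genes: list[str]) -> ad.AnnData:
    return ad.AnnData(
        X=np.asarray(X, dtype=np.int64),
        obs=pd.DataFrame(index=[f"cell{i}" for i in range(X.shape[0])]),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )


def brute_force_droplet(adata, params):
    """Independent reimplementation: gene filter, then cell predicates."""
    X = np.asarray(adata.X)
    gene_keep = (X > 0).sum(axis=0) >= params.min_cells_per_gene
    Xg = X[:, gene_keep]
    names = adata.var_names[gene_keep]
    kept_cells = []
    for i in range(X.shape[0]):
        genes_det = int((Xg[i] > 0).sum())
        umi = int(Xg[i].sum())
        mito = sum(
            Xg[i, j]
            for j, g in enumerate(names)
            if g.lower().startswith(params.mito_prefix.lower())
        )
        frac = mito / umi if umi else 0.0
        ok = genes_det >= params.min_genes_per_cell and frac <= params.max_frac_mito
        if params.max_umi is not None:
            ok = ok and umi < params.max_umi
        if params.max_genes is not None:
            ok = ok and genes_det < params.max_genes
        if ok:
            kept_cells.append(i)
    return kept_cells, np.flatnonzero(gene_keep).tolist()


def test_droplet_strict_boundaries():
    """Exactly 200 detected genes and exactly 10% mito are both kept."""
    n_genes = 300
    genes = [f"g{i}" for i in range(n_genes - 1)] + ["mt-x"]
    # every gene expressed in >= 3 cells so the gene filter is neutral
    base = np.ones((6, n_genes), dtype=np.int64)
    X = base.copy()
    X[0, : n_genes - 200] = 0  # cell0: exactly 200 detected genes
    X[1, : n_genes - 199] = 0  # cell1: 199 detected genes
    adata = _adata(X, genes)
    params = DropletFilterParams(min_cells_per_gene=0, min_genes_per_cell=200)
    filtered, report = apply_droplet_filters(adata, params)
    assert "cell0" in filtered.obs_names
    assert "cell1" not in filtered.obs_names
    assert report.removed["cell1"] == ["genes"]


def test_droplet_mito_fraction_boundary():
    genes = ["mt-a"] + [f"g{i}" for i in range(9)]
    at = np.ones((3, 10), dtype=np.int64)
    at[0, 0] = 1  # 1/10 = 0.10 exactly -> kept
    at[1, 0] = 2  # 2/11 > 0.10 -> removed
    at[2, 0] = 0
    adata = _adata(at, genes)
    params = DropletFilterParams(
        min_cells_per_gene=0, min_genes_per_cell=1, max_frac_mito=0.10
    )
    filtered, report = apply_droplet_filters(adata, params)
    assert list(filtered.obs_names) == ["cell0", "cell2"]
    assert report.removed["cell1"] == ["frac_mito"]


def test_droplet_umi_cap_is_strict():
    genes = [f"g{i}" for i in range(10)]
    X = np.full((2, 10), 10, dtype=np.int64)
    X[1, 0] = 11  # totals: 100 (kept, < cap) and 101 (removed, >= cap)
    adata = _adata(X, genes)
    params = DropletFilterParams(
        min_cells_per_gene=0, min_genes_per_cell=1, max_umi=101
    )
    filtered, _ = apply_droplet_filters(adata, params)
    assert list(filtered.obs_names) == ["cell0"]


def test_droplet_gene_filter_runs_before_cell_filter():
    """A cell passing on raw genes fails after rare genes are removed."""
    genes = [f"g{i}" for i in range(5)]
    X = np.array(
        [
            [1, 1, 1, 1, 1],  # cell0: 5 detected, but g4 is rare
            [1, 1, 1, 1, 0],
            [1, 1, 1, 1, 0],
            [1, 1, 1, 1, 0],
        ],
        dtype=np.int64,
    )
    adata = _adata(X, genes)
    params = DropletFilterParams(min_cells_per_gene=3, min_genes_per_cell=5)
    filtered, report = apply_droplet_filters(adata, params)
    assert report.n_genes_kept == 4  # g4 dropped first
    assert filtered.n_obs == 0  # then no cell reaches 5 detected genes


def test_droplet_matches_brute_force(rng):
    genes = [f"g{i}" for i in range(295)] + [f"mt-{i}" for i in range(5)]
    X = rng.poisson(0.8, size=(500, 300)).astype(np.int64)
    X[:, 295:] += rng.poisson(2.0, size=(500, 5))
    adata = _adata(X, genes)
    params = DropletFilterParams(
        min_cells_per_gene=3, min_genes_per_cell=120, max_frac_mito=0.08,
        max_umi=320, max_genes=260,
    )
    filtered, report = apply_droplet_filters(adata, params)
    kept_cells, kept_genes = brute_force_droplet(adata, params)
    assert list(filtered.obs_names) == [f"cell{i}" for i in kept_cells]
    assert list(filtered.var_names) == [genes[j] for j in kept_genes]
    assert report.n_kept == len(kept_cells)


def test_droplet_rejects_negative_and_empty():
    adata = _adata(np.array([[1, -1]]), ["a", "b"])
    with pytest.raises(ValueError, match="non-negative"):
        apply_droplet_filters(adata)
    empty = _adata(np.zeros((0, 2), dtype=np.int64), ["a", "b"])
    with pytest.raises(ValueError, match="empty"):
        apply_droplet_filters(empty)


def test_remove_genes_drops_contaminants_and_ignores_missing(caplog):
    genes = ["Gm42418", "Actb", "AY036118", "Plp1"]
    adata = _adata(np.arange(8).reshape(2, 4), genes)
    out = remove_genes(adata)
    assert list(out.var_names) == ["Actb", "Plp1"]
    assert out.n_obs == 2
    np.testing.assert_array_equal(np.asarray(out.X), np.asarray(adata.X)[:, [1, 3]])
    # absent names are ignored; identity otherwise
    with caplog.at_level("INFO"):
        same = remove_genes(adata, ["NotAGene"])
    assert list(same.var_names) == genes
    assert "NotAGene" in caplog.text
    identical = remove_genes(adata, [])
    assert list(identical.var_names) == genes
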